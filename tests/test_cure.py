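"""Curing loop: read splitting, consensus substitution, iterative reach
into diverged clusters, convergence and change-log accounting."""

import numpy as np
import pytest

from homeocure.cure import (
    CuringConfig,
    build_cured_pair,
    cure_cycle,
    cure_reference,
    split_reads,
)
from homeocure.seqio import Read, ReadSet, UnigeneReference


def _mkread(rid, bases, q=30):
    return Read(rid, bases, np.full(len(bases), q))


def _tiling_reads(seq, read_len=80, step=1, copies=1, uid="u"):
    reads = []
    for c in range(copies):
        for s in range(0, len(seq) - read_len + 1, step):
            reads.append(_mkread(f"t{c}_{s}|{uid}|+|{s}|A", seq[s : s + read_len]))
    return ReadSet(reads, genome_tag="A")


class TestSplitReads:
    def test_halves_concatenate_to_original(self):
        rng = np.random.default_rng(0)
        bases = "".join(rng.choice(list("ACGT"), 80))
        quals = rng.integers(2, 41, 80)
        res = split_reads(ReadSet([Read("r", bases, quals)]))
        first, second = res
        assert first.reads[0].bases + second.reads[0].bases == bases
        assert list(first.reads[0].quals) + list(second.reads[0].quals) == list(quals)
        assert len(first.reads[0]) == len(second.reads[0]) == 40
        assert res.n_dropped == 0

    def test_empty_set_splits_to_empty_sets(self):
        res = split_reads(ReadSet([], nominal_length=80))
        assert len(res.first) == 0 and len(res.second) == 0

    def test_too_short_read_dropped_and_counted(self):
        rs = ReadSet([_mkread("r", "A" * 79)])
        res = split_reads(rs)
        assert res.n_dropped == 1
        assert len(res.first) == 0


class TestCureCycle:
    def test_reads_from_reference_itself_are_a_fixpoint(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 300))
        ref = UnigeneReference([("u", seq)])
        halves = split_reads(_tiling_reads(seq, step=7))
        cfg = CuringConfig(rng_seed=1)
        new_ref, stats = cure_cycle(ref, halves.first, halves.second, cfg)
        assert new_ref == ref
        assert stats.n_bases_changed_this_cycle == 0
        assert stats.n_reads_mapped == len(halves.first) + len(halves.second)

    def test_planted_wrong_base_is_corrected(self):
        rng = np.random.default_rng(2)
        true_seq = "".join(rng.choice(list("ACGT"), 300))
        wrong = list(true_seq)
        wrong[150] = "ACGT"["ACGT".index(true_seq[150]) - 1]
        ref = UnigeneReference([("u", "".join(wrong))])
        halves = split_reads(_tiling_reads(true_seq, step=5))
        new_ref, stats = cure_cycle(ref, halves.first, halves.second, CuringConfig())
        assert stats.n_bases_changed_this_cycle == 1
        assert new_ref["u"] == true_seq


class TestCureReference:
    def test_zero_cycles_returns_input_unchanged(self):
        ref = UnigeneReference([("u", "ACGT" * 30)])
        cured, stats, changes = cure_reference(
            ref, ReadSet([], nominal_length=80), CuringConfig(n_cycles=0)
        )
        assert cured == ref and stats == [] and changes == []

    def test_empty_progenitor_reads_leave_reference_naive(self):
        rng = np.random.default_rng(3)
        ref = UnigeneReference([("u", "".join(rng.choice(list("ACGT"), 200)))])
        cured, stats, changes = cure_reference(
            ref, ReadSet([], nominal_length=80), CuringConfig()
        )
        assert cured == ref
        assert changes == []
        assert all(s.n_reads_mapped == 0 for s in stats)

    def test_diverged_cluster_needs_later_cycles(self):
        """A dense divergent tract is unreachable at first: every read
        window covering its centre exceeds the mismatch cap, so the centre
        is cured only after flanking corrections let more reads align."""
        rng = np.random.default_rng(4)
        naive = "".join(rng.choice(list("ACGT"), 240))
        true_seq = list(naive)
        cluster = list(range(100, 133, 4))  # 9 sites, 4 bp apart
        for p in cluster:
            true_seq[p] = "ACGT"["ACGT".index(naive[p]) - 2]
        true_seq = "".join(true_seq)
        reads = _tiling_reads(true_seq, copies=2)
        ref = UnigeneReference([("u", naive)])
        cured, stats, changes = cure_reference(ref, reads, CuringConfig(rng_seed=9))
        assert cured["u"] == true_seq
        cycle_of = {c.pos: c.cycle for c in changes}
        assert set(cycle_of) == set(cluster)
        assert cycle_of[116] > 1  # centre waits for flanking corrections
        assert min(cycle_of.values()) == 1  # cluster edges reachable at once
        mapped = [s.n_reads_mapped for s in stats]
        assert mapped == sorted(mapped)

    def test_converged_reference_is_idempotent(self):
        rng = np.random.default_rng(5)
        naive = "".join(rng.choice(list("ACGT"), 300))
        true_seq = list(naive)
        for p in (50, 120, 200):
            true_seq[p] = "ACGT"["ACGT".index(naive[p]) - 1]
        true_seq = "".join(true_seq)
        reads = _tiling_reads(true_seq, step=3)
        cfg = CuringConfig(rng_seed=2)
        cured, _, _ = cure_reference(UnigeneReference([("u", naive)]), reads, cfg)
        recured, stats, changes = cure_reference(cured, reads, cfg)
        assert recured == cured and changes == []

    def test_lengths_and_ids_always_preserved(self, cure_fixture):
        naive = cure_fixture.truth.naive_reference()
        for cured in (cure_fixture.pair.a_ref, cure_fixture.pair.c_ref):
            assert cured.ids == naive.ids
            assert cured.lengths() == naive.lengths()

    def test_change_precision_under_sequencing_error(self, cure_fixture):
        """With 30x coverage and 1% error, essentially every substitution
        made by curing moves the reference onto the true progenitor base."""
        for tag in "AC":
            true_ref = cure_fixture.truth.true_reference(tag)
            changes = (
                cure_fixture.pair.a_changes if tag == "A" else cure_fixture.pair.c_changes
            )
            assert changes
            good = sum(
                1 for c in changes if true_ref[c.unigene_id][c.pos] == c.new_base
            )
            assert good / len(changes) >= 0.99


class TestBuildCuredPair:
    def test_identical_read_sets_give_identical_references(self):
        rng = np.random.default_rng(6)
        naive = "".join(rng.choice(list("ACGT"), 200))
        true_seq = list(naive)
        true_seq[100] = "ACGT"["ACGT".index(naive[100]) - 1]
        reads = _tiling_reads("".join(true_seq), step=2)
        pair = build_cured_pair(
            UnigeneReference([("u", naive)]), reads, reads, CuringConfig(rng_seed=3)
        )
        assert pair.a_ref == pair.c_ref
        assert len(pair.concerted_changes()) == len(pair.a_changes) == 1

    def test_one_empty_progenitor_leaves_that_genome_naive(self, tiny_truth):
        from homeocure.simdata import simulate_reads

        naive = tiny_truth.naive_reference()
        reads_a = simulate_reads(tiny_truth, "A", depth_target=15, seed=30)
        pair = build_cured_pair(
            naive, reads_a, ReadSet([], nominal_length=80), CuringConfig(rng_seed=4)
        )
        assert pair.c_ref == naive
        assert pair.c_changes == []
        assert all(s.n_bases_changed_this_cycle == 0 for s in pair.c_stats)
        assert len(pair.a_changes) > 0

    def test_cumulative_changes_are_running_sums(self, cure_fixture):
        for stats in (cure_fixture.pair.a_stats, cure_fixture.pair.c_stats):
            total = 0
            for s in stats:
                total += s.n_bases_changed_this_cycle
                assert s.cumulative_bases_changed == total


def test_every_ihp_position_traces_to_a_change_log_entry(cure_fixture):
    """Consistency between curing and IHP calling: any position where the
    cured references differ was substituted in at least one genome run
    (the naive base cannot differ from itself)."""
    from homeocure.ihp import compare_references

    table = compare_references(cure_fixture.pair.a_ref, cure_fixture.pair.c_ref)
    changed = {
        (c.unigene_id, c.pos)
        for c in cure_fixture.pair.a_changes + cure_fixture.pair.c_changes
    }
    for rec in table.records:
        assert (rec.unigene_id, rec.pos) in changed
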