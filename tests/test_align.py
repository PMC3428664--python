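"""Aligner contract: agreement with the exhaustive-scan oracle, strand
symmetry, tie-break fairness, pileups and consensus thresholds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import oracle_align, revcomp

from homeocure.align import (
    PileupColumn,
    align_read,
    align_readset,
    build_pileup,
    call_consensus,
)
from homeocure.seqio import Read, ReadSet, UnigeneReference


def _mkread(rid, bases, q=30):
    return Read(rid, bases, np.full(len(bases), q))


def _random_ref(rng, n_unigenes, max_len, min_len=60):
    entries = []
    for i in range(n_unigenes):
        L = int(rng.integers(min_len, max_len + 1))
        entries.append((f"u{i}", "".join(rng.choice(list("ACGT"), L))))
    return UnigeneReference(entries)


def assert_matches_oracle(reads, ref, cap, seed=0):
    alns = align_readset(reads, ref, max_mismatches=cap, seed=seed)
    mapped = {r.read_id: r for r in alns.records}
    entries = dict(ref.items())
    for read in reads:
        best, placements = oracle_align(read.bases, entries, cap)
        if best is None:
            assert read.id not in mapped
            continue
        rec = mapped[read.id]
        assert rec.mismatches == best
        assert (rec.unigene_id, rec.start, rec.strand) in placements
        assert rec.tie_broken == (len(placements) > 1)


class TestAlignRead:
    def test_exact_unique_match(self):
        rng = np.random.default_rng(0)
        ref = _random_ref(rng, 1, 200, 200)
        read = _mkread("r", ref["u0"][50:90])
        rec = align_read(read, ref, 3)
        assert (rec.unigene_id, rec.start, rec.strand) == ("u0", 50, "+")
        assert rec.mismatches == 0 and not rec.tie_broken

    def test_best_placement_beyond_cap_is_unmapped(self):
        rng = np.random.default_rng(1)
        ref = _random_ref(rng, 1, 200, 200)
        bases = list(ref["u0"][50:90])
        for i in (5, 15, 25, 35):  # 4 substitutions, cap 3
            bases[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bases[i]]
        assert align_read(_mkread("r", "".join(bases)), ref, 3) is None
        assert align_read(_mkread("r", "".join(bases)), ref, 4) is not None

    def test_reverse_complement_flips_strand_only(self):
        rng = np.random.default_rng(2)
        ref = _random_ref(rng, 3, 500)
        read = ref["u1"][10:50]
        fwd = align_read(_mkread("f", read), ref, 3)
        rev = align_read(_mkread("r", revcomp(read)), ref, 3)
        assert (fwd.unigene_id, fwd.start) == (rev.unigene_id, rev.start)
        assert {fwd.strand, rev.strand} == {"+", "-"}
        assert fwd.mismatches == rev.mismatches == 0

    def test_n_counts_as_mismatch(self):
        ref = UnigeneReference([("u0", "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGG")])
        read = ref["u0"][:20]
        noisy = "NNN" + read[3:]
        rec = align_read(_mkread("r", noisy), ref, 3)
        assert rec is not None and rec.mismatches == 3
        assert align_read(_mkread("r", "NNNN" + read[4:]), ref, 3) is None


class TestAlignReadset:
    def test_error_free_reads_all_map(self, tiny_truth):
        ref = tiny_truth.true_reference("A")
        rng = np.random.default_rng(5)
        reads = []
        for i, uid in enumerate(ref.ids):
            s = int(rng.integers(0, len(ref[uid]) - 40))
            reads.append(_mkread(f"r{i}", ref[uid][s : s + 40]))
        alns = align_readset(ReadSet(reads), ref, 3, seed=1)
        assert alns.n_mapped_reads == alns.n_input_reads == len(reads)

    def test_random_reads_match_oracle_even_when_unmapped(self):
        rng = np.random.default_rng(6)
        ref = _random_ref(rng, 3, 300)
        reads = ReadSet(
            [_mkread(f"r{i}", "".join(rng.choice(list("ACGT"), 40))) for i in range(50)]
        )
        alns = align_readset(reads, ref, 3, seed=2)
        assert alns.n_mapped_reads <= 2  # random 40-mers essentially never map
        assert_matches_oracle(reads, ref, 3, seed=2)

    def test_same_seed_reproduces_identical_alignments(self):
        rng = np.random.default_rng(7)
        ref = UnigeneReference([("a", "ACGT" * 50), ("b", "ACGT" * 50)])
        reads = ReadSet([_mkread(f"r{i}", "ACGT" * 10) for i in range(30)])
        a1 = align_readset(reads, ref, 3, seed=9)
        a2 = align_readset(reads, ref, 3, seed=9)
        for x, y in zip(a1.records, a2.records):
            assert (x.unigene_id, x.start, x.strand, x.mismatches) == (
                y.unigene_id, y.start, y.strand, y.mismatches
            )

    def test_tie_break_between_identical_unigenes_is_fair(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), 500))
        ref = UnigeneReference([("copy1", seq), ("copy2", seq)])
        n = 4000
        reads = ReadSet(
            [
                _mkread(f"r{i}", seq[s : s + 40])
                for i, s in enumerate(rng.integers(0, 460, n))
            ]
        )
        alns = align_readset(reads, ref, 3, seed=11)
        assert alns.n_mapped_reads == n
        assert all(alns.tie_broken)
        frac = np.mean([r.unigene_id == "copy1" for r in alns.records])
        se = 0.5 / np.sqrt(n)
        assert abs(frac - 0.5) <= 3 * se


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.data())
def test_aligner_equals_brute_force_oracle_property(data):
    """On small random instances the seeded search equals the full scan."""
    seed = data.draw(st.integers(0, 10_000))
    cap = data.draw(st.integers(0, 3))
    rng = np.random.default_rng(seed)
    ref = _random_ref(rng, int(rng.integers(1, 6)), 300, 80)
    read_len = data.draw(st.sampled_from([40, 80]))
    reads = []
    for i in range(15):
        uid = ref.ids[int(rng.integers(0, len(ref)))]
        s = int(rng.integers(0, len(ref[uid]) - read_len + 1))
        bases = list(ref[uid][s : s + read_len])
        for p in rng.choice(read_len, int(rng.integers(0, 6)), replace=False):
            bases[p] = "ACGT"[int(rng.integers(0, 4))]
        if rng.random() < 0.5:
            bases = list(revcomp("".join(bases)))
        reads.append(_mkread(f"r{i}", "".join(bases)))
    assert_matches_oracle(ReadSet(reads), ref, cap, seed=seed)


class TestPileup:
    def test_single_perfect_read_concentrates_on_ref_base(self):
        ref = UnigeneReference([("u", "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT")])
        reads = ReadSet([_mkread("r", ref["u"][:20], q=25)])
        alns = align_readset(reads, ref, 3, seed=0)
        cols = build_pileup(alns, reads, ref)
        assert len(cols) == 20
        for col in cols:
            assert col.depth == 1
            assert col.base_counts[col.ref_base] == 1
            assert col.base_quals[col.ref_base] == 25

    def test_two_identical_reads_double_depth(self):
        ref = UnigeneReference([("u", "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT")])
        reads = ReadSet([_mkread("r1", ref["u"][:20]), _mkread("r2", ref["u"][:20])])
        alns = align_readset(reads, ref, 3, seed=0)
        cols = build_pileup(alns, reads, ref)
        assert all(c.depth == 2 for c in cols)

    def test_depth_conservation_equals_mapped_bases(self, tiny_truth):
        from homeocure.simdata import simulate_reads

        ref = tiny_truth.true_reference("A")
        reads = simulate_reads(tiny_truth, "A", depth_target=5, seed=9)
        alns = align_readset(reads, ref, 3, seed=1)
        cols = build_pileup(alns, reads, ref)
        assert sum(c.depth for c in cols) == 80 * alns.n_mapped_reads

    def test_reverse_strand_reads_contribute_complemented_bases(self):
        rng = np.random.default_rng(17)
        ref = _random_ref(rng, 1, 40, 40)
        reads = ReadSet([_mkread("r", revcomp(ref["u0"][:30]))])
        alns = align_readset(reads, ref, 3, seed=0)
        assert alns.records[0].strand == "-"
        cols = build_pileup(alns, reads, ref)
        for col in cols:
            assert col.base_counts[col.ref_base] == 1

    def test_majority_base_recovers_truth_under_1pct_error(self):
        from homeocure.simdata import simulate_diverged_pair, simulate_reads

        truth = simulate_diverged_pair(3, 500, 0.0, seed=13)
        ref = truth.true_reference("A")
        reads = simulate_reads(truth, "A", depth_target=30, error_rate=0.01, seed=14)
        alns = align_readset(reads, ref, 3, seed=3)
        cols = build_pileup(alns, reads, ref)
        deep = [c for c in cols if c.depth >= 10]
        agree = [
            max(c.base_counts, key=c.base_counts.get) == c.ref_base for c in deep
        ]
        assert np.mean(agree) >= 0.99


class TestConsensus:
    def _col(self, counts, quals, ref="T"):
        full_c = {b: counts.get(b, 0) for b in "ACGTN"}
        full_q = {b: quals.get(b, 0) for b in "ACGTN"}
        return PileupColumn("u", 0, ref, sum(full_c.values()), full_c, full_q)

    def test_confident_call_overrides_reference_base(self):
        col = self._col({"G": 5}, {"G": 150})
        call = call_consensus(col)
        assert call.called_base == "G"
        assert call.consensus_quality == 93  # capped
        assert call.supporting_depth == 5

    def test_depth_exactly_three_fails_strictly_greater_rule(self):
        col = self._col({"G": 3}, {"G": 120})
        assert call_consensus(col).called_base == "N"

    def test_summed_quality_exactly_forty_fails_strictly_greater_rule(self):
        col = self._col({"G": 4}, {"G": 40})
        assert call_consensus(col).called_base == "N"

    def test_competing_bases_reduce_consensus_quality(self):
        col = self._col({"G": 5, "A": 2}, {"G": 100, "A": 55})
        call = call_consensus(col)
        assert call.called_base == "G"
        assert call.consensus_quality == 45

    def test_quality_tie_gives_n(self):
        col = self._col({"G": 5, "A": 5}, {"G": 100, "A": 100})
        assert call_consensus(col).called_base == "N"
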