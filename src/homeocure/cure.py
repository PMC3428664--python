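"""Iterative reference curing toward a progenitor genome.

A consensus unigene set co-assembled from an allopolyploid mixes the two
parental (homoeologous) gene copies, so reads from either diploid
progenitor carry systematic mismatches against it and many fail the
aligner's mismatch cap. Curing rewrites the reference toward one progenitor
genome: the progenitor's 80-base reads are split into two 40-base halves
(halving the mismatch load per aligned unit), aligned to the current
reference, merged into a single pileup, and every position whose
high-confidence consensus base (depth > 3, consensus quality > 40)
disagrees with the reference is substituted. Because each round of
substitutions lets additional reads clear the mismatch cap in the next
round, the process is iterated — six cycles by default. Curing never
inserts or deletes, so unigene identifiers and lengths are preserved
exactly; running the procedure once per progenitor yields the A-genome and
C-genome cured references whose base-by-base differences are the
inter-homoeologue polymorphisms used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import align as _align
from .align import ReferenceIndex, align_codes, consensus_codes, encode_reads
from .seqio import Read, ReadSet, UnigeneReference

DEFAULT_N_CYCLES = 6
DEFAULT_SPLIT_LENGTH = 40


@dataclass
class CuringConfig:
    """Parameters of the curing loop.

    Defaults mirror the published procedure: six cycles, 40-base split
    reads, mismatch cap 3, and consensus thresholds of depth strictly
    greater than 3 with consensus quality strictly greater than 40.
    """

    n_cycles: int = DEFAULT_N_CYCLES
    max_mismatches: int = _align.DEFAULT_MAX_MISMATCHES
    min_depth_exclusive: int = _align.DEFAULT_MIN_DEPTH_EXCLUSIVE
    min_consensus_quality: int = _align.DEFAULT_MIN_CONSENSUS_QUALITY
    split_length: int = DEFAULT_SPLIT_LENGTH
    rng_seed: int = 0
    early_stop: bool = False  # stop as soon as a cycle changes zero bases

    def __post_init__(self):
        for name in (
            "n_cycles",
            "max_mismatches",
            "min_depth_exclusive",
            "min_consensus_quality",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.split_length < 1:
            raise ValueError("split_length must be >= 1")

    def cycle_seed(self, cycle: int, half: int = 0) -> int:
        # deterministic per-cycle reseeding keeps the whole run reproducible
        return (self.rng_seed * 1_000_003 + 101 * cycle + half) % (2**31)


@dataclass
class CureCycleStats:
    cycle_index: int  # 1-based
    n_reads_mapped: int
    n_bases_changed_this_cycle: int
    cumulative_bases_changed: int


@dataclass
class ChangeRecord:
    unigene_id: str
    pos: int  # 0-based
    old_base: str
    new_base: str
    cycle: int


@dataclass
class SplitResult:
    """The two half-read sets produced by :func:`split_reads`.

    Iterable as a (first, second) pair; ``n_dropped`` counts input reads too
    short to split.
    """

    first: ReadSet
    second: ReadSet
    n_dropped: int = 0

    def __iter__(self):
        return iter((self.first, self.second))


@dataclass
class CuredReferencePair:
    """A- and C-cured references with per-cycle statistics and change logs."""

    a_ref: UnigeneReference
    c_ref: UnigeneReference
    a_stats: list[CureCycleStats] = field(default_factory=list)
    c_stats: list[CureCycleStats] = field(default_factory=list)
    a_changes: list[ChangeRecord] = field(default_factory=list)
    c_changes: list[ChangeRecord] = field(default_factory=list)

    def concerted_changes(self) -> list[tuple[str, int, str]]:
        """Positions changed to the same base in both genome runs.

        Such concerted changes correct assembly artefacts shared by both
        progenitors and never become inter-homoeologue polymorphisms.
        """
        a = {(c.unigene_id, c.pos): c.new_base for c in self.a_changes}
        out = []
        for c in self.c_changes:
            key = (c.unigene_id, c.pos)
            if a.get(key) == c.new_base:
                out.append((c.unigene_id, c.pos, c.new_base))
        return out


def split_reads(reads: ReadSet, split_length: int = DEFAULT_SPLIT_LENGTH) -> SplitResult:
    """Split each read into a leading and a trailing ``split_length``-base read.

    The first output holds bases [0, split_length), the second
    [split_length, 2 * split_length), each with its own qualities. Reads
    shorter than twice the split length are dropped and counted.
    """
    first, second = [], []
    n_dropped = 0
    for r in reads:
        if len(r) < 2 * split_length:
            n_dropped += 1
            continue
        first.append(Read(r.id + "/1", r.bases[:split_length], r.quals[:split_length]))
        second.append(
            Read(
                r.id + "/2",
                r.bases[split_length : 2 * split_length],
                r.quals[split_length : 2 * split_length],
            )
        )
    mk = lambda lst: ReadSet(
        lst,
        sample=reads.sample,
        genome_tag=reads.genome_tag,
        nominal_length=split_length if not lst else None,
    )
    return SplitResult(mk(first), mk(second), n_dropped)


def _cure_cycle_codes(
    ref_index: ReferenceIndex,
    half_mats: list[tuple[np.ndarray, np.ndarray]],
    cfg: CuringConfig,
    cycle: int,
) -> tuple[np.ndarray, int, np.ndarray]:
    """One curing cycle on encoded data.

    Returns (new reference codes, merged mapped-read count, changed global
    positions). The two half-read alignments are merged into a single
    pileup before consensus, with qualities summed across both.
    """
    total = ref_index.total_length
    counts = np.zeros((5, total), dtype=np.int64)
    quals = np.zeros((5, total), dtype=np.int64)
    n_mapped = 0
    for half, (codes, qmat) in enumerate(half_mats):
        if codes.shape[0] == 0:
            continue
        res = align_codes(
            codes, ref_index, cfg.max_mismatches, cfg.cycle_seed(cycle, half)
        )
        mapped = res[:, 3] >= 0
        n_mapped += int(mapped.sum())
        if not mapped.any():
            continue
        L = codes.shape[1]
        sub = codes[mapped].copy()
        q = qmat[mapped].astype(np.int64)
        rev = res[mapped, 2].astype(bool)
        if rev.any():
            rc = sub[rev][:, ::-1]
            sub[rev] = np.where(rc < 4, 3 - rc, 4).astype(np.uint8)
            q[rev] = q[rev][:, ::-1]
        gstart = ref_index.bounds[res[mapped, 0]] + res[mapped, 1]
        pos = gstart[:, None] + np.arange(L)[None, :]
        flat = (sub.astype(np.int64) * total + pos).ravel()
        counts += np.bincount(flat, minlength=5 * total).reshape(5, -1)
        quals += np.bincount(
            flat, weights=q.ravel().astype(np.float64), minlength=5 * total
        ).astype(np.int64).reshape(5, -1)
    called, _cq = consensus_codes(
        counts, quals, cfg.min_depth_exclusive, cfg.min_consensus_quality
    )
    changed = np.nonzero((called != 4) & (called != ref_index.codes))[0]
    new_codes = ref_index.codes.copy()
    new_codes[changed] = called[changed]
    return new_codes, n_mapped, changed


def cure_cycle(
    ref: UnigeneReference,
    half_reads_1: ReadSet,
    half_reads_2: ReadSet,
    cfg: CuringConfig,
    cycle: int = 1,
) -> tuple[UnigeneReference, CureCycleStats]:
    """Run a single curing cycle against ``ref`` (public per-cycle entry point)."""
    index = ReferenceIndex(ref)
    mats = [encode_reads(half_reads_1.reads), encode_reads(half_reads_2.reads)]
    new_codes, n_mapped, changed = _cure_cycle_codes(index, mats, cfg, cycle)
    new_ref = _codes_to_reference(index, new_codes)
    stats = CureCycleStats(
        cycle_index=cycle,
        n_reads_mapped=n_mapped,
        n_bases_changed_this_cycle=len(changed),
        cumulative_bases_changed=len(changed),
    )
    return new_ref, stats


def _codes_to_reference(index: ReferenceIndex, codes: np.ndarray) -> UnigeneReference:
    ref = UnigeneReference()
    for u, name in enumerate(index.ids):
        lo, hi = index.bounds[u], index.bounds[u + 1]
        ref.add(name, _align.decode_sequence(codes[lo:hi]))
    return ref


def cure_reference(
    naive: UnigeneReference,
    progenitor_reads: ReadSet,
    cfg: CuringConfig | None = None,
) -> tuple[UnigeneReference, list[CureCycleStats], list[ChangeRecord]]:
    """Cure the naive reference toward one progenitor genome.

    Splits the progenitor reads once, then runs ``cfg.n_cycles`` curing
    cycles, re-aligning the halves to the evolving reference each time.
    Positions never reaching the consensus thresholds keep their naive base.
    """
    cfg = cfg or CuringConfig()
    halves = split_reads(progenitor_reads, cfg.split_length)
    mats = [encode_reads(halves.first.reads), encode_reads(halves.second.reads)]
    index = ReferenceIndex(naive)
    codes = index.codes.copy()
    stats: list[CureCycleStats] = []
    changes: list[ChangeRecord] = []
    cumulative = 0
    for cycle in range(1, cfg.n_cycles + 1):
        cyc_index = ReferenceIndex.__new__(ReferenceIndex)
        cyc_index.ids = index.ids
        cyc_index.bounds = index.bounds
        cyc_index.codes = codes
        cyc_index.total_length = index.total_length
        cyc_index._kmer_cache = {}
        new_codes, n_mapped, changed = _cure_cycle_codes(cyc_index, mats, cfg, cycle)
        for g in changed:
            u = index.unigene_of(int(g))
            changes.append(
                ChangeRecord(
                    unigene_id=index.ids[u],
                    pos=int(g - index.bounds[u]),
                    old_base="ACGTN"[codes[g]],
                    new_base="ACGTN"[new_codes[g]],
                    cycle=cycle,
                )
            )
        cumulative += len(changed)
        stats.append(
            CureCycleStats(
                cycle_index=cycle,
                n_reads_mapped=n_mapped,
                n_bases_changed_this_cycle=len(changed),
                cumulative_bases_changed=cumulative,
            )
        )
        codes = new_codes
        if cfg.early_stop and len(changed) == 0:
            break
    cured = _codes_to_reference(index, codes)
    return cured, stats, changes


def build_cured_pair(
    naive: UnigeneReference,
    a_progenitor_reads: ReadSet,
    c_progenitor_reads: ReadSet,
    cfg: CuringConfig | None = None,
) -> CuredReferencePair:
    """Two independent curing runs from the same naive reference."""
    cfg = cfg or CuringConfig()
    a_ref, a_stats, a_changes = cure_reference(naive, a_progenitor_reads, cfg)
    c_ref, c_stats, c_changes = cure_reference(naive, c_progenitor_reads, cfg)
    return CuredReferencePair(
        a_ref=a_ref,
        c_ref=c_ref,
        a_stats=a_stats,
        c_stats=c_stats,
        a_changes=a_changes,
        c_changes=c_changes,
    )


def write_cycle_stats_tsv(path, a_stats, c_stats) -> None:
    with open(path, "w") as fh:
        fh.write("genome\tcycle\treads_mapped\tbases_changed\tcumulative_changed\n")
        for tag, stats in (("A", a_stats), ("C", c_stats)):
            for s in stats:
                fh.write(
                    f"{tag}\t{s.cycle_index}\t{s.n_reads_mapped}\t"
                    f"{s.n_bases_changed_this_cycle}\t{s.cumulative_bases_changed}\n"
                )


def write_change_log_tsv(path, a_changes, c_changes) -> None:
    # positions are 1-based in files, 0-based in memory
    with open(path, "w") as fh:
        fh.write("genome\tunigene\tpos\told\tnew\tcycle\n")
        for tag, changes in (("A", a_changes), ("C", c_changes)):
            for c in changes:
                fh.write(
                    f"{tag}\t{c.unigene_id}\t{c.pos + 1}\t{c.old_base}\t"
                    f"{c.new_base}\t{c.cycle}\n"
                )
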