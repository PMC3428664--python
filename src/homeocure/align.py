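"""Ungapped best-hit short-read alignment, pileups, and consensus calling.

This is the pipeline's internal aligner. Each read is placed, fully
contained and without gaps, at the position (on either strand, over all
unigenes) with the fewest base mismatches, subject to a mismatch cap
(default 3). When several placements are equally good, one is chosen
uniformly at random and flagged, which distributes reads evenly between
identical sequence tracts — the behaviour the downstream homoeologue
apportioning relies on.

The search uses pigeonhole seeding: a read of length L with at most m
mismatches must contain an exact window of length L // (m + 1), so exact
k-mer lookups against an index of the reference enumerate every placement
within the cap. Candidate verification and tie-breaking run in a numba
kernel. N in either read or reference always counts as a mismatch, and
reference windows containing N are simply absent from the k-mer index
(any placement whose only exact seed would cross an N has, by the same
pigeonhole argument, more than m mismatches).

Consensus calling follows the curing rule: the winning base at a column is
the one with the highest summed Phred quality; the consensus quality is
that sum minus the summed quality of all other non-N bases (floored at 0,
capped at 93); a base is called only with read depth strictly greater than
3 and consensus quality strictly greater than 40 — otherwise the call is N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from numba import njit

from .seqio import PHRED_MAX, Read, ReadSet, UnigeneReference

DEFAULT_MAX_MISMATCHES = 3
DEFAULT_MIN_DEPTH_EXCLUSIVE = 3
DEFAULT_MIN_CONSENSUS_QUALITY = 40

_MAX_SEED_LEN = 31  # 4^31 < 2^63: seed codes stay exact in int64/uint64

# base encoding: A=0 C=1 G=2 T=3 N=4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def encode_reads(reads: list[Read]) -> tuple[np.ndarray, np.ndarray]:
    """Stack same-length reads into (bases, quals) matrices of shape (n, L)."""
    if not reads:
        return np.empty((0, 0), np.uint8), np.empty((0, 0), np.int16)
    joined = "".join(r.bases for r in reads)
    codes = encode_sequence(joined).reshape(len(reads), -1)
    quals = np.empty_like(codes, dtype=np.int16)
    for i, r in enumerate(reads):
        quals[i] = r.quals
    return codes, quals


class ReferenceIndex:
    """Concatenated, encoded reference with cached k-mer indexes.

    Unigenes are laid end to end; placements are only ever accepted when
    fully contained within one unigene, so no separators are needed.
    """

    def __init__(self, ref: UnigeneReference):
        self.ids = ref.ids
        seqs = [ref[u] for u in self.ids]
        lengths = np.array([len(s) for s in seqs], dtype=np.int64)
        self.bounds = np.concatenate([[0], np.cumsum(lengths)])
        self.codes = (
            encode_sequence("".join(seqs)) if seqs else np.empty(0, np.uint8)
        )
        self.total_length = int(self.bounds[-1])
        self._kmer_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def kmer_index(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """(sorted k-mer codes, their positions) over all N-free windows."""
        if k in self._kmer_cache:
            return self._kmer_cache[k]
        arr = self.codes
        n_win = arr.size - k + 1
        if n_win <= 0:
            out = (np.empty(0, np.uint64), np.empty(0, np.int64))
            self._kmer_cache[k] = out
            return out
        is_n = (arr == 4).astype(np.int64)
        cum = np.concatenate([[0], np.cumsum(is_n)])
        has_n = (cum[k:] - cum[:-k]) > 0
        a4 = np.where(arr == 4, 0, arr).astype(np.uint64)
        code = np.zeros(n_win, dtype=np.uint64)
        for j in range(k):
            code = code * np.uint64(4) + a4[j : j + n_win]
        pos = np.nonzero(~has_n)[0].astype(np.int64)
        valid = code[~has_n]
        order = np.argsort(valid, kind="stable")
        out = (valid[order], pos[order])
        self._kmer_cache[k] = out
        return out

    def unigene_of(self, gpos: int) -> int:
        return int(np.searchsorted(self.bounds, gpos, side="right") - 1)


@dataclass
class AlignmentRecord:
    """One read's single best placement on the reference."""

    read_id: str
    unigene_id: str
    start: int  # 0-based offset on the unigene
    strand: str  # "+" or "-"
    mismatches: int
    tie_broken: bool = False


@dataclass
class AlignmentSet:
    """Best single placements for the mapped subset of an input read set.

    Stored columnar for speed; ``records`` materialises the per-read view.
    ``read_idx`` indexes into the read set the alignment was computed from.
    """

    ref_ids: list[str]
    read_ids: list[str]
    read_idx: np.ndarray  # into the source ReadSet
    uni_idx: np.ndarray
    start: np.ndarray  # 0-based on the unigene
    strand_rev: np.ndarray  # bool, True = reverse strand
    mismatches: np.ndarray
    tie_broken: np.ndarray
    n_input_reads: int
    rng_seed: int
    read_length: np.ndarray = field(default=None)

    @property
    def n_mapped_reads(self) -> int:
        return len(self.read_ids)

    @cached_property
    def records(self) -> list[AlignmentRecord]:
        return [
            AlignmentRecord(
                self.read_ids[i],
                self.ref_ids[self.uni_idx[i]],
                int(self.start[i]),
                "-" if self.strand_rev[i] else "+",
                int(self.mismatches[i]),
                bool(self.tie_broken[i]),
            )
            for i in range(self.n_mapped_reads)
        ]


@dataclass
class PileupColumn:
    """Per-position tally of aligned read bases and summed qualities."""

    unigene_id: str
    pos: int  # 0-based
    ref_base: str
    depth: int
    base_counts: dict[str, int]
    base_quals: dict[str, int]


@dataclass
class ConsensusCall:
    unigene_id: str
    pos: int
    called_base: str  # N means the call failed the thresholds
    supporting_depth: int
    consensus_quality: int


@njit(cache=False)
def _align_kernel(
    read_codes, ref_codes, bounds, sorted_codes, sorted_pos, k, max_mm, seed
):  # pragma: no cover - exercised via align_readset
    np.random.seed(seed)
    n, L = read_codes.shape
    out = np.full((n, 5), -1, dtype=np.int64)  # uni, start, rev, mm, tie
    n_windows = L // k
    fwd = np.empty(L, np.uint8)
    rev = np.empty(L, np.uint8)
    for i in range(n):
        for j in range(L):
            fwd[j] = read_codes[i, j]
            b = read_codes[i, L - 1 - j]
            rev[j] = 3 - b if b < 4 else 4
        best_mm = max_mm + 1
        best_g = np.int64(-1)
        best_u = np.int64(-1)
        best_rev = 0
        n_ties = 0
        for strand in range(2):
            rc = fwd if strand == 0 else rev
            total = 0
            for w in range(n_windows):
                off = w * k
                code = np.uint64(0)
                valid = True
                for j in range(k):
                    b = rc[off + j]
                    if b >= 4:
                        valid = False
                        break
                    code = code * np.uint64(4) + np.uint64(b)
                if not valid:
                    continue
                lo = np.searchsorted(sorted_codes, code, side="left")
                hi = np.searchsorted(sorted_codes, code, side="right")
                total += hi - lo
            if total == 0:
                continue
            cand = np.empty(total, np.int64)
            p = 0
            for w in range(n_windows):
                off = w * k
                code = np.uint64(0)
                valid = True
                for j in range(k):
                    b = rc[off + j]
                    if b >= 4:
                        valid = False
                        break
                    code = code * np.uint64(4) + np.uint64(b)
                if not valid:
                    continue
                lo = np.searchsorted(sorted_codes, code, side="left")
                hi = np.searchsorted(sorted_codes, code, side="right")
                for t in range(lo, hi):
                    cand[p] = sorted_pos[t] - off
                    p += 1
            cand = np.sort(cand[:p])
            prev = np.int64(-1) - np.int64(1)
            for t in range(p):
                g = cand[t]
                if g == prev or g < 0:
                    continue
                prev = g
                u = np.searchsorted(bounds, g, side="right") - 1
                if g + L > bounds[u + 1]:
                    continue
                mm = 0
                limit = best_mm  # mm > best_mm can neither win nor tie
                ok = True
                for j in range(L):
                    a = rc[j]
                    b = ref_codes[g + j]
                    if a != b or a >= 4:
                        mm += 1
                        if mm > limit:
                            ok = False
                            break
                if not ok:
                    continue
                if mm < best_mm:
                    best_mm = mm
                    best_g = g
                    best_u = u
                    best_rev = strand
                    n_ties = 1
                elif mm == best_mm:
                    n_ties += 1
                    if np.random.random() < 1.0 / n_ties:
                        best_g = g
                        best_u = u
                        best_rev = strand
        if best_mm <= max_mm:
            out[i, 0] = best_u
            out[i, 1] = best_g - bounds[best_u]
            out[i, 2] = best_rev
            out[i, 3] = best_mm
            out[i, 4] = 1 if n_ties > 1 else 0
    return out


def _seed_length(read_length: int, max_mismatches: int) -> int:
    k = read_length // (max_mismatches + 1)
    return max(1, min(k, _MAX_SEED_LEN))


def align_codes(
    read_codes: np.ndarray,
    index: ReferenceIndex,
    max_mismatches: int,
    seed: int,
) -> np.ndarray:
    """Align an (n, L) matrix of encoded reads; returns the raw kernel output.

    Columns: unigene index, start, reverse-strand flag, mismatches,
    tie-broken flag; all -1 / unset for unmapped reads.
    """
    n, L = read_codes.shape
    if n == 0 or index.total_length == 0:
        return np.full((n, 5), -1, dtype=np.int64)
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    if max_mismatches >= L:
        raise ValueError("max_mismatches must be smaller than the read length")
    k = _seed_length(L, max_mismatches)
    sorted_codes, sorted_pos = index.kmer_index(k)
    return _align_kernel(
        np.ascontiguousarray(read_codes, dtype=np.uint8),
        index.codes,
        index.bounds,
        sorted_codes,
        sorted_pos,
        k,
        max_mismatches,
        int(seed) % (2**31),
    )


def align_readset(
    reads: ReadSet,
    ref: UnigeneReference | ReferenceIndex,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    seed: int = 0,
) -> AlignmentSet:
    """Best-hit align every read in a set; deterministic given ``seed``.

    Unmapped reads (best placement exceeding the cap, or none at all) are
    simply absent from the result; ``n_input_reads`` keeps the accounting.
    """
    index = ref if isinstance(ref, ReferenceIndex) else ReferenceIndex(ref)
    groups: dict[int, list[int]] = {}
    for i, r in enumerate(reads):
        groups.setdefault(len(r), []).append(i)
    idx_parts, out_parts, len_parts = [], [], []
    for sub, (L, members) in enumerate(sorted(groups.items())):
        if L == 0:
            continue
        sub_reads = [reads.reads[i] for i in members]
        codes, _ = encode_reads(sub_reads)
        res = align_codes(codes, index, max_mismatches, seed + 7919 * sub)
        mapped = res[:, 3] >= 0
        idx_parts.append(np.asarray(members, dtype=np.int64)[mapped])
        out_parts.append(res[mapped])
        len_parts.append(np.full(int(mapped.sum()), L, dtype=np.int64))
    if idx_parts:
        read_idx = np.concatenate(idx_parts)
        out = np.concatenate(out_parts)
        rlen = np.concatenate(len_parts)
        order = np.argsort(read_idx, kind="stable")
        read_idx, out, rlen = read_idx[order], out[order], rlen[order]
    else:
        read_idx = np.empty(0, np.int64)
        out = np.empty((0, 5), np.int64)
        rlen = np.empty(0, np.int64)
    return AlignmentSet(
        ref_ids=index.ids,
        read_ids=[reads.reads[i].id for i in read_idx],
        read_idx=read_idx,
        uni_idx=out[:, 0].copy(),
        start=out[:, 1].copy(),
        strand_rev=out[:, 2].astype(bool),
        mismatches=out[:, 3].copy(),
        tie_broken=out[:, 4].astype(bool),
        n_input_reads=len(reads),
        rng_seed=seed,
        read_length=rlen,
    )


def align_read(
    read: Read,
    ref: UnigeneReference | ReferenceIndex,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    rng: np.random.Generator | None = None,
) -> AlignmentRecord | None:
    """Align a single read; returns None when unmapped."""
    rng = rng if rng is not None else np.random.default_rng(0)
    seed = int(rng.integers(0, 2**31))
    alns = align_readset(
        ReadSet([read]), ref, max_mismatches=max_mismatches, seed=seed
    )
    return alns.records[0] if alns.n_mapped_reads else None


# ---------------------------------------------------------------------------
# Pileups

def pileup_arrays(
    alns: AlignmentSet, reads: ReadSet, index: ReferenceIndex
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate base counts and summed Phred qualities over the reference.

    Returns (counts, quals), each of shape (5, total reference length) in
    base-code order A, C, G, T, N. Reverse-strand reads contribute their
    reverse complement at the correct reference positions.
    """
    counts = np.zeros((5, index.total_length), dtype=np.int64)
    quals = np.zeros((5, index.total_length), dtype=np.int64)
    if alns.n_mapped_reads == 0:
        return counts, quals
    by_len: dict[int, list[int]] = {}
    for j in range(alns.n_mapped_reads):
        by_len.setdefault(int(alns.read_length[j]), []).append(j)
    for L, members in by_len.items():
        members = np.asarray(members, dtype=np.int64)
        sub = [reads.reads[i] for i in alns.read_idx[members]]
        codes, q = encode_reads(sub)
        q = q.astype(np.int64)
        rev = alns.strand_rev[members]
        if rev.any():
            rc = codes[rev][:, ::-1]
            rc = np.where(rc < 4, 3 - rc, 4).astype(np.uint8)
            codes[rev] = rc
            q[rev] = q[rev][:, ::-1]
        gstart = index.bounds[alns.uni_idx[members]] + alns.start[members]
        if np.any(gstart < 0) or np.any(gstart + L > index.total_length):
            raise ValueError("alignment record extends beyond the reference")
        ends = index.bounds[alns.uni_idx[members] + 1]
        if np.any(alns.start[members] + L > ends - index.bounds[alns.uni_idx[members]]):
            raise ValueError("alignment record extends beyond its unigene")
        pos = gstart[:, None] + np.arange(L)[None, :]
        flat = codes.astype(np.int64) * index.total_length + pos
        flat = flat.ravel()
        counts += np.bincount(
            flat, minlength=5 * index.total_length
        ).reshape(5, -1)
        quals += np.bincount(
            flat, weights=q.ravel().astype(np.float64),
            minlength=5 * index.total_length,
        ).astype(np.int64).reshape(5, -1)
    return counts, quals


def build_pileup(
    alns: AlignmentSet, reads: ReadSet, ref: UnigeneReference | ReferenceIndex
) -> list[PileupColumn]:
    """Materialise pileup columns for every covered reference position."""
    index = ref if isinstance(ref, ReferenceIndex) else ReferenceIndex(ref)
    counts, quals = pileup_arrays(alns, reads, index)
    depth = counts.sum(axis=0)
    covered = np.nonzero(depth > 0)[0]
    cols = []
    for g in covered:
        u = index.unigene_of(int(g))
        cols.append(
            PileupColumn(
                unigene_id=index.ids[u],
                pos=int(g - index.bounds[u]),
                ref_base="ACGTN"[index.codes[g]],
                depth=int(depth[g]),
                base_counts={b: int(counts[i, g]) for i, b in enumerate("ACGTN")},
                base_quals={b: int(quals[i, g]) for i, b in enumerate("ACGTN")},
            )
        )
    return cols


# ---------------------------------------------------------------------------
# Consensus

def consensus_codes(
    counts: np.ndarray,
    quals: np.ndarray,
    min_depth_exclusive: int = DEFAULT_MIN_DEPTH_EXCLUSIVE,
    min_consensus_quality: int = DEFAULT_MIN_CONSENSUS_QUALITY,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised consensus over pileup arrays.

    Returns (called base codes, consensus qualities); code 4 (N) marks a
    failed call. The winner is the base with the highest summed quality
    (ties, or N winning, give N); its consensus quality is the winner's
    summed quality minus that of all other non-N bases, floored at 0 and
    capped at 93; the call stands only with depth > ``min_depth_exclusive``
    and consensus quality > ``min_consensus_quality``.
    """
    q = quals.astype(np.int64)
    best = np.argmax(q, axis=0)  # ties resolve to the lowest code...
    top = np.take_along_axis(q, best[None, :], axis=0)[0]
    n_top = (q == top[None, :]).sum(axis=0)
    tied = n_top > 1
    nonn_total = q[:4].sum(axis=0)
    other = np.where(best < 4, nonn_total - top, nonn_total)
    cq = np.clip(top - other, 0, PHRED_MAX)
    depth_best = np.take_along_axis(counts, best[None, :], axis=0)[0]
    called = best.copy()
    fail = (
        tied
        | (best == 4)
        | (depth_best <= min_depth_exclusive)
        | (cq <= min_consensus_quality)
    )
    called[fail] = 4
    return called.astype(np.uint8), cq


def call_consensus(
    col: PileupColumn,
    min_depth_exclusive: int = DEFAULT_MIN_DEPTH_EXCLUSIVE,
    min_consensus_quality: int = DEFAULT_MIN_CONSENSUS_QUALITY,
) -> ConsensusCall:
    """Consensus call for a single pileup column (see :func:`consensus_codes`)."""
    counts = np.array([[col.base_counts[b]] for b in "ACGTN"], dtype=np.int64)
    quals = np.array([[col.base_quals[b]] for b in "ACGTN"], dtype=np.int64)
    called, cq = consensus_codes(
        counts, quals, min_depth_exclusive, min_consensus_quality
    )
    base = "ACGTN"[called[0]]
    return ConsensusCall(
        unigene_id=col.unigene_id,
        pos=col.pos,
        called_base=base,
        supporting_depth=col.base_counts.get(base, 0) if base != "N" else col.depth,
        consensus_quality=int(cq[0]),
    )


# ---------------------------------------------------------------------------
# Export

def write_sam(
    alns: AlignmentSet, reads: ReadSet, ref: UnigeneReference, path
) -> None:
    """Minimal single-end SAM export with NM mismatch tags."""
    lengths = ref.lengths()
    read_by_id = {r.id: r for r in reads}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name in ref.ids:
            fh.write(f"@SQ\tSN:{name}\tLN:{lengths[name]}\n")
        for rec in alns.records:
            r = read_by_id[rec.read_id]
            flag = 16 if rec.strand == "-" else 0
            if rec.strand == "-":
                seq = decode_sequence(
                    np.where(
                        encode_sequence(r.bases)[::-1] < 4,
                        3 - encode_sequence(r.bases)[::-1],
                        4,
                    )
                )
                qual = (r.quals[::-1] + 33).astype(np.uint8).tobytes().decode()
            else:
                seq = r.bases
                qual = (r.quals + 33).astype(np.uint8).tobytes().decode()
            fh.write(
                f"{rec.read_id}\t{flag}\t{rec.unigene_id}\t{rec.start + 1}\t255\t"
                f"{len(r)}M\t*\t0\t0\t{seq}\t{qual}\tNM:i:{rec.mismatches}\n"
            )


def write_pileup_tsv(cols: list[PileupColumn], path) -> None:
    """Pileup export: unigene, 1-based pos, ref, depth, per-base counts, quals."""
    with open(path, "w") as fh:
        fh.write(
            "unigene\tpos\tref\tdepth\tA\tC\tG\tT\tN\t"
            "qA\tqC\tqG\tqT\tqN\n"
        )
        for c in cols:
            counts = "\t".join(str(c.base_counts[b]) for b in "ACGTN")
            quals = "\t".join(str(c.base_quals[b]) for b in "ACGTN")
            fh.write(
                f"{c.unigene_id}\t{c.pos + 1}\t{c.ref_base}\t{c.depth}\t"
                f"{counts}\t{quals}\n"
            )
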