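"""Homoeologue-resolved quantification against the combined cured reference.

The two cured references are concatenated into one combined reference
holding an "_A" and a "_C" version of every unigene. Polyploid reads are
aligned to it with the usual best-hit rules; reads that match both versions
equally (no informative IHP in the covered window) are assigned uniformly
at random by the aligner, so identical tracts split ~50:50 while reads
spanning IHPs sort to their genome of origin. Counts per version are
normalised to RPKM (reads per kilobase of unigene per million aligned reads
in the sample), and qualitative expressed/non-expressed calls follow the
all-replicates rule: expressed iff every replicate has at least one read,
non-expressed iff every replicate has zero, inconsistent otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AlignmentSet, ReferenceIndex, align_readset
from .cure import CuredReferencePair
from .seqio import ReadSet, UnigeneReference

VERSION_SUFFIXES = ("_A", "_C")


@dataclass
class CombinedReference:
    """Reference holding the A and C variants of every unigene.

    Version identifiers are ``<unigene>_A`` and ``<unigene>_C``; the two
    variants of a pair have equal lengths.
    """

    reference: UnigeneReference
    base_ids: list[str]

    @classmethod
    def from_pair(cls, pair: CuredReferencePair) -> "CombinedReference":
        combined = UnigeneReference()
        base_ids = []
        if pair.a_ref.ids != pair.c_ref.ids:
            raise ValueError("cured pair has mismatched unigene identifiers")
        for name in pair.a_ref.ids:
            if len(pair.a_ref[name]) != len(pair.c_ref[name]):
                raise ValueError(f"unigene {name!r}: cured lengths differ")
            combined.add(name + "_A", pair.a_ref[name])
            combined.add(name + "_C", pair.c_ref[name])
            base_ids.append(name)
        return cls(reference=combined, base_ids=base_ids)

    @staticmethod
    def split_version_id(version_id: str) -> tuple[str, str]:
        """(base unigene id, genome) from a suffixed version id."""
        for suffix in VERSION_SUFFIXES:
            if version_id.endswith(suffix):
                return version_id[: -len(suffix)], suffix[-1]
        raise ValueError(f"{version_id!r} lacks an _A/_C version suffix")

    @property
    def version_ids(self) -> list[str]:
        return self.reference.ids

    def __len__(self) -> int:
        return len(self.reference)


def build_combined_reference(pair: CuredReferencePair) -> CombinedReference:
    """Combine the A- and C-cured references (2N entries for N unigenes)."""
    return CombinedReference.from_pair(pair)


def count_by_version(alns: AlignmentSet, combined: CombinedReference) -> pd.Series:
    """Mapped-read counts per genome version (zeros included).

    Each mapped read increments exactly one version, so per unigene pair
    count(u_A) + count(u_C) equals the reads mapped to that pair.
    """
    if alns.ref_ids != combined.version_ids:
        missing = set(alns.ref_ids) - set(combined.version_ids)
        if missing:
            raise ValueError(
                f"alignments refer to unknown versions: {sorted(missing)[:5]}"
            )
        raise ValueError(
            "alignments were not made against this combined reference"
        )
    values = np.zeros(len(combined.version_ids), dtype=np.int64)
    if alns.n_mapped_reads:
        idx, n = np.unique(alns.uni_idx, return_counts=True)
        values[idx] = n
    return pd.Series(
        values, index=pd.Index(combined.version_ids, name="version")
    )


def rpkm(count: int, length_bases: int, total_mapped: int) -> float:
    """Reads per kilobase of sequence per million aligned reads."""
    if length_bases <= 0:
        raise ValueError("length_bases must be positive")
    if total_mapped == 0:
        if count == 0:
            return 0.0
        raise ValueError("total_mapped is zero but count is positive")
    return count * 1e9 / (length_bases * total_mapped)


@dataclass
class CountMatrix:
    """Per-version read counts and RPKM across samples.

    ``counts`` and ``rpkm`` are DataFrames with genome-version rows and
    sample columns; ``total_mapped`` holds each sample's aligned-read total
    (the RPKM denominator, counted over the whole combined reference).
    """

    counts: pd.DataFrame
    rpkm: pd.DataFrame
    total_mapped: pd.Series
    lengths: pd.Series = field(default=None)

    def by_base_unigene(self) -> pd.DataFrame:
        """Counts summed over the A and C versions of each unigene."""
        base = [CombinedReference.split_version_id(v)[0] for v in self.counts.index]
        return self.counts.groupby(pd.Index(base, name="unigene"), sort=False).sum()

    def version_pair(self, unigene: str) -> pd.DataFrame:
        return self.counts.loc[[unigene + "_A", unigene + "_C"]]


def quantify_samples(
    combined: CombinedReference,
    samples: list[ReadSet],
    max_mismatches: int = 3,
    seed: int = 0,
) -> tuple[CountMatrix, list[AlignmentSet]]:
    """Align each sample to the combined reference and tabulate counts/RPKM."""
    index = ReferenceIndex(combined.reference)
    lengths = pd.Series(combined.reference.lengths())
    counts = {}
    totals = {}
    all_alns = []
    for j, sample in enumerate(samples):
        name = sample.sample or f"sample{j + 1}"
        alns = align_readset(sample, index, max_mismatches=max_mismatches,
                             seed=seed + 104729 * (j + 1))
        all_alns.append(alns)
        counts[name] = count_by_version(alns, combined)
        totals[name] = alns.n_mapped_reads
    count_df = pd.DataFrame(counts)
    total = pd.Series(totals)
    rpkm_df = count_df * 1e9
    rpkm_df = rpkm_df.div(lengths.reindex(count_df.index), axis=0)
    # samples with zero mapped reads have all-zero counts; their RPKM is 0
    safe_total = total.replace(0, 1)
    rpkm_df = rpkm_df.div(safe_total, axis=1)
    return CountMatrix(counts=count_df, rpkm=rpkm_df, total_mapped=total,
                       lengths=lengths), all_alns


def call_expression(counts_per_replicate) -> str:
    """Qualitative call over replicates: all > 0 → expressed; all == 0 →
    non_expressed; anything else → inconsistent."""
    counts = list(counts_per_replicate)
    if not counts:
        raise ValueError("at least one replicate count is required")
    if min(counts) > 0:
        return "expressed"
    if max(counts) == 0:
        return "non_expressed"
    return "inconsistent"


def expression_calls(counts: pd.DataFrame) -> pd.Series:
    """Row-wise expression calls over a counts matrix (columns = replicates)."""
    return pd.Series(
        {u: call_expression(row.values) for u, row in counts.iterrows()},
        name="call",
    )


def a_fraction(counts: pd.DataFrame, combined: CombinedReference) -> pd.Series:
    """Per-unigene fraction of pair reads assigned to the A version.

    Computed on counts summed over samples; unigene pairs with zero reads
    are NaN.
    """
    total = counts.sum(axis=1)
    out = {}
    for u in combined.base_ids:
        a = float(total.get(u + "_A", 0))
        c = float(total.get(u + "_C", 0))
        out[u] = a / (a + c) if a + c > 0 else np.nan
    return pd.Series(out, name="a_fraction")


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "version") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)
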