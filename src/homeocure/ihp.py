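"""Inter-homoeologue polymorphism (IHP) calling and summary statistics.

An IHP is a position at which the A-cured and C-cured versions of a unigene
carry different, unambiguous bases. Positions where either version is N
(no confident consensus was reached during curing) are silently
non-comparable. IHP density is reported per kilobase of full unigene
length, and the mean density is taken over the unigenes that contain at
least one IHP.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .align import encode_sequence
from .seqio import UnigeneReference


@dataclass
class IHP:
    unigene_id: str
    pos: int  # 0-based
    base_a: str
    base_c: str


@dataclass
class IHPSummary:
    n_unigenes_with_ihps: int
    total_ihps: int
    mean_density_per_kb: float  # over unigenes with >= 1 IHP
    max_density_per_kb: float
    count_histogram: dict[int, int]  # IHPs-per-unigene -> number of unigenes


@dataclass
class IHPTable:
    """IHPs with per-unigene counts and densities (IHPs per kb).

    Unigenes without IHPs are absent from the per-unigene maps but their
    lengths are retained so summaries know the full universe.
    """

    records: list[IHP]
    unigene_lengths: dict[str, int]
    per_unigene_counts: dict[str, int] = field(default_factory=dict)
    per_unigene_density: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.per_unigene_counts:
            for r in self.records:
                self.per_unigene_counts[r.unigene_id] = (
                    self.per_unigene_counts.get(r.unigene_id, 0) + 1
                )
        if not self.per_unigene_density:
            self.per_unigene_density = {
                u: n * 1000.0 / self.unigene_lengths[u]
                for u, n in self.per_unigene_counts.items()
            }

    def positions(self, unigene_id: str) -> list[int]:
        return [r.pos for r in self.records if r.unigene_id == unigene_id]

    def unigenes_with_min_ihps(self, n: int) -> set[str]:
        return {u for u, c in self.per_unigene_counts.items() if c >= n}


def compare_references(a_ref: UnigeneReference, c_ref: UnigeneReference) -> IHPTable:
    """Base-by-base comparison of the two cured references.

    Both references must contain the same unigene identifiers with equal
    per-unigene lengths (curing only substitutes). Yields one IHP per
    position where the bases differ and neither is N.
    """
    if a_ref.ids != c_ref.ids:
        raise ValueError("references contain different unigene identifiers")
    records: list[IHP] = []
    lengths: dict[str, int] = {}
    for name in a_ref.ids:
        sa, sc = a_ref[name], c_ref[name]
        if len(sa) != len(sc):
            raise ValueError(f"unigene {name!r}: lengths differ between references")
        lengths[name] = len(sa)
        ca, cc = encode_sequence(sa), encode_sequence(sc)
        diff = np.nonzero((ca != cc) & (ca != 4) & (cc != 4))[0]
        for p in diff:
            records.append(IHP(name, int(p), sa[p], sc[p]))
    return IHPTable(records=records, unigene_lengths=lengths)


def ihp_summary(table: IHPTable) -> IHPSummary:
    """Summary statistics; mean density is over unigenes with >= 1 IHP."""
    counts = table.per_unigene_counts
    if not counts:
        return IHPSummary(0, 0, 0.0, 0.0, {})
    densities = list(table.per_unigene_density.values())
    hist: dict[int, int] = {}
    for c in counts.values():
        hist[c] = hist.get(c, 0) + 1
    return IHPSummary(
        n_unigenes_with_ihps=len(counts),
        total_ihps=len(table.records),
        mean_density_per_kb=float(np.mean(densities)),
        max_density_per_kb=float(np.max(densities)),
        count_histogram=dict(sorted(hist.items())),
    )


def write_ihp_tsv(table: IHPTable, path) -> None:
    # positions are 1-based in files
    with open(path, "w") as fh:
        fh.write("unigene\tpos\tA_base\tC_base\n")
        for r in table.records:
            fh.write(f"{r.unigene_id}\t{r.pos + 1}\t{r.base_a}\t{r.base_c}\n")


def write_ihp_summary_json(summary: IHPSummary, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "n_unigenes_with_ihps": summary.n_unigenes_with_ihps,
                "total_ihps": summary.total_ihps,
                "mean_density_per_kb": summary.mean_density_per_kb,
                "max_density_per_kb": summary.max_density_per_kb,
                "count_histogram": {
                    str(k): v for k, v in summary.count_histogram.items()
                },
            },
            fh,
            indent=2,
        )
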