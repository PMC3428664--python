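"""Synthetic allopolyploid transcriptome fixtures with known ground truth.

The generator emulates the data the pipeline is built for: a set of
ancestral unigene sequences standing in for the consensus (naive)
reference; A- and C-genome homoeologues derived from them by independent
per-site substitution at ~3% total divergence (each divergent site mutated
in exactly one genome, so the ancestral base always matches the other);
fixed-length 80-base single-end reads with per-base Phred qualities
(flat Q30 with a decaying tail after base 60) and uniform substitution
errors; and polyploid samples in four biological replicates whose
per-unigene A:C read mix follows planted expression levels, with
gamma-Poisson replicate noise calibrated to a target quasi-Poisson
dispersion Phi.

Everything is substitution-only (no indels), matching the ungapped
alignment scope, and every generator takes an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import decode_sequence, encode_sequence
from .seqio import Read, ReadSet, UnigeneReference

DEFAULT_N_UNIGENES = 200
DEFAULT_UNIGENE_LENGTH = 1000
DEFAULT_DIVERGENCE = 0.03
DEFAULT_DEPTH = 30
DEFAULT_READ_LENGTH = 80
DEFAULT_ERROR_RATE = 0.01
DEFAULT_N_REPLICATES = 4
DEFAULT_PHI = 3.0


@dataclass
class SimulationTruth:
    """Planted ground truth for one simulated unigene universe."""

    ids: list[str]
    ancestral: list[str]
    a_seqs: list[str]
    c_seqs: list[str]
    # per unigene: list of (pos, a_base, c_base) at planted divergent sites
    divergent: dict[str, list[tuple[int, str, str]]]
    a_levels: np.ndarray  # per-unigene A expression level
    c_levels: np.ndarray
    seed: int
    naive_noise: dict[str, list[int]] = field(default_factory=dict)

    def lengths(self) -> dict[str, int]:
        return {u: len(s) for u, s in zip(self.ids, self.ancestral)}

    def naive_reference(self) -> UnigeneReference:
        return UnigeneReference(zip(self.ids, self.ancestral))

    def true_reference(self, genome: str) -> UnigeneReference:
        seqs = {"A": self.a_seqs, "C": self.c_seqs}[genome]
        return UnigeneReference(zip(self.ids, seqs))

    def n_divergent_sites(self) -> int:
        return sum(len(v) for v in self.divergent.values())

    def a_fraction(self) -> np.ndarray:
        tot = self.a_levels + self.c_levels
        return np.divide(self.a_levels, tot, out=np.full_like(tot, np.nan),
                         where=tot > 0)


def simulate_diverged_pair(
    n_unigenes: int = DEFAULT_N_UNIGENES,
    length_distribution: int | tuple[int, int] = DEFAULT_UNIGENE_LENGTH,
    divergence_rate: float = DEFAULT_DIVERGENCE,
    seed: int = 0,
    a_fraction: float | np.ndarray = 0.5,
    naive_noise_rate: float = 0.0,
) -> SimulationTruth:
    """Plant a homoeologous unigene pair universe.

    Ancestral bases are i.i.d. uniform over {A, C, G, T}. Each position is
    independently divergent with probability ``divergence_rate``; a
    divergent site is mutated to a random different base in exactly one of
    the two genomes (chosen fairly), so the other genome keeps the
    ancestral base. ``a_fraction`` (scalar or per-unigene array) sets the
    planted expression bias: levels are 2f for A and 2(1 - f) for C, so a
    pair's total level is always 2. ``naive_noise_rate`` optionally
    corrupts the ancestral copy used as the naive reference, emulating
    co-assembly artefacts shared by neither genome.
    """
    if not 0.0 <= divergence_rate <= 1.0:
        raise ValueError("divergence_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if isinstance(length_distribution, int):
        lengths = np.full(n_unigenes, length_distribution)
    else:
        lo, hi = length_distribution
        lengths = rng.integers(lo, hi + 1, size=n_unigenes)
    ids = [f"u{i + 1}" for i in range(n_unigenes)]
    ancestral, a_seqs, c_seqs = [], [], []
    divergent: dict[str, list[tuple[int, str, str]]] = {}
    naive_noise: dict[str, list[int]] = {}
    for i, (uid, L) in enumerate(zip(ids, lengths)):
        anc = rng.integers(0, 4, size=L).astype(np.uint8)
        a = anc.copy()
        c = anc.copy()
        div_mask = rng.random(L) < divergence_rate
        div_pos = np.nonzero(div_mask)[0]
        sites = []
        for p in div_pos:
            new = (anc[p] + rng.integers(1, 4)) % 4
            if rng.random() < 0.5:
                a[p] = new
            else:
                c[p] = new
            sites.append((int(p), "ACGTN"[a[p]], "ACGTN"[c[p]]))
        if naive_noise_rate > 0:
            noise_pos = np.nonzero(rng.random(L) < naive_noise_rate)[0]
            for p in noise_pos:
                anc[p] = (anc[p] + rng.integers(1, 4)) % 4
            naive_noise[uid] = [int(p) for p in noise_pos]
        ancestral.append(decode_sequence(anc))
        a_seqs.append(decode_sequence(a))
        c_seqs.append(decode_sequence(c))
        divergent[uid] = sites
    f = np.broadcast_to(np.asarray(a_fraction, dtype=float), (n_unigenes,)).copy()
    if np.any((f < 0) | (f > 1)):
        raise ValueError("a_fraction must be in [0, 1]")
    return SimulationTruth(
        ids=ids,
        ancestral=ancestral,
        a_seqs=a_seqs,
        c_seqs=c_seqs,
        divergent=divergent,
        a_levels=2.0 * f,
        c_levels=2.0 * (1.0 - f),
        seed=seed,
        naive_noise=naive_noise,
    )


def quality_profile(read_length: int) -> np.ndarray:
    """Per-base Phred profile: flat Q30, decaying toward Q20 after base 60."""
    q = np.full(read_length, 30, dtype=np.int16)
    if read_length > 61:
        tail = np.arange(61, read_length)
        q[61:] = np.maximum(
            20, 30 - np.round(10 * (tail - 60) / (read_length - 61))
        ).astype(np.int16)
    return q


def _reads_from_template(
    uid: str,
    template: np.ndarray,
    n_reads: int,
    read_length: int,
    error_rate: float,
    quals: np.ndarray,
    rng: np.random.Generator,
    genome_label: str,
    id_prefix: str,
) -> list[Read]:
    L = read_length
    span = len(template) - L + 1
    if span <= 0 or n_reads == 0:
        return []
    starts = rng.integers(0, span, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    mat = template[starts[:, None] + np.arange(L)[None, :]].copy()
    rev = strands == 1
    if rev.any():
        rc = mat[rev][:, ::-1]
        mat[rev] = np.where(rc < 4, 3 - rc, 4).astype(np.uint8)
    if error_rate > 0:
        err = rng.random(mat.shape) < error_rate
        shift = rng.integers(1, 4, size=mat.shape).astype(np.uint8)
        mat = np.where(err & (mat < 4), (mat + shift) % 4, mat).astype(np.uint8)
    reads = []
    for j in range(n_reads):
        strand = "-" if strands[j] else "+"
        rid = f"{id_prefix}{j}|{uid}|{strand}|{int(starts[j])}|{genome_label}"
        reads.append(Read(rid, decode_sequence(mat[j]), quals))
    return reads


def parse_read_truth(read_id: str) -> tuple[str, str, int, str]:
    """(unigene, strand, start, template genome) from a simulated read id."""
    _, uid, strand, start, genome = read_id.split("|")
    return uid, strand, int(start), genome


def simulate_reads(
    truth: SimulationTruth,
    genome: str,
    depth_target: float = DEFAULT_DEPTH,
    read_length: int = DEFAULT_READ_LENGTH,
    error_rate: float = DEFAULT_ERROR_RATE,
    quality_model: str = "q30_tail",
    seed: int = 0,
    sample: str | None = None,
) -> ReadSet:
    """Simulate one sample's reads from the planted genomes.

    Per unigene the read count is Poisson with mean
    ``depth_target * length / read_length``. ``genome`` selects the
    template: "A", "C", or "polyploid", where each read's template genome
    is drawn with probability proportional to the planted expression
    levels. Start positions and strands are uniform; substitution errors
    hit each base independently at ``error_rate``. Read identifiers encode
    the true origin for recovery checks.
    """
    if genome not in {"A", "C", "polyploid"}:
        raise ValueError("genome must be A, C, or polyploid")
    if quality_model != "q30_tail":
        raise ValueError(f"unknown quality model {quality_model!r}")
    rng = np.random.default_rng(seed)
    quals = quality_profile(read_length)
    reads: list[Read] = []
    for i, uid in enumerate(truth.ids):
        L_u = len(truth.ancestral[i])
        if L_u < read_length:
            continue
        lam = depth_target * L_u / read_length
        n = int(rng.poisson(lam))
        if genome == "polyploid":
            tot = truth.a_levels[i] + truth.c_levels[i]
            p_a = truth.a_levels[i] / tot if tot > 0 else 0.5
            n_a = int(rng.binomial(n, p_a))
            for g, cnt, seq in (
                ("A", n_a, truth.a_seqs[i]),
                ("C", n - n_a, truth.c_seqs[i]),
            ):
                reads.extend(
                    _reads_from_template(
                        uid, encode_sequence(seq), cnt, read_length, error_rate,
                        quals, rng, g, f"p_{uid}_{g}_",
                    )
                )
        else:
            seq = truth.a_seqs[i] if genome == "A" else truth.c_seqs[i]
            reads.extend(
                _reads_from_template(
                    uid, encode_sequence(seq), n, read_length, error_rate,
                    quals, rng, genome, f"{genome.lower()}_{uid}_",
                )
            )
    tag = genome if genome in {"A", "C"} else "polyploid"
    return ReadSet(
        reads,
        sample=sample or f"{genome}_sim",
        genome_tag=tag,
        nominal_length=read_length if not reads else None,
    )


@dataclass
class SimulatedExperiment:
    """A replicated polyploid experiment with its generating truth."""

    replicates: list[ReadSet]
    true_counts: pd.DataFrame  # generated template counts, rows u_A/u_C
    expected_counts: pd.DataFrame  # gamma-free Poisson means
    truth: SimulationTruth


def simulate_paired_experiment(
    truth: SimulationTruth,
    n_replicates: int = DEFAULT_N_REPLICATES,
    dispersion_phi: float = DEFAULT_PHI,
    depth_target: float = DEFAULT_DEPTH,
    read_length: int = DEFAULT_READ_LENGTH,
    error_rate: float = DEFAULT_ERROR_RATE,
    seed: int = 0,
) -> SimulatedExperiment:
    """Generate per-replicate polyploid read sets with target dispersion.

    Counts per (unigene, genome, replicate) are gamma-Poisson: the Poisson
    mean ``mu = depth * length / read_length * level / 2`` is multiplied by
    an observation-level Gamma(k, 1/k) factor with ``k = mu / (phi - 1)``,
    giving variance ``phi * mu``; a shared lognormal replicate factor adds
    the paired block structure that the test's replicate indicators absorb.
    """
    if dispersion_phi < 1.0:
        raise ValueError("dispersion_phi must be >= 1")
    rng = np.random.default_rng(seed)
    quals = quality_profile(read_length)
    rep_factor = np.exp(rng.normal(0.0, 0.15, size=n_replicates) - 0.15**2 / 2)
    rows = []
    for uid in truth.ids:
        rows.extend([uid + "_A", uid + "_C"])
    true_counts = pd.DataFrame(
        0, index=rows, columns=[f"rep{r + 1}" for r in range(n_replicates)]
    )
    expected = true_counts.astype(float).copy()
    replicates = []
    for r in range(n_replicates):
        reads: list[Read] = []
        for i, uid in enumerate(truth.ids):
            L_u = len(truth.ancestral[i])
            if L_u < read_length:
                continue
            base = depth_target * L_u / read_length * rep_factor[r]
            for g, level, seq in (
                ("A", truth.a_levels[i], truth.a_seqs[i]),
                ("C", truth.c_levels[i], truth.c_seqs[i]),
            ):
                mu = base * level / 2.0
                expected.loc[f"{uid}_{g}", f"rep{r + 1}"] = mu
                if mu <= 0:
                    continue
                if dispersion_phi > 1.0:
                    k = mu / (dispersion_phi - 1.0)
                    mult = rng.gamma(k, 1.0 / k)
                else:
                    mult = 1.0
                n = int(rng.poisson(mu * mult))
                true_counts.loc[f"{uid}_{g}", f"rep{r + 1}"] = n
                reads.extend(
                    _reads_from_template(
                        uid, encode_sequence(seq), n, read_length, error_rate,
                        quals, rng, g, f"r{r + 1}_{uid}_{g}_",
                    )
                )
        replicates.append(
            ReadSet(
                reads,
                sample=f"rep{r + 1}",
                genome_tag="polyploid",
                nominal_length=read_length if not reads else None,
            )
        )
    return SimulatedExperiment(
        replicates=replicates,
        true_counts=true_counts,
        expected_counts=expected,
        truth=truth,
    )


def simulate_paired_counts(
    n_unigenes: int,
    n_replicates: int = DEFAULT_N_REPLICATES,
    mean_a: float | np.ndarray = 50.0,
    mean_c: float | np.ndarray = 50.0,
    dispersion_phi: float = DEFAULT_PHI,
    seed: int = 0,
    rep_effect_sd: float = 0.15,
) -> tuple[np.ndarray, np.ndarray]:
    """Direct gamma-Poisson paired count matrices (no reads).

    The fast path for calibrating and testing the paired quasi-Poisson
    statistics: returns (A, C) integer matrices of shape
    ``(n_unigenes, n_replicates)`` with observation-level dispersion Phi
    around means ``mean_a`` / ``mean_c`` and a shared per-replicate
    lognormal factor.
    """
    if dispersion_phi < 1.0:
        raise ValueError("dispersion_phi must be >= 1")
    rng = np.random.default_rng(seed)
    ma = np.broadcast_to(np.asarray(mean_a, float), (n_unigenes,))
    mc = np.broadcast_to(np.asarray(mean_c, float), (n_unigenes,))
    rep = np.exp(rng.normal(0.0, rep_effect_sd, size=n_replicates)
                 - rep_effect_sd**2 / 2)
    out = []
    for means in (ma, mc):
        mu = means[:, None] * rep[None, :]
        if dispersion_phi > 1.0:
            k = mu / (dispersion_phi - 1.0)
            mult = rng.gamma(np.maximum(k, 1e-12), 1.0 / np.maximum(k, 1e-12))
        else:
            mult = np.ones_like(mu)
        out.append(rng.poisson(mu * mult).astype(np.int64))
    return out[0], out[1]


def write_truth_tsv(truth: SimulationTruth, path) -> None:
    """Planted divergent sites and expression levels (1-based positions)."""
    with open(path, "w") as fh:
        fh.write("unigene\tpos\tA_base\tC_base\tA_level\tC_level\n")
        for i, uid in enumerate(truth.ids):
            for pos, a, c in truth.divergent[uid]:
                fh.write(
                    f"{uid}\t{pos + 1}\t{a}\t{c}\t"
                    f"{truth.a_levels[i]:.4f}\t{truth.c_levels[i]:.4f}\n"
                )
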