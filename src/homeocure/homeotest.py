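"""Paired quasi-Poisson test for differential homoeologue contribution.

For each unigene the paired A/C abundances over the n biological
replicates (2n observations) are fit with a log-link GLM using the Poisson
variance function: predictors are replicate indicators (the paired
blocking) plus a genome indicator (C vs A). The dispersion parameter Phi
is not fixed at 1 but estimated from the Pearson statistic (Pearson chi2 /
residual df), so the coefficient estimates equal those of a plain Poisson
fit while inference is over-dispersion-adjusted: the genome coefficient's
Wald statistic uses Phi-scaled standard errors and is referred to a t
distribution with the residual degrees of freedom (n - 1 for n pairs).
Raw p-values are Benjamini–Hochberg adjusted; adjusted p < alpha (default
0.05) with the coefficient's sign gives the A-higher / C-higher bias call.

Quasi-likelihood requires no integer response, so the fits accept RPKM
values directly (the default); a raw-counts mode is the caller's choice by
simply passing counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05


@dataclass
class PairedAbundance:
    """Per-replicate paired A/C abundances (RPKM or counts) for one unigene."""

    unigene: str
    a_values: np.ndarray
    c_values: np.ndarray

    def __post_init__(self):
        self.a_values = np.asarray(self.a_values, dtype=float)
        self.c_values = np.asarray(self.c_values, dtype=float)
        if self.a_values.shape != self.c_values.shape or self.a_values.ndim != 1:
            raise ValueError("a_values and c_values must be 1-d and paired")
        if np.any(self.a_values < 0) or np.any(self.c_values < 0):
            raise ValueError("abundances must be non-negative")

    @property
    def n_replicates(self) -> int:
        return self.a_values.size


@dataclass
class HomoeologueTestResult:
    unigene: str
    mean_a: float
    mean_c: float
    genome_effect: float  # log-scale coefficient, C relative to A
    dispersion_phi: float
    p_raw: float
    p_adjusted: float = np.nan
    bias: str = "none"  # {A_higher, C_higher, none}
    tested: bool = True


def fit_paired_quasipoisson(
    data: PairedAbundance,
) -> tuple[float, float, float]:
    """Fit one unigene's paired series; returns (effect, phi, p_raw).

    Raises ValueError for fewer than 2 replicates or an all-zero series
    (no information to test; callers should drop and report such rows).
    """
    n = data.n_replicates
    if n < 2:
        raise ValueError(f"{data.unigene}: need >= 2 replicates, got {n}")
    y = np.concatenate([data.a_values, data.c_values])
    if not np.all(np.isfinite(y)):
        raise ValueError(f"{data.unigene}: non-finite abundance values")
    if y.max() == 0:
        raise ValueError(f"{data.unigene}: all abundances are zero")
    rep = np.tile(np.arange(n), 2)
    genome = np.repeat([0.0, 1.0], n)  # 0 = A, 1 = C
    X = np.column_stack(
        [np.ones(2 * n)]
        + [(rep == r).astype(float) for r in range(1, n)]
        + [genome]
    )
    model = sm.GLM(y, X, family=sm.families.Poisson())
    try:
        with warnings.catch_warnings():
            # a genome with all-zero counts separates perfectly; the huge
            # scaled SE already makes the test conservative there
            warnings.simplefilter("ignore")
            res = model.fit(scale="X2")
    except Exception as exc:  # non-convergence / separation
        raise FitError(f"{data.unigene}: GLM fit failed ({exc})") from exc
    if not np.all(np.isfinite(res.params)):
        raise FitError(f"{data.unigene}: non-finite coefficient estimates")
    effect = float(res.params[-1])
    phi = float(res.scale)
    se = float(res.bse[-1])
    df_resid = 2 * n - X.shape[1]  # = n - 1
    if se == 0.0 or not np.isfinite(se) or phi <= 1e-8:
        # (near-)perfect fit: Pearson chi2 ~ 0 makes the scaled SE
        # meaningless; perfectly symmetric data carry no evidence at all
        p_raw = 1.0 if abs(effect) < 1e-8 else 0.0
    else:
        t = effect / se
        p_raw = float(2.0 * sps.t.sf(abs(t), df_resid))
    return effect, phi, p_raw


class FitError(RuntimeError):
    """A per-unigene GLM fit failed to converge to finite estimates."""


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_bias(
    results: list[HomoeologueTestResult], alpha: float = DEFAULT_ALPHA
) -> list[HomoeologueTestResult]:
    """Fill bias calls in place: significant + sign of the genome effect.

    The effect is the log abundance of C relative to A, so a negative
    effect with adjusted p < alpha is A_higher and a positive one C_higher.
    """
    for r in results:
        if not r.tested or not np.isfinite(r.p_adjusted):
            r.bias = "none"
        elif r.p_adjusted < alpha and r.genome_effect < 0:
            r.bias = "A_higher"
        elif r.p_adjusted < alpha and r.genome_effect > 0:
            r.bias = "C_higher"
        else:
            r.bias = "none"
    return results


def test_homoeologue_pairs(
    pairs: list[PairedAbundance],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Run the paired test over many unigenes with BH adjustment.

    All-zero or failing unigenes are kept in the output with
    ``tested=False`` and NaN statistics; they do not enter the BH family.
    """
    results: list[HomoeologueTestResult] = []
    for d in pairs:
        base = dict(
            unigene=d.unigene,
            mean_a=float(np.mean(d.a_values)),
            mean_c=float(np.mean(d.c_values)),
        )
        try:
            effect, phi, p_raw = fit_paired_quasipoisson(d)
            results.append(
                HomoeologueTestResult(
                    genome_effect=effect, dispersion_phi=phi, p_raw=p_raw, **base
                )
            )
        except (ValueError, FitError):
            results.append(
                HomoeologueTestResult(
                    genome_effect=np.nan,
                    dispersion_phi=np.nan,
                    p_raw=np.nan,
                    tested=False,
                    **base,
                )
            )
    tested = [r for r in results if r.tested]
    if tested:
        adj = bh_adjust([r.p_raw for r in tested])
        for r, a in zip(tested, adj):
            r.p_adjusted = float(a)
    classify_bias(results, alpha)
    return pd.DataFrame(
        {
            "unigene": [r.unigene for r in results],
            "mean_rpkm_A": [r.mean_a for r in results],
            "mean_rpkm_C": [r.mean_c for r in results],
            "effect": [r.genome_effect for r in results],
            "phi": [r.dispersion_phi for r in results],
            "p": [r.p_raw for r in results],
            "p_adj": [r.p_adjusted for r in results],
            "bias": [r.bias for r in results],
            "tested": [r.tested for r in results],
        }
    ).set_index("unigene")


def paired_abundances_from_matrix(
    rpkm: pd.DataFrame,
    base_ids: list[str] | None = None,
    ihp_unigenes: set[str] | None = None,
) -> list[PairedAbundance]:
    """Build paired series from a version-level abundance matrix.

    Rows of ``rpkm`` are ``<unigene>_A`` / ``<unigene>_C``, columns are the
    replicates. Without IHPs the two versions are indistinguishable and the
    50:50 tie-splitting forces apparent equality, so when ``ihp_unigenes``
    is given, unigenes outside it are excluded from testing.
    """
    if base_ids is None:
        base_ids = sorted(
            {v[:-2] for v in rpkm.index if v.endswith(("_A", "_C"))}
        )
    out = []
    for u in base_ids:
        if ihp_unigenes is not None and u not in ihp_unigenes:
            continue
        if u + "_A" not in rpkm.index or u + "_C" not in rpkm.index:
            raise KeyError(f"matrix lacks both versions of unigene {u!r}")
        out.append(
            PairedAbundance(
                u,
                rpkm.loc[u + "_A"].to_numpy(dtype=float),
                rpkm.loc[u + "_C"].to_numpy(dtype=float),
            )
        )
    return out


def consistency_across_conditions(
    result_tables: list[pd.DataFrame], mode: str = "intersect"
) -> pd.DataFrame:
    """Cross-tabulate bias calls over several conditions.

    Each input is a table from :func:`test_homoeologue_pairs`, all indexed
    by the same unigene universe. Returns counts for every observed
    combination of bias categories across conditions (including the
    discordant A-in-one / C-in-another classes), plus per-category
    intersection counts.
    """
    if mode != "intersect":
        raise ValueError(f"unknown mode {mode!r}")
    if not result_tables:
        raise ValueError("no result tables supplied")
    universe = result_tables[0].index
    for t in result_tables[1:]:
        if not t.index.equals(universe):
            raise ValueError("result tables are indexed by different unigenes")
    combo = pd.DataFrame(
        {f"condition{i + 1}": t["bias"] for i, t in enumerate(result_tables)}
    )
    counts = combo.value_counts().rename("n_unigenes").reset_index()
    return counts


def consistent_bias_sets(result_tables: list[pd.DataFrame]) -> dict[str, set[str]]:
    """Unigenes with the same significant call in every condition."""
    out = {}
    for cat in ("A_higher", "C_higher"):
        sets = [set(t.index[t["bias"] == cat]) for t in result_tables]
        out[cat] = set.intersection(*sets) if sets else set()
    return out
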