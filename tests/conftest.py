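"""Shared fixtures: the default simulated curing fixture and helpers.

The session-scoped ``cure_fixture`` is the package's standard study
condition — 200 unigenes of 1 kb at 3% homoeologue divergence, 30x
progenitor coverage of 80-base reads with 1% substitution error, cured for
six cycles — and is shared by the curing, IHP and mapping-gain checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from homeocure import CuringConfig, ReadSet, build_cured_pair
from homeocure.simdata import (
    SimulationTruth,
    parse_read_truth,
    simulate_diverged_pair,
    simulate_reads,
)


def genome_coverage(truth: SimulationTruth, reads: ReadSet) -> dict[str, np.ndarray]:
    """True per-position read coverage from simulated read identifiers."""
    cov = {u: np.zeros(len(s), dtype=np.int64) for u, s in zip(truth.ids, truth.ancestral)}
    for r in reads:
        uid, _strand, start, _genome = parse_read_truth(r.id)
        cov[uid][start : start + len(r)] += 1
    return cov


@dataclass
class CureFixture:
    truth: SimulationTruth
    reads_a: ReadSet
    reads_c: ReadSet
    cfg: CuringConfig
    pair: object  # CuredReferencePair
    coverage_a: dict[str, np.ndarray]
    coverage_c: dict[str, np.ndarray]


@pytest.fixture(scope="session")
def cure_fixture() -> CureFixture:
    truth = simulate_diverged_pair(
        n_unigenes=200, length_distribution=1000, divergence_rate=0.03, seed=42
    )
    reads_a = simulate_reads(truth, "A", depth_target=30, error_rate=0.01, seed=421)
    reads_c = simulate_reads(truth, "C", depth_target=30, error_rate=0.01, seed=422)
    cfg = CuringConfig(rng_seed=7)
    pair = build_cured_pair(truth.naive_reference(), reads_a, reads_c, cfg)
    return CureFixture(
        truth=truth,
        reads_a=reads_a,
        reads_c=reads_c,
        cfg=cfg,
        pair=pair,
        coverage_a=genome_coverage(truth, reads_a),
        coverage_c=genome_coverage(truth, reads_c),
    )


@pytest.fixture(scope="session")
def tiny_truth() -> SimulationTruth:
    return simulate_diverged_pair(
        n_unigenes=8, length_distribution=400, divergence_rate=0.03, seed=3
    )
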