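"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import icrcall as ic

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


GENOTYPE_EXPECTED_STATUS = {
    ic.Genotype.NORMAL: ("NORMAL", "NORMAL"),
    ic.Genotype.ICR1_GOM: ("GOM", "NORMAL"),
    ic.Genotype.ICR1_LOM: ("LOM", "NORMAL"),
    ic.Genotype.ICR2_LOM: ("NORMAL", "LOM"),
    ic.Genotype.ICR1_GOM_ICR2_LOM: ("GOM", "LOM"),
}


def make_truths(counts: dict[ic.Genotype, int], purity: float = 1.0,
                cfdna_tumor_fraction: float = 0.0) -> list[ic.SyntheticTruth]:
    """Deterministic truth list: one block per genotype, in dict order."""
    truths = []
    for genotype, n in counts.items():
        for i in range(n):
            truths.append(
                ic.SyntheticTruth(
                    sample_id=f"{genotype.value}-{i + 1:02d}",
                    genotype=genotype,
                    purity=purity,
                    cfdna_tumor_fraction=cfdna_tumor_fraction,
                )
            )
    return truths


@pytest.fixture
def noiseless_cohort() -> ic.BetaMatrix:
    """One sample of each genotype, zero-noise limit, purity 1."""
    truths = make_truths({g: 1 for g in ic.Genotype})
    return ic.simulate_beta_cohort(
        truths, noise=ic.NoiseModel.noiseless(), seed=0
    )


def brute_force_complete_linkage(D: np.ndarray):
    """Naive agglomeration oracle: repeatedly merge the closest pair under
    complete linkage (max pairwise leaf distance), ties by lowest pair index.

    Returns a list of (leaf_set_a, leaf_set_b, height) in merge order.
    """
    n = D.shape[0]
    active: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(active) > 1:
        best = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                d = max(D[a, b] for a in active[i] for b in active[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merges.append((active[i], active[j], d))
        merged = active[i] | active[j]
        active = [c for k, c in enumerate(active) if k not in (i, j)]
        active.append(merged)
    return merges


def random_distance_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    """Symmetric zero-diagonal distances with distinct off-diagonal values."""
    vals = rng.permutation(np.linspace(0.1, 2.0, n * (n - 1) // 2))
    D = np.zeros((n, n))
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = vals[k]
            k += 1
    return D
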