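"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from liabscan.relationships import Pedigree


def dense_tabular_a(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Independent dense numerator-relationship oracle (plain recursion).

    Written directly from the textbook definition: a_ij = 0.5(a_{i,s_j} +
    a_{i,d_j}) for i < j and a_ii = 1 + 0.5 a_{s_i, d_i}; deliberately kept
    separate from the package's implementations.
    """
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i] - 1, dam[i] - 1  # -1 means unknown
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[i, j] = A[j, i] = a
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return A


def random_pedigree(rng: np.random.Generator, n_animals: int, n_founders: int | None = None) -> Pedigree:
    """Random topologically ordered pedigree with some unknown parents."""
    if n_founders is None:
        n_founders = max(2, n_animals // 5)
    sire = np.zeros(n_animals, dtype=np.int64)
    dam = np.zeros(n_animals, dtype=np.int64)
    for i in range(n_founders, n_animals):
        # occasionally leave one parent unknown
        sire[i] = rng.integers(1, i + 1) if rng.random() > 0.1 else 0
        dam[i] = rng.integers(1, i + 1) if rng.random() > 0.1 else 0
    return Pedigree(sire=sire, dam=dam)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_study():
    """One small synthetic study reused by read-only tests."""
    from liabscan.config import SimConfig
    from liabscan.simulate import simulate_study

    cfg = SimConfig(
        n_founders=120,
        n_generations=2,
        matings_per_generation=150,
        offspring_per_mating=2,
        n_sires_per_generation=15,
        n_chromosomes=3,
        snps_per_chromosome=60,
        n_qtl=3,
        n_records=400,
        n_service_sires=25,
        prop_genotyped=0.25,
        seed=42,
    )
    return simulate_study(cfg)


@pytest.fixture()
def toy_snp_map():
    return pd.DataFrame(
        {
            "snp_id": ["s1", "s2", "s3", "s4"],
            "chromosome": ["1", "1", "1", "1"],
            "position_bp": [100_000, 1_000_000, 1_900_000, 2_500_000],
        }
    )
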