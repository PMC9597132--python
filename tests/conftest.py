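"""Shared fixtures: schemes, catalogs, and small seeded synthetic corpora."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tas_masem import (build_catalog, default_population, default_scheme,
                       generate_corpus, pool)

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def catalog(scheme):
    return build_catalog(scheme)


@pytest.fixture(scope="session")
def homogeneous_population():
    """Pure three-correlated-factor population: no residual correlations,
    no group differences — every sample reports raw correlations."""
    return default_population(
        seed=101,
        residual_correlation=0.0,
        group_perturbations={},
        clinical_perturbation={},
        reporting_mix={"raw_correlations": 1.0, "efa_pattern": 0.0, "cfa_pattern": 0.0},
        k=12,
        n_median=800,
        n_sigma=0.4,
        languages={"English": 12},
        english_clinical_samples=0,
        other_clinical_rate=0.0,
    )


@pytest.fixture(scope="session")
def homogeneous_corpus(homogeneous_population):
    records, truth = generate_corpus(homogeneous_population)
    return records, truth


@pytest.fixture(scope="session")
def homogeneous_pooled(homogeneous_corpus):
    records, _ = homogeneous_corpus
    return pool(records)


@pytest.fixture(scope="session")
def mixed_corpus():
    """Small corpus exercising all three reporting kinds and censoring."""
    pop = default_population(
        seed=202, k=10, n_median=500, n_sigma=0.4,
        reporting_mix={"raw_correlations": 0.3, "efa_pattern": 0.4, "cfa_pattern": 0.3},
        languages={"English": 6, "French": 4},
        english_clinical_samples=1,
    )
    return generate_corpus(pop)


@pytest.fixture(scope="session")
def default_population_matrix(scheme):
    pop = default_population(seed=0, residual_correlation=0.0,
                             group_perturbations={}, clinical_perturbation={})
    from tas_masem import population_matrix
    return population_matrix(pop, scheme=scheme)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
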