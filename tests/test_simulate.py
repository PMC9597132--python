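"""Synthetic corpus generator: population matrices, sampling, degradation."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from tas_masem import (default_population, degrade_to_pattern, generate_corpus,
                       implied_correlations, impute_censored, pool,
                       population_matrix, sample_study, summarize, write_corpus)
from tas_masem.pooling import vech


@pytest.fixture(scope="module")
def pop():
    return default_population(seed=9)


class TestPopulationMatrix:
    def test_uniform_one_factor_case(self, pop, scheme):
        spec = dataclasses.replace(
            pop, partition="one_factor", phi=np.eye(1), residual_correlation=0.0,
            group_perturbations={}, clinical_perturbation={},
            loadings={it: 0.7 for it in scheme.item_labels})
        R = population_matrix(spec, scheme=scheme)
        off = ~np.eye(20, dtype=bool)
        np.testing.assert_allclose(R[off], 0.49, atol=1e-12)

    def test_cross_factor_entry_is_hand_product(self, pop, scheme):
        spec = dataclasses.replace(pop, residual_correlation=0.0,
                                   group_perturbations={}, clinical_perturbation={})
        R = population_matrix(spec, scheme=scheme)
        i, j = scheme.index["item01"], scheme.index["item02"]   # DIF x DDF
        expected = spec.loadings["item01"] * 0.77 * spec.loadings["item02"]
        assert R[i, j] == pytest.approx(expected)

    def test_perturbation_locality(self, pop, scheme):
        base = dataclasses.replace(pop, residual_correlation=0.0,
                                   clinical_perturbation={},
                                   group_perturbations={"X": {"item05": 0.15}})
        R0 = population_matrix(base, scheme=scheme)
        R1 = population_matrix(base, "X", scheme=scheme)
        diff = R1 != R0
        k = scheme.index["item05"]
        touched = np.zeros_like(diff)
        touched[k, :] = touched[:, k] = True
        touched[k, k] = False
        assert not diff[~touched].any()
        assert diff[touched].any()

    def test_non_positive_definite_perturbation_rejected(self, pop, scheme):
        bad = dataclasses.replace(
            pop, group_perturbations={"X": {it: 0.6 for it in scheme.item_labels}})
        with pytest.raises(ValueError, match="X"):
            population_matrix(bad, "X", scheme=scheme)

    def test_residual_overlay_only_on_reverse_keyed_pairs(self, pop, scheme):
        with_res = dataclasses.replace(pop, group_perturbations={},
                                       clinical_perturbation={})
        without = dataclasses.replace(with_res, residual_correlation=0.0)
        D = population_matrix(with_res, scheme=scheme) - population_matrix(
            without, scheme=scheme)
        neg = [scheme.index[i] for i in sorted(scheme.negative_keyed)]
        for a in neg:
            for b in neg:
                if a != b:
                    assert D[a, b] == pytest.approx(0.15)
        D[np.ix_(neg, neg)] = 0.0
        assert np.abs(D).max() == 0.0


class TestSampleStudy:
    def test_same_seed_identical(self, default_population_matrix):
        a = sample_study(default_population_matrix, 200, seed=5)
        b = sample_study(default_population_matrix, 200, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_large_n_converges_to_population(self, default_population_matrix):
        R = sample_study(default_population_matrix, 1_000_000, seed=1)
        assert np.abs(R - default_population_matrix).max() < 0.005

    def test_small_n_still_valid(self, default_population_matrix):
        R = sample_study(default_population_matrix, 30, seed=2)
        np.testing.assert_allclose(R, R.T)
        np.testing.assert_allclose(np.diag(R), 1.0)

    def test_tiny_n_rejected(self, default_population_matrix):
        with pytest.raises(ValueError):
            sample_study(default_population_matrix, 15, seed=0)


class TestDegradeToPattern:
    def test_zero_threshold_never_censors(self, default_population_matrix):
        R = sample_study(default_population_matrix, 2_000, seed=3)
        sol = degrade_to_pattern(R, m=3, rotation="quartimin", censor_threshold=0.0)
        assert not sol.censored_mask.any()

    def test_full_censoring_reconstructs_identity_and_pools(
            self, default_population_matrix, homogeneous_corpus):
        R = sample_study(default_population_matrix, 2_000, seed=3)
        sol = degrade_to_pattern(R, m=3, censor_threshold=1.0)
        assert sol.censored_mask.all()
        rebuilt = implied_correlations(impute_censored(sol))
        np.testing.assert_array_equal(rebuilt, np.eye(20))
        records, _ = homogeneous_corpus
        degraded = dataclasses.replace(
            records[0], sample_id="blank", correlation=None, factor_corr=sol.phi,
            pattern=impute_censored(sol).loadings, source_kind="efa_pattern")
        pooled = pool([degraded] + list(records[1:]))   # must still run
        assert pooled.k == len(records)

    def test_censored_reconstruction_tracks_sample_matrix(
            self, default_population_matrix):
        """Censoring at .40 suppresses most of the weak EOT loadings
        (population values .32-.50), so some structure is irrecoverable;
        the measured element-wise correlation stays above .92."""
        R = sample_study(default_population_matrix, 5_000, seed=4)
        sol = degrade_to_pattern(R, m=3, rotation="quartimin", censor_threshold=0.40)
        rebuilt = implied_correlations(impute_censored(sol))
        corr = np.corrcoef(vech(rebuilt), vech(R))[0, 1]
        assert corr > 0.92


class TestGenerateCorpus:
    def test_counts_and_labels(self, pop):
        records, truth = generate_corpus(pop)
        assert len(records) == 88
        s = summarize(records)
        assert s.language_counts["English"] == 34
        assert s.language_counts["French"] == 8
        assert truth["k"] == 88 and truth["total_N"] == s.total_N

    def test_reporting_mix_and_censoring(self, pop):
        records, _ = generate_corpus(pop)
        kinds = summarize(records).source_counts
        assert set(kinds) <= {"raw_correlations", "efa_pattern", "cfa_pattern"}
        assert kinds["cfa_pattern"] > kinds["efa_pattern"] > 0
        efa = [r for r in records if r.source_kind == "efa_pattern"]
        assert any(np.isnan(r.pattern).any() for r in efa)
        finite = np.concatenate([r.pattern[np.isfinite(r.pattern)] for r in efa])
        assert (np.abs(finite) >= 0.40 - 1e-12).all()

    def test_sample_sizes_within_configured_range(self, pop):
        records, _ = generate_corpus(pop)
        ns = np.array([r.n for r in records])
        assert ns.min() >= 99 and ns.max() <= 12_706

    def test_same_seed_byte_identical_serialization(self, tmp_path):
        spec = default_population(seed=77, k=8, n_median=300, n_sigma=0.3,
                                  languages={"English": 5, "German": 3})
        for sub in ("a", "b"):
            records, _ = generate_corpus(spec)
            write_corpus(records, tmp_path / sub)
        for fa in sorted((tmp_path / "a").rglob("*.csv")):
            fb = tmp_path / "b" / fa.relative_to(tmp_path / "a")
            assert fa.read_bytes() == fb.read_bytes(), fa.name

    def test_language_counts_must_sum_to_k(self, pop):
        with pytest.raises(ValueError, match="sum to k"):
            generate_corpus(dataclasses.replace(pop, k=87))

    def test_reporting_mix_must_sum_to_one(self, pop):
        with pytest.raises(ValueError, match="sum to 1"):
            dataclasses.replace(pop, reporting_mix={"raw_correlations": 0.5})
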