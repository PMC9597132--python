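"""WLS CFA engine: discrepancy minimization, fit statistics, reliabilities."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tas_masem import (StudyRecord, build_catalog, default_population, fit_indices,
                       fit_wls, generate_corpus, omega, pool, srmr)
from tas_masem.cfa import FitResult, residual_correlation_summary
from tas_masem.items import ItemScheme
from tas_masem.models import ModelSpec
from tas_masem.pooling import PooledCorrelation, asymptotic_covariance


def make_pooled(R: np.ndarray, N: int) -> PooledCorrelation:
    return PooledCorrelation(R=R, total_N=N, acov=asymptotic_covariance(R, N), k=1)


class TestEngine:
    def test_saturated_model_fits_perfectly(self, catalog, homogeneous_pooled):
        fit = fit_wls(catalog["saturated"], homogeneous_pooled)
        assert fit.chi_square == pytest.approx(0.0, abs=1e-10)
        assert fit.df == 0

    def test_population_parameters_recovered_exactly(self, catalog, scheme,
                                                     default_population_matrix):
        """Fitting the generating model to its own population matrix recovers
        every loading and factor correlation to 1e-4."""
        pop = default_population(seed=0, residual_correlation=0.0,
                                 group_perturbations={}, clinical_perturbation={})
        pooled = make_pooled(default_population_matrix, 69_722)
        fit = fit_wls(catalog["3a"], pooled, scheme=scheme)
        assert fit.converged
        for factor, items in catalog["3a"].factors.items():
            for it in items:
                assert fit.theta[f"lambda[{it},{factor}]"] == \
                       pytest.approx(pop.loadings[it], abs=1e-4)
        assert fit.theta["phi[DIF,DDF]"] == pytest.approx(0.77, abs=1e-4)
        assert fit.theta["phi[DDF,EOT]"] == pytest.approx(0.47, abs=1e-4)
        assert fit.theta["phi[DIF,EOT]"] == pytest.approx(0.32, abs=1e-4)
        assert fit.chi_square == pytest.approx(0.0, abs=1e-6)
        assert fit.indices.cfi == pytest.approx(1.0)
        assert fit.indices.rmsea == pytest.approx(0.0)

    def test_matches_brute_force_grid_on_toy(self):
        """Three items, one factor: the engine's minimum coincides with an
        exhaustive grid search over (λ1, λ2, λ3)."""
        scheme3 = ItemScheme(n_items=3, item_labels=("v1", "v2", "v3"),
                             negative_keyed=frozenset(),
                             factor_assignments={"one": {"F": ("v1", "v2", "v3")}})
        spec = ModelSpec(name="toy", description="", correlated=False,
                         factors={"F": ("v1", "v2", "v3")})
        R = np.array([[1.0, 0.42, 0.30], [0.42, 1.0, 0.25], [0.30, 0.25, 1.0]])
        N = 500
        pooled = PooledCorrelation(R=R, total_N=N, acov=asymptotic_covariance(R, N), k=1)
        fit = fit_wls(spec, pooled, scheme=scheme3)

        Vinv = np.linalg.inv(pooled.acov)
        r = pooled.r

        def discrepancy(lams):  # vectorized over a grid of candidate loadings
            rho = np.stack([lams[..., 1] * lams[..., 0], lams[..., 2] * lams[..., 0],
                            lams[..., 2] * lams[..., 1]], axis=-1)
            d = r - rho
            return np.einsum("...i,ij,...j->...", d, Vinv, d)

        grid = np.arange(0.0, 1.0, 0.01)
        G = np.stack(np.meshgrid(grid, grid, grid, indexing="ij"), axis=-1)
        F = discrepancy(G)
        best = np.unravel_index(np.argmin(F), F.shape)
        center = G[best]
        fine = [np.arange(max(c - 0.02, 0), min(c + 0.02, 1) + 1e-9, 1e-3)
                for c in center]
        Gf = np.stack(np.meshgrid(*fine, indexing="ij"), axis=-1)
        Ff = discrepancy(Gf)
        bf = np.unravel_index(np.argmin(Ff), Ff.shape)
        lam_grid, F_grid = Gf[bf], Ff[bf]

        lam_fit = np.array([fit.theta[f"lambda[v{i},F]"] for i in (1, 2, 3)])
        np.testing.assert_allclose(np.abs(lam_fit), lam_grid, atol=1e-3)
        assert fit.chi_square <= F_grid + 1e-10

    def test_nested_model_chi_square_monotone(self, catalog, homogeneous_pooled):
        fits = {name: fit_wls(catalog[name], homogeneous_pooled, seed=2)
                for name in ("1", "2", "3a", "6", "7")}
        chi = {k: v.chi_square for k, v in fits.items()}
        assert chi["1"] >= chi["2"] >= chi["3a"]
        assert chi["3a"] >= chi["6"]
        assert chi["3a"] >= chi["7"]

    def test_baseline_cfi_is_zero(self, catalog, homogeneous_pooled):
        fit = fit_wls(catalog["independence"], homogeneous_pooled)
        assert fit.indices.cfi == pytest.approx(0.0)
        assert fit.df == 190

    def test_pooled_loading_estimates_unbiased(self, catalog):
        """Across replicate synthetic corpora the pooled loading estimates
        show negligible bias (fixed-effects consistency)."""
        errors = []
        for rep in range(12):
            pop = default_population(
                seed=400 + rep, residual_correlation=0.0, group_perturbations={},
                clinical_perturbation={}, k=30, n_median=327, n_sigma=0.6,
                reporting_mix={"raw_correlations": 1.0, "efa_pattern": 0.0,
                               "cfa_pattern": 0.0},
                languages={"English": 30}, english_clinical_samples=0,
                other_clinical_rate=0.0)
            records, truth = generate_corpus(pop)
            fit = fit_wls(catalog["3a"], pool(records), n_starts=1)
            errors.append([
                fit.theta[f"lambda[{it},{f}]"] - truth["loadings"][it]
                for f, its in catalog["3a"].factors.items() for it in its
            ])
        bias = np.mean(errors, axis=0)
        assert np.abs(bias).mean() < 0.01


class TestFitStatistics:
    def test_exact_fit_boundary(self):
        ind = fit_indices(chi_square=167.0, df=167, chi_square_baseline=30_000,
                          df_baseline=190, N=69_722)
        assert ind.cfi == pytest.approx(1.0)
        assert ind.rmsea == pytest.approx(0.0)

    def test_zero_df_flags_rmsea(self):
        ind = fit_indices(0.0, 0, 100.0, 3, N=1_000)
        assert ind.rmsea == 0.0 and ind.rmsea_ci is None

    def test_rmsea_ci_brackets_point_estimate(self):
        ind = fit_indices(8_424.2, 167, 128_390.0, 190, N=69_722)
        lo, hi = ind.rmsea_ci
        assert lo <= ind.rmsea <= hi
        assert ind.rmsea == pytest.approx(0.027, abs=5e-4)

    def test_srmr_cases(self, rng):
        assert srmr(np.zeros(190)) == 0.0
        assert srmr(np.full(190, -0.03)) == pytest.approx(0.03)
        resid = rng.normal(size=190)
        assert srmr(resid) == pytest.approx(np.sqrt((resid**2).sum() / 190))

    @given(c=st.floats(-0.5, 0.5))
    def test_srmr_of_constant_vector_is_magnitude(self, c):
        assert srmr(np.full(190, c)) == pytest.approx(abs(c))

    def test_omega_closed_forms(self):
        assert omega([0.8, 0.8, 0.8], [0.36] * 3) == pytest.approx(5.76 / 6.84)
        assert omega([0.0, 0.0], [1.0, 1.0]) == 0.0
        assert omega([1.0], [0.0]) == 1.0
        with pytest.raises(ValueError):
            omega([], [])

    def test_residual_summary(self):
        fit = FitResult(model_name="7", chi_square=1.0, df=157,
                        residual_correlations={("a", "b"): 0.2, ("a", "c"): 0.2,
                                               ("b", "c"): 0.2})
        assert residual_correlation_summary(fit) == (0.2, 0.2, 0.2)
        with pytest.raises(ValueError):
            residual_correlation_summary(FitResult(model_name="3a", chi_square=1.0,
                                                   df=167))

    def test_heywood_flagged(self, scheme):
        """A near-singular two-item cluster drives a loading past one."""
        R = np.eye(20)
        R[0, 1] = R[1, 0] = 0.72
        R[0, 2] = R[2, 0] = 0.32
        R[1, 2] = R[2, 1] = 0.64   # implies lambda_2^2 = .72*.64/.32 = 1.44
        spec = ModelSpec(name="toy20", description="", correlated=False,
                         factors={"F": tuple(scheme.item_labels)})
        pooled = make_pooled(R, 2_000)
        with pytest.warns(UserWarning, match="Heywood"):
            fit = fit_wls(spec, pooled, scheme=scheme, n_starts=1)
        assert fit.heywood
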