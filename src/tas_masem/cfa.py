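"""Stage-2 weighted least squares confirmatory factor analysis.

A measurement model parameterizes the implied correlation matrix as

    Σ(θ) = Λ Φ Λᵀ + Θ      (off-diagonal; the diagonal is fixed at 1),

with unit-variance factors, all assigned loadings free, free
correlations among content factors (overlay factors orthogonal), and
optional free residual correlations Θ_ij.  The engine minimizes the WLS
discrepancy over the unique correlations,

    F(θ) = (r − ρ(θ))ᵀ V⁻¹ (r − ρ(θ)),

where r is the pooled correlation vector and V its asymptotic
covariance.  Because V carries the 1/N scaling, the minimum F̂ serves
directly as the model χ².  Uniquenesses are derived as 1 − communality,
consistent with analyzing a correlation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from .items import ItemScheme, default_scheme
from .models import ModelSpec
from .pooling import PooledCorrelation, vech_indices

__all__ = [
    "FitIndices",
    "FitResult",
    "fit_wls",
    "fit_indices",
    "srmr",
    "omega",
    "residual_correlation_summary",
]

EPS_CFI = 1e-10


# ---------------------------------------------------------------------------
# parameterization


class _Parameterization:
    """Index bookkeeping between θ and (Λ, Φ, Θ)."""

    def __init__(self, spec: ModelSpec, scheme: ItemScheme):
        self.spec = spec
        self.scheme = scheme
        self.p = scheme.n_items
        idx = scheme.index
        self.content_factors = list(spec.factors)
        self.factor_names = list(self.content_factors)
        if spec.general_factor:
            self.factor_names.append("G")
        if spec.method_items:
            self.factor_names.append("METHOD")
        self.n_factors = len(self.factor_names)

        self.loading_slots: list[tuple[int, int, str]] = []   # (item, factor col, name)
        for c, f in enumerate(self.content_factors):
            for it in spec.factors[f]:
                self.loading_slots.append((idx[it], c, f"lambda[{it},{f}]"))
        if spec.general_factor:
            c = self.factor_names.index("G")
            for it in scheme.item_labels:
                self.loading_slots.append((idx[it], c, f"lambda[{it},G]"))
        if spec.method_items:
            c = self.factor_names.index("METHOD")
            for it in spec.method_items:
                self.loading_slots.append((idx[it], c, f"lambda[{it},METHOD]"))

        self.phi_slots: list[tuple[int, int, str]] = []
        if spec.correlated:
            for a in range(len(self.content_factors)):
                for b in range(a + 1, len(self.content_factors)):
                    self.phi_slots.append(
                        (a, b, f"phi[{self.content_factors[a]},{self.content_factors[b]}]"))

        self.resid_slots: list[tuple[int, int, str]] = [
            (idx[i], idx[j], f"theta[{i},{j}]") for i, j in spec.residual_pairs
        ]
        self.n_params = len(self.loading_slots) + len(self.phi_slots) + len(self.resid_slots)
        self.names = ([s[2] for s in self.loading_slots]
                      + [s[2] for s in self.phi_slots]
                      + [s[2] for s in self.resid_slots])
        self.tril = vech_indices(self.p)

    def split(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nl, nphi = len(self.loading_slots), len(self.phi_slots)
        return theta[:nl], theta[nl:nl + nphi], theta[nl + nphi:]

    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        lam, phi, res = self.split(theta)
        L = np.zeros((self.p, self.n_factors))
        for v, (i, c, _) in zip(lam, self.loading_slots):
            L[i, c] = v
        Phi = np.eye(self.n_factors)
        for v, (a, b, _) in zip(phi, self.phi_slots):
            Phi[a, b] = Phi[b, a] = v
        Theta = np.zeros((self.p, self.p))
        for v, (i, j, _) in zip(res, self.resid_slots):
            Theta[i, j] = Theta[j, i] = v
        return L, Phi, Theta

    def rho(self, theta: np.ndarray) -> np.ndarray:
        L, Phi, Theta = self.matrices(theta)
        S = L @ Phi @ L.T + Theta
        return S[self.tril]

    def jacobian(self, theta: np.ndarray) -> np.ndarray:
        L, Phi, _ = self.matrices(theta)
        M = L @ Phi                       # p x F; dΣ_ab/dλ_ic = δ_ai M_bc + δ_bi M_ac
        I, J = self.tril
        q = self.n_params
        Jac = np.zeros((I.size, q))
        col = 0
        for (i, c, _) in self.loading_slots:
            d = np.zeros(I.size)
            d[I == i] += M[J[I == i], c]
            d[J == i] += M[I[J == i], c]
            Jac[:, col] = d
            col += 1
        for (a, b, _) in self.phi_slots:
            Jac[:, col] = L[I, a] * L[J, b] + L[I, b] * L[J, a]
            col += 1
        for (i, j, _) in self.resid_slots:
            Jac[:, col] = ((I == i) & (J == j)) | ((I == j) & (J == i))
            col += 1
        return Jac

    def start(self) -> np.ndarray:
        x = np.concatenate([
            np.full(len(self.loading_slots), 0.5),
            np.full(len(self.phi_slots), 0.3),
            np.zeros(len(self.resid_slots)),
        ])
        return x

    def bounds(self, loading_bound: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
        lo = np.concatenate([
            np.full(len(self.loading_slots), -loading_bound),
            np.full(len(self.phi_slots), -0.999),
            np.full(len(self.resid_slots), -0.999),
        ])
        return lo, -lo


# ---------------------------------------------------------------------------
# results


@dataclass
class FitIndices:
    cfi: float
    rmsea: float
    rmsea_ci: tuple[float, float] | None    # None when not computable
    aic: float
    bic: float


@dataclass
class FitResult:
    model_name: str
    chi_square: float
    df: int
    theta: dict[str, float] = field(default_factory=dict)
    loadings: pd.DataFrame | None = None
    factor_corr: pd.DataFrame | None = None
    residual_correlations: dict[tuple[str, str], float] = field(default_factory=dict)
    uniquenesses: pd.Series | None = None
    indices: FitIndices | None = None
    srmr: float | None = None
    omegas: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    heywood: bool = False
    n_function_evals: int = 0
    gradient_norm: float = 0.0
    residuals: np.ndarray | None = None     # r - rho(theta_hat)

    @property
    def cfi(self) -> float | None:
        return self.indices.cfi if self.indices else None

    @property
    def rmsea(self) -> float | None:
        return self.indices.rmsea if self.indices else None


# ---------------------------------------------------------------------------
# fit statistics


def srmr(residuals: np.ndarray) -> float:
    """Root of the mean squared residual over the unique correlations."""
    residuals = np.asarray(residuals, dtype=float)
    return float(np.sqrt(np.mean(residuals**2)))


def omega(lam: np.ndarray, psi: np.ndarray) -> float:
    """McDonald's ω = (Σλ)² / ((Σλ)² + Σψ) for one factor's items."""
    lam = np.asarray(lam, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if lam.size == 0:
        raise ValueError("omega requires at least one item")
    s = lam.sum() ** 2
    return float(s / (s + psi.sum()))


def _rmsea_ci(chi2: float, df: int, N: int, level: float = 0.90) -> tuple[float, float] | None:
    """Noncentrality-inversion confidence interval for the RMSEA."""
    lo_p, hi_p = (1 + level) / 2, (1 - level) / 2   # 0.95, 0.05
    scale = df * (N - 1)

    def solve(target: float) -> float | None:
        f = lambda nc: stats.ncx2.cdf(chi2, df, nc) - target  # noqa: E731
        if f(0.0) <= 0:
            return 0.0
        hi = max(chi2, 1.0)
        for _ in range(60):
            if f(hi) < 0:
                break
            hi *= 2
        else:
            return None
        try:
            return float(optimize.brentq(f, 0.0, hi, xtol=1e-8))
        except ValueError:
            return None

    nc_lo, nc_hi = solve(lo_p), solve(hi_p)
    if nc_lo is None or nc_hi is None or not np.isfinite(nc_lo + nc_hi):
        return None
    return (float(np.sqrt(nc_lo / scale)), float(np.sqrt(nc_hi / scale)))


def fit_indices(chi_square: float, df: int, chi_square_baseline: float,
                df_baseline: int, N: int) -> FitIndices:
    """CFI, RMSEA (with 90% CI), AIC, and BIC from χ² statistics.

    The baseline is the independence model fitted to the same pooled
    input.  The RMSEA CI is flagged not computable (``rmsea_ci=None``)
    when the noncentral-χ² inversion fails.
    """
    d_t = max(chi_square - df, 0.0)
    d_0 = chi_square_baseline - df_baseline
    cfi = 1.0 - d_t / max(d_0, d_t, EPS_CFI)
    aic = chi_square - 2.0 * df
    bic = chi_square - np.log(N) * df
    if df <= 0:
        return FitIndices(cfi=cfi, rmsea=0.0, rmsea_ci=None, aic=aic, bic=bic)
    rmsea = float(np.sqrt(d_t / (df * (N - 1))))
    return FitIndices(cfi=cfi, rmsea=rmsea, rmsea_ci=_rmsea_ci(chi_square, df, N),
                      aic=aic, bic=bic)


def residual_correlation_summary(fit: FitResult) -> tuple[float, float, float]:
    """(min, max, median) of a fitted model's residual correlations."""
    if not fit.residual_correlations:
        raise ValueError(f"model {fit.model_name} has no residual correlations")
    vals = np.array(list(fit.residual_correlations.values()))
    return float(vals.min()), float(vals.max()), float(np.median(vals))


# ---------------------------------------------------------------------------
# engine


def _baseline_chi2(pooled: PooledCorrelation) -> float:
    c, low = cho_factor(pooled.acov, lower=True)
    r = pooled.r
    return float(r @ cho_solve((c, low), r))


def fit_wls(spec: ModelSpec, pooled: PooledCorrelation, *,
            scheme: ItemScheme | None = None, weight: str = "acov",
            n_starts: int = 5, seed: int = 0, with_indices: bool = True,
            gradient_rtol: float = 1e-4) -> FitResult:
    """Fit a measurement model to a pooled correlation matrix by WLS.

    ``weight='acov'`` uses the asymptotic covariance of the pooled
    correlations (the default, giving χ² = F̂); ``weight='identity'``
    gives unweighted least squares, useful for fitting a model to a
    single sample matrix where no weight matrix is available.

    Non-convergence after the multi-start schedule is reported through
    ``converged=False`` with diagnostics, not an exception; implied
    communalities above one raise a Heywood warning flag.
    """
    scheme = scheme or default_scheme()
    p = scheme.n_items
    n_unique = p * (p - 1) // 2
    r = pooled.r

    if spec.kind == "saturated":
        return FitResult(model_name=spec.name, chi_square=0.0, df=0,
                         residuals=np.zeros(n_unique), srmr=0.0)
    if spec.kind == "independence":
        chi2 = _baseline_chi2(pooled) if weight == "acov" else float(r @ r)
        res = FitResult(model_name=spec.name, chi_square=chi2, df=n_unique,
                        residuals=r.copy(), srmr=srmr(r))
        if with_indices:
            res.indices = fit_indices(chi2, n_unique, chi2, n_unique, pooled.total_N)
        return res

    par = _Parameterization(spec, scheme)
    df = n_unique - par.n_params
    if df < 0:
        raise ValueError(f"model {spec.name} is not identified (df={df})")

    if weight == "acov":
        A = cholesky(pooled.acov, lower=True)
        whiten = lambda v: solve_triangular(A, v, lower=True)  # noqa: E731
    elif weight == "identity":
        whiten = lambda v: v  # noqa: E731
    else:
        raise ValueError(f"unknown weight {weight!r}")

    def resid(theta: np.ndarray) -> np.ndarray:
        return whiten(r - par.rho(theta))

    def jac(theta: np.ndarray) -> np.ndarray:
        return -whiten(par.jacobian(theta))

    lo, hi = par.bounds()
    rng = np.random.default_rng(seed)
    base = par.start()
    starts = [base] + [
        np.clip(base + rng.uniform(-0.1, 0.1, size=base.size), lo + 1e-6, hi - 1e-6)
        for _ in range(max(0, n_starts - 1))
    ]
    best = None
    nfev = 0
    for x0 in starts:
        sol = optimize.least_squares(resid, x0, jac=jac, bounds=(lo, hi), method="trf",
                                     xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000)
        nfev += sol.nfev
        if best is None or sol.cost < best.cost:
            best = sol

    theta = best.x
    chi2 = float(2.0 * best.cost)
    e = best.fun
    g = best.jac.T @ e
    grad_norm = float(np.abs(g).max())
    converged = bool(best.status > 0 and grad_norm <= gradient_rtol * max(1.0, chi2))

    L, Phi, _ = par.matrices(theta)
    communality = np.einsum("if,fg,ig->i", L, Phi, L)
    psi = 1.0 - communality
    heywood = bool(np.any(communality > 1.0 + 1e-8) or np.any(np.abs(L) > 1.0 + 1e-8))
    if heywood:
        warnings.warn(f"model {spec.name}: Heywood case (communality or |loading| > 1)",
                      stacklevel=2)

    nl, nphi = len(par.loading_slots), len(par.phi_slots)
    loadings = pd.DataFrame(L, index=list(scheme.item_labels), columns=par.factor_names)
    factor_corr = pd.DataFrame(Phi, index=par.factor_names, columns=par.factor_names)
    resid_cor = {
        (i, j): float(v)
        for v, (_, _, name), (i, j) in zip(theta[nl + nphi:], par.resid_slots,
                                           spec.residual_pairs)
    }
    omegas = {}
    for f in par.content_factors:
        items = list(spec.factors[f])
        ix = [scheme.index[it] for it in items]
        omegas[f] = omega(L[ix, par.factor_names.index(f)], psi[ix])

    raw_resid = r - par.rho(theta)
    out = FitResult(
        model_name=spec.name,
        chi_square=chi2,
        df=df,
        theta=dict(zip(par.names, map(float, theta))),
        loadings=loadings,
        factor_corr=factor_corr,
        residual_correlations=resid_cor,
        uniquenesses=pd.Series(psi, index=list(scheme.item_labels)),
        srmr=srmr(raw_resid),
        omegas=omegas,
        converged=converged,
        heywood=heywood,
        n_function_evals=nfev,
        gradient_norm=grad_norm,
        residuals=raw_resid,
    )
    if with_indices and weight == "acov":
        out.indices = fit_indices(chi2, df, _baseline_chi2(pooled), n_unique, pooled.total_N)
    return out
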