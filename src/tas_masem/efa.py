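"""Exploratory analyses on the pooled correlation matrix.

Factor-number criteria (Velicer's minimum average partial, Horn's
parallel analysis, sample-size-adjusted BIC, sequential χ² tests of
exact fit) and the top-down "bass-ackwards" hierarchy of varimax-rotated
principal-component solutions of increasing dimensionality, linked by
component-score correlations across adjacent levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.multivariate.factor import Factor
from statsmodels.multivariate.factor_rotation import rotate_factors

__all__ = [
    "FactorNumberReport",
    "BassAckwardsLevels",
    "map_test",
    "parallel_analysis",
    "sequential_criteria",
    "bass_ackwards",
]


@dataclass
class FactorNumberReport:
    map_suggestion: int
    parallel_suggestion: int
    sabic_suggestion: int
    seq_chisq_suggestion: int
    traces: dict[str, np.ndarray] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# factor-number criteria


def _pca_loadings(R: np.ndarray, m: int) -> np.ndarray:
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, V = w[order][:m], V[:, order][:, :m]
    return V * np.sqrt(np.clip(w, 0, None))


def map_test(R: np.ndarray, max_factors: int | None = None) -> tuple[int, np.ndarray]:
    """Velicer's minimum average partial test.

    For m = 0..max, the average squared partial correlation after
    partialling out the first m principal components; the suggestion is
    the argmin over m >= 1.  When the trace is minimal at m = 0 the
    matrix has no common-component structure (flagged by suggestion 0).
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    max_factors = max_factors or p - 2
    off = ~np.eye(p, dtype=bool)
    trace = np.full(max_factors + 1, np.nan)
    trace[0] = np.mean(R[off] ** 2)
    for m in range(1, max_factors + 1):
        L = _pca_loadings(R, m)
        C = R - L @ L.T
        d = np.diag(C).copy()
        if np.any(d < 1e-10):
            break
        P = C / np.sqrt(np.outer(d, d))
        trace[m] = np.mean(P[off] ** 2)
    valid = np.where(np.isfinite(trace))[0]
    pos = valid[valid >= 1]
    if pos.size == 0 or trace[0] <= trace[int(pos[np.argmin(trace[pos])])]:
        warnings.warn("average partial correlations are minimal before any component "
                      "is removed: no common factors", stacklevel=2)
        return 0, trace
    return int(pos[np.argmin(trace[pos])]), trace


def parallel_analysis(R: np.ndarray, N: int, *, n_reps: int = 100,
                      quantile: float | None = None,
                      seed: int = 0) -> tuple[int, dict[str, np.ndarray]]:
    """Horn's parallel analysis with the mean-eigenvalue rule.

    Components are retained while the observed eigenvalue exceeds the
    mean (or, if ``quantile`` is given, that quantile of the) eigenvalue
    of correlation matrices of N x p standard-normal data at the matched
    position.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if N <= p or n_reps <= 0:
        raise ValueError("need N > p and n_reps > 0")
    obs = np.sort(np.linalg.eigvalsh(R))[::-1]
    rng = np.random.default_rng(seed)
    sims = np.empty((n_reps, p))
    for rep in range(n_reps):
        X = rng.standard_normal((N, p))
        sims[rep] = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    ref = np.mean(sims, axis=0) if quantile is None else np.quantile(sims, quantile, axis=0)
    keep = obs > ref
    suggestion = int(np.argmin(keep)) if not keep.all() else p
    return suggestion, {"observed": obs, "reference": ref}


def _ml_discrepancy(R: np.ndarray, loadings: np.ndarray, uniqueness: np.ndarray) -> float:
    Sigma = loadings @ loadings.T + np.diag(uniqueness)
    p = R.shape[0]
    _, ld_s = np.linalg.slogdet(Sigma)
    _, ld_r = np.linalg.slogdet(R)
    return float(ld_s + np.trace(np.linalg.solve(Sigma, R)) - ld_r - p)


def sequential_criteria(R: np.ndarray, N: int, max_factors: int = 6,
                        *, alpha: float = 0.05,
                        ) -> tuple[int, int, dict[str, np.ndarray]]:
    """Sample-size-adjusted BIC and sequential χ² exact-fit tests.

    ML exploratory factor models for m = 1..max_factors;
    χ²_m = (N − 1 − (2p+5)/6 − 2m/3) · F_m with df_m = ((p−m)² − (p+m))/2.
    SABIC_m = χ²_m − df_m · ln((N+2)/24) is minimized; the sequential
    test suggests the smallest m whose exact-fit test is non-significant
    at ``alpha``.  Non-converged solutions are flagged (NaN in the trace)
    and skipped.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    chi2s = np.full(max_factors + 1, np.nan)
    dfs = np.full(max_factors + 1, np.nan)
    pvals = np.full(max_factors + 1, np.nan)
    sabic = np.full(max_factors + 1, np.nan)
    for m in range(1, max_factors + 1):
        df = ((p - m) ** 2 - (p + m)) / 2
        if df < 0:
            break
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = Factor(corr=R, n_factor=m, method="ml").fit()
            F = _ml_discrepancy(R, res.loadings, res.uniqueness)
        except Exception:
            continue
        chi2 = max(N - 1 - (2 * p + 5) / 6 - 2 * m / 3, 1.0) * F
        chi2s[m], dfs[m] = chi2, df
        pvals[m] = stats.chi2.sf(chi2, df) if df > 0 else np.nan
        sabic[m] = chi2 - df * np.log((N + 2) / 24.0)
    traces = {"chi2": chi2s, "df": dfs, "p": pvals, "sabic": sabic}
    valid = np.where(np.isfinite(sabic))[0]
    if valid.size == 0:
        raise RuntimeError("no exploratory factor solution converged")
    sabic_suggestion = int(valid[np.argmin(sabic[valid])])
    ns = np.where(pvals > alpha)[0]
    seq_suggestion = int(ns[0]) if ns.size else int(valid[-1])
    return sabic_suggestion, seq_suggestion, traces


# ---------------------------------------------------------------------------
# bass-ackwards hierarchy


@dataclass
class BassAckwardsLevels:
    """Varimax-rotated component solutions of increasing dimensionality.

    ``loadings[l-1]`` is the p x l rotated component loading matrix at
    level l; ``cross_level_corr[l-1]`` is the l x (l+1) matrix of
    component-score correlations between levels l and l+1 (regression
    scores, unit variance); ``variance_explained[l-1]`` is the fraction
    of total variance the level accounts for.
    """

    loadings: list[np.ndarray]
    weights: list[np.ndarray]
    cross_level_corr: list[np.ndarray]
    variance_explained: list[float]

    def edges(self, *, solid: float = 0.50, minimum: float = 0.30) -> list[dict]:
        """Edge list between adjacent levels, omitting |r| below ``minimum``.

        Edges with |r| below ``solid`` are styled dashed, mirroring the
        usual rendering of the hierarchy.
        """
        out = []
        for lev, C in enumerate(self.cross_level_corr, start=1):
            for a in range(C.shape[0]):
                for b in range(C.shape[1]):
                    r = float(C[a, b])
                    if abs(r) >= minimum:
                        out.append({
                            "from": f"L{lev}C{a + 1}", "to": f"L{lev + 1}C{b + 1}",
                            "r": round(r, 3),
                            "style": "solid" if abs(r) >= solid else "dashed",
                        })
        return out


def _fix_signs(L: np.ndarray) -> np.ndarray:
    """Make each component's largest-magnitude loading positive."""
    L = L.copy()
    for c in range(L.shape[1]):
        j = np.argmax(np.abs(L[:, c]))
        if L[j, c] < 0:
            L[:, c] = -L[:, c]
    return L


def bass_ackwards(R: np.ndarray, L_max: int = 4) -> BassAckwardsLevels:
    """Top-down hierarchy of varimax-rotated principal components.

    At each level l the first l principal components are varimax-rotated
    (level 1 has nothing to rotate); component scores are defined by the
    regression weights W = R⁻¹Λ scaled to unit variance, which makes the
    within-level score correlations exactly zero for an orthogonal
    rotation.  Adjacent levels are linked by WₗᵀRWₗ₊₁.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if not 1 <= L_max <= p:
        raise ValueError("L_max must be between 1 and the number of items")
    loadings: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    variance: list[float] = []
    for level in range(1, L_max + 1):
        A = _pca_loadings(R, level)
        if level > 1:
            A, _ = rotate_factors(A, "varimax")
            # order rotated components by explained variance
            A = A[:, np.argsort(-(A**2).sum(axis=0))]
        A = _fix_signs(A)
        W = np.linalg.solve(R, A)
        scale = np.sqrt(np.einsum("ij,ik,kj->j", W, R, W))
        W = W / scale
        loadings.append(A)
        weights.append(W)
        variance.append(float((A**2).sum() / p))
    cross = [weights[l].T @ R @ weights[l + 1] for l in range(L_max - 1)]
    return BassAckwardsLevels(loadings=loadings, weights=weights,
                              cross_level_corr=cross, variance_explained=variance)
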