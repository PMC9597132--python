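"""Stage 1 of the two-stage meta-analytic SEM: fixed-effects pooling.

Under a fixed-effects model every sample shares one population
correlation matrix; studies differ only by sampling error, so each
unique correlation is pooled as the sample-size-weighted mean

    r̄_jk = Σ_i n_i r_ijk / Σ_i n_i .

Stage 2 needs the asymptotic covariance of the 190 pooled unique
correlations as its WLS weight matrix; it is evaluated with the
normal-theory (Olkin–Siotani / Pearson–Filon) formula at the pooled
values and scaled by 1/ΣN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .corpus import StudyRecord
from .reconstruct import resolve_correlation

__all__ = [
    "PooledCorrelation",
    "pool",
    "asymptotic_covariance",
    "vech_indices",
    "vech",
]


def vech_indices(p: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the unique off-diagonal correlations.

    Fixed ordering used everywhere in the package: row-major lower
    triangle (2,1), (3,1), (3,2), ... (0-based: (1,0), (2,0), (2,1), ...).
    """
    return np.tril_indices(p, k=-1)


def vech(R: np.ndarray) -> np.ndarray:
    """Stack the unique off-diagonal entries of a symmetric matrix."""
    i, j = vech_indices(R.shape[0])
    return R[i, j]


@dataclass
class PooledCorrelation:
    """Fixed-effects pooled correlation matrix with its WLS weight input."""

    R: np.ndarray            # p x p pooled correlation matrix, unit diagonal
    total_N: int
    acov: np.ndarray         # p(p-1)/2 square covariance of the pooled r's
    k: int                   # number of pooled samples
    group_label: str | None = None

    @property
    def r(self) -> np.ndarray:
        """Pooled unique correlations in the package's fixed ordering."""
        return vech(self.R)

    @property
    def n_unique(self) -> int:
        return self.acov.shape[0]


def asymptotic_covariance(R: np.ndarray, N: int) -> np.ndarray:
    """Normal-theory covariance of the unique Pearson correlations.

    For multivariate-normal data with correlation matrix ρ,

      N·cov(r_ij, r_kl) = ½ ρ_ij ρ_kl (ρ_ik² + ρ_il² + ρ_jk² + ρ_jl²)
                          + ρ_ik ρ_jl + ρ_il ρ_jk
                          − ρ_ij (ρ_jk ρ_jl + ρ_ik ρ_il)
                          − ρ_kl (ρ_jk ρ_ik + ρ_jl ρ_il),

    which gives the familiar diagonal (1 − ρ_jk²)² / N.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if N <= p:
        raise ValueError(f"N={N} too small for p={p} variables")
    if np.linalg.eigvalsh(R).min() <= 0:
        raise ValueError(
            "correlation matrix is not positive definite; repair it "
            "(e.g. corpus.nearest_correlation) before computing the covariance"
        )
    I, J = vech_indices(p)
    # broadcast: rows index pair (i,j), columns pair (k,l)
    i, j = I[:, None], J[:, None]
    k, l = I[None, :], J[None, :]
    r_ij, r_kl = R[i, j], R[k, l]
    r_ik, r_il, r_jk, r_jl = R[i, k], R[i, l], R[j, k], R[j, l]
    cov = (
        0.5 * r_ij * r_kl * (r_ik**2 + r_il**2 + r_jk**2 + r_jl**2)
        + r_ik * r_jl + r_il * r_jk
        - r_ij * (r_jk * r_jl + r_ik * r_il)
        - r_kl * (r_jk * r_ik + r_jl * r_il)
    ) / N
    return (cov + cov.T) / 2.0


def pool(records: Sequence[StudyRecord],
         reconstructor: Callable[[StudyRecord], np.ndarray] = resolve_correlation,
         *, group_label: str | None = None) -> PooledCorrelation:
    """Pool study correlation matrices under the fixed-effects model.

    Every record is resolved to a full correlation matrix (directly, or
    via model-implied reconstruction from its reported pattern), then
    averaged with weights n_i.  The asymptotic covariance is evaluated
    at the pooled matrix with N = Σ n_i, matching the point at which the
    stage-2 WLS discrepancy is evaluated.
    """
    if not records:
        raise ValueError("cannot pool an empty corpus")
    num = None
    total_n = 0
    for rec in records:
        try:
            R_i = reconstructor(rec)
        except Exception as exc:
            raise ValueError(f"sample {rec.sample_id}: cannot resolve correlations ({exc})") from exc
        num = rec.n * R_i if num is None else num + rec.n * R_i
        total_n += rec.n
    R = num / total_n
    np.fill_diagonal(R, 1.0)
    if np.linalg.eigvalsh(R).min() <= 0:
        warnings.warn("pooled correlation matrix is not positive definite", stacklevel=2)
    acov = asymptotic_covariance(R, total_n)
    return PooledCorrelation(R=R, total_N=total_n, acov=acov, k=len(records),
                             group_label=group_label)
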