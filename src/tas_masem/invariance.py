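"""Configural measurement invariance across study subgroups.

Groups (language versions, clinical status) are pooled and fitted
separately with the same measurement model; comparability is assessed
descriptively through per-group fit statistics and differences in
standardized loadings against a reference group (Δλ), not through
equality-constrained simultaneous estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cfa import FitResult, fit_wls
from .corpus import StudyRecord
from .items import ItemScheme, default_scheme
from .models import ModelSpec
from .pooling import pool
from .reconstruct import resolve_correlation

__all__ = ["GroupFitTable", "LoadingDeltaTable", "group_analysis", "loading_deltas"]

log = logging.getLogger(__name__)


@dataclass
class GroupFitTable:
    """Per-group pool-and-fit results for one measurement model."""

    table: pd.DataFrame                 # rows: group; cols: k, n, chi2, df, cfi, ...
    fits: dict[str, FitResult]
    model_name: str
    grouping_key: str


@dataclass
class LoadingDeltaTable:
    """Per-item loading differences against a reference group."""

    loadings: pd.DataFrame              # items x groups, primary-factor loadings
    deltas: pd.DataFrame                # items x non-reference groups
    group_summary: pd.DataFrame         # mean |delta|, min, max per group
    item_means: pd.Series               # mean delta per item across groups
    reference: str


def group_analysis(records: Sequence[StudyRecord], grouping_key: str,
                   spec: ModelSpec, *, min_samples: int = 5,
                   scheme: ItemScheme | None = None,
                   reconstructor: Callable = resolve_correlation,
                   seed: int = 0) -> GroupFitTable:
    """Pool and fit one model per group of a grouping variable.

    Groups with fewer than ``min_samples`` samples are excluded (logged).
    A group whose pooled weight matrix is singular gets a flagged row
    with NaN statistics rather than aborting the analysis.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    scheme = scheme or default_scheme()
    groups: dict[str, list[StudyRecord]] = {}
    for rec in records:
        groups.setdefault(getattr(rec, grouping_key), []).append(rec)

    rows = []
    fits: dict[str, FitResult] = {}
    order = sorted(groups, key=lambda g: (-len(groups[g]), g))
    for label in order:
        members = groups[label]
        if len(members) < min_samples:
            log.info("group %r excluded: only %d sample(s) (< %d)",
                     label, len(members), min_samples)
            continue
        row: dict = {"group": label, "k": len(members),
                     "n": sum(r.n for r in members)}
        try:
            pooled = pool(members, reconstructor, group_label=label)
            fit = fit_wls(spec, pooled, scheme=scheme, seed=seed)
        except (np.linalg.LinAlgError, ValueError) as exc:
            log.warning("group %r flagged: %s", label, exc)
            row.update({"flagged": True})
            rows.append(row)
            continue
        fits[label] = fit
        ci = fit.indices.rmsea_ci if fit.indices else None
        row.update({
            "chi2": fit.chi_square, "df": fit.df,
            "cfi": fit.cfi, "rmsea": fit.rmsea,
            "rmsea_lo": ci[0] if ci else np.nan,
            "rmsea_hi": ci[1] if ci else np.nan,
            "srmr": fit.srmr,
            **{f"omega_{f}": v for f, v in fit.omegas.items()},
            "converged": fit.converged, "flagged": False,
        })
        rows.append(row)
    table = pd.DataFrame(rows).set_index("group")
    return GroupFitTable(table=table, fits=fits, model_name=spec.name,
                         grouping_key=grouping_key)


def _primary_loadings(fit: FitResult, spec: ModelSpec) -> pd.Series:
    """Each item's standardized loading on its assigned content factor."""
    out = {}
    for factor, items in spec.factors.items():
        for it in items:
            out[it] = float(fit.loadings.loc[it, factor])
    return pd.Series(out).sort_index()


def loading_deltas(fits: dict[str, FitResult], reference: str,
                   spec: ModelSpec) -> LoadingDeltaTable:
    """Δλ = λ_group − λ_reference, per item and per group.

    All fits must come from the same model specification; a mismatch in
    the loading layout raises.
    """
    if reference not in fits:
        raise ValueError(f"reference group {reference!r} has no fit")
    lam = {}
    for label, fit in fits.items():
        if not fit.converged:
            log.warning("group %r fit did not converge; deltas may be unreliable", label)
        if list(fit.loadings.columns[:len(spec.factors)]) != list(spec.factors):
            raise ValueError(f"group {label!r} was fitted with a different factor layout")
        lam[label] = _primary_loadings(fit, spec)
    loadings = pd.DataFrame(lam)
    others = [g for g in loadings.columns if g != reference]
    deltas = loadings[others].sub(loadings[reference], axis=0)
    group_summary = pd.DataFrame({
        "mean_abs_delta": deltas.abs().mean(),
        "min": deltas.min(),
        "max": deltas.max(),
    })
    item_means = deltas.mean(axis=1)
    return LoadingDeltaTable(loadings=loadings, deltas=deltas,
                             group_summary=group_summary, item_means=item_means,
                             reference=reference)
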