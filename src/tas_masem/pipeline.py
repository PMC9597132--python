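"""End-to-end orchestration: corpus -> pooling -> EFA -> CFA -> invariance.

``run_full`` executes the whole workflow on a stored or simulated corpus
and writes a report bundle: the pooled matrix, a model-comparison table
(one row per fitted model plus the null baseline), per-group fit and
loading-difference tables, the EFA report, and a MANIFEST recording
seeds, versions, and stage completion.  Every report cell is copied
from a FitResult field; nothing is computed at formatting time.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cfa import FitResult, fit_wls
from .corpus import read_corpus, summarize, write_corpus
from .efa import FactorNumberReport, bass_ackwards, map_test, parallel_analysis, \
    sequential_criteria
from .invariance import group_analysis, loading_deltas
from .items import default_scheme
from .models import build_catalog
from .pooling import pool
from .simulate import default_population, generate_corpus

__all__ = ["RunConfig", "run_full", "fit_all_models", "comparison_table"]

log = logging.getLogger(__name__)

DEFAULT_MODELS = ["1", "2", "3a", "3b", "3c", "4", "5", "6", "7"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML round-trippable)."""

    seed: int = 0
    corpus_path: str | None = None      # coding sheet; None -> simulate
    out_dir: str = "masem_run"
    models: list[str] = field(default_factory=lambda: list(DEFAULT_MODELS))
    invariance_by: list[str] = field(default_factory=lambda: ["language", "clinical_status"])
    reference_group: str = "English"
    min_samples: int = 5
    efa_max_factors: int = 6
    parallel_reps: int = 100
    bass_levels: int = 4
    censor_threshold: float = 0.40
    edge_threshold: float = 0.30
    edge_solid: float = 0.50
    fit_cutoffs: dict = field(default_factory=lambda: {"cfi": 0.95, "rmsea": 0.08,
                                                       "srmr": 0.10})

    def __post_init__(self) -> None:
        for key, val in [("censor_threshold", self.censor_threshold),
                         ("edge_threshold", self.edge_threshold),
                         ("edge_solid", self.edge_solid)]:
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{key} must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def fit_all_models(pooled, model_names, *, catalog=None, scheme=None,
                   seed: int = 0) -> dict[str, FitResult]:
    scheme = scheme or default_scheme()
    catalog = catalog or build_catalog(scheme)
    return {name: fit_wls(catalog[name], pooled, scheme=scheme, seed=seed)
            for name in model_names}


def comparison_table(fits: dict[str, FitResult]) -> pd.DataFrame:
    """Model-comparison table shaped like the usual published fit table."""
    rows = []
    for name, fit in fits.items():
        ind = fit.indices
        rows.append({
            "model": name, "chi2": fit.chi_square, "df": fit.df,
            "cfi": ind.cfi if ind else np.nan,
            "rmsea": ind.rmsea if ind else np.nan,
            "rmsea_lo": ind.rmsea_ci[0] if ind and ind.rmsea_ci else np.nan,
            "rmsea_hi": ind.rmsea_ci[1] if ind and ind.rmsea_ci else np.nan,
            "srmr": fit.srmr,
            "aic": ind.aic if ind else np.nan,
            "bic": ind.bic if ind else np.nan,
            "converged": fit.converged,
            **{f"omega_{f}": v for f, v in fit.omegas.items()},
        })
    return pd.DataFrame(rows).set_index("model")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_full(config: RunConfig) -> dict:
    """Run the complete workflow; returns the report bundle as a dict.

    Stages: load or simulate the corpus, summarize, pool, EFA report,
    fit the selected models plus the null baseline, invariance analyses.
    Partial outputs are preserved on failure; the MANIFEST records which
    stages completed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = default_scheme()
    catalog = build_catalog(scheme)
    manifest = {"version": __version__, "seed": config.seed, "stages": [],
                "config": dataclasses.asdict(config)}
    bundle: dict = {}
    try:
        if config.corpus_path is None:
            pop = default_population(seed=config.seed,
                                     censor_threshold=config.censor_threshold)
            records, truth = generate_corpus(pop, scheme)
            write_corpus(records, out / "corpus", scheme)
            _write_json(truth, out / "corpus" / "truth.json")
            manifest["stages"].append("simulate")
        else:
            records = read_corpus(config.corpus_path, scheme=scheme)
            manifest["stages"].append("read")

        summary = summarize(records)
        bundle["summary"] = dataclasses.asdict(summary)
        _write_json(bundle["summary"], out / "corpus_summary.json")
        manifest["stages"].append("summarize")

        pooled = pool(records)
        pd.DataFrame(pooled.R, index=list(scheme.item_labels),
                     columns=list(scheme.item_labels)).to_csv(
            out / "pooled_correlations.csv", float_format="%.10g")
        bundle["pooled"] = pooled
        manifest["stages"].append("pool")

        efa_report = _efa_stage(pooled, config)
        bundle["efa"] = efa_report
        _write_json(efa_report["json"], out / "efa_report.json")
        manifest["stages"].append("efa")

        fits = fit_all_models(pooled, config.models, catalog=catalog, scheme=scheme,
                              seed=config.seed)
        fits["independence"] = fit_wls(catalog["independence"], pooled, scheme=scheme)
        table = comparison_table(fits)
        table.to_csv(out / "model_comparison.csv", float_format="%.6g")
        bundle["fits"], bundle["model_comparison"] = fits, table
        manifest["stages"].append("fit")

        bundle["invariance"] = {}
        for key in config.invariance_by:
            sub = records
            if key == "clinical_status":
                sub = [r for r in records if r.language == config.reference_group]
            gt = group_analysis(sub, key, catalog["3a"], min_samples=config.min_samples,
                                scheme=scheme, seed=config.seed)
            gt.table.to_csv(out / f"invariance_{key}.csv", float_format="%.6g")
            entry: dict = {"table": gt.table, "fits": gt.fits}
            ref = (config.reference_group if key == "language" else
                   ("nonclinical" if "nonclinical" in gt.fits else None))
            if ref in gt.fits:
                ld = loading_deltas(gt.fits, ref, catalog["3a"])
                ld.deltas.to_csv(out / f"loading_deltas_{key}.csv", float_format="%.6g")
                entry["deltas"] = ld
            bundle["invariance"][key] = entry
        manifest["stages"].append("invariance")
        manifest["status"] = "complete"
    finally:
        _write_json(manifest, out / "MANIFEST.json")
    bundle["manifest"] = manifest
    return bundle


def _efa_stage(pooled, config: RunConfig) -> dict:
    R, N = pooled.R, pooled.total_N
    map_m, map_trace = map_test(R)
    par_m, par_trace = parallel_analysis(R, N, n_reps=config.parallel_reps,
                                         seed=config.seed)
    sabic_m, seq_m, seq_traces = sequential_criteria(R, N,
                                                     max_factors=config.efa_max_factors)
    report = FactorNumberReport(
        map_suggestion=map_m, parallel_suggestion=par_m,
        sabic_suggestion=sabic_m, seq_chisq_suggestion=seq_m,
        traces={"map": map_trace, **{f"parallel_{k}": v for k, v in par_trace.items()},
                **seq_traces},
    )
    ba = bass_ackwards(R, L_max=config.bass_levels)
    as_json = {
        "map_suggestion": map_m, "parallel_suggestion": par_m,
        "sabic_suggestion": sabic_m, "seq_chisq_suggestion": seq_m,
        "level1_variance_explained": ba.variance_explained[0],
        "variance_explained": ba.variance_explained,
        "edges": ba.edges(solid=config.edge_solid, minimum=config.edge_threshold),
    }
    return {"report": report, "bass_ackwards": ba, "json": as_json}
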