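"""Synthetic meta-analytic corpora with known population structure.

The generator emulates the evidence base the pipeline is built for:
~88 samples with lognormal sample sizes (median 327), a three-
correlated-factor population with weak residual correlations among the
reverse-keyed items, per-language loading perturbations for translated
versions, and primary-study reporting that returns either a raw
correlation matrix, a censored EFA pattern (loadings below .40
suppressed), or a CFA pattern with factor correlations.  Every draw is
reproducible from a single seed, and a truth record retains all
population parameters for recovery tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml
from statsmodels.multivariate.factor import Factor
from statsmodels.multivariate.factor_rotation import rotate_factors

from .corpus import StudyRecord
from .items import ItemScheme, default_scheme, item_label
from .models import build_catalog
from .pooling import PooledCorrelation
from .reconstruct import FactorSolution

__all__ = [
    "PopulationSpec",
    "default_population",
    "population_matrix",
    "sample_study",
    "degrade_to_pattern",
    "generate_corpus",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Population parameters and corpus composition for the generator."""

    loadings: dict[str, float]                  # item label -> primary loading
    phi: np.ndarray                             # factor correlations (DIF, DDF, EOT order)
    residual_correlation: float = 0.0           # among reverse-keyed item pairs
    group_perturbations: dict[str, dict[str, float]] = field(default_factory=dict)
    clinical_perturbation: dict[str, float] = field(default_factory=dict)
    k: int = 88
    n_median: int = 327
    n_sigma: float = 1.2
    n_range: tuple[int, int] = (99, 12_706)
    reporting_mix: dict[str, float] = field(
        default_factory=lambda: {"raw_correlations": 1.0, "efa_pattern": 0.0,
                                 "cfa_pattern": 0.0})
    censor_threshold: float = 0.40
    efa_factors: int = 3                        # factors extracted by "EFA studies"
    cfa_reported_model: str | None = None       # catalog model "CFA studies" report;
                                                # None -> the partition's plain model
    languages: dict[str, int] = field(default_factory=lambda: {"English": 88})
    english_clinical_samples: int = 0
    other_clinical_rate: float = 0.0
    seed: int = 0
    partition: str = "three_factor"

    def __post_init__(self) -> None:
        total = sum(self.reporting_mix.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError("reporting_mix proportions must sum to 1")
        object.__setattr__(self, "phi", np.asarray(self.phi, dtype=float))


def default_population(seed: int = 0, **overrides) -> PopulationSpec:
    """The packaged default population (data/population.yaml)."""
    with resources.files("tas_masem.data").joinpath("population.yaml").open("r") as fh:
        cfg = yaml.safe_load(fh)
    spec = PopulationSpec(
        loadings={item_label(int(i)): float(v) for i, v in cfg["loadings"].items()},
        phi=np.array(cfg["factor_correlations"], dtype=float),
        residual_correlation=float(cfg["residual_correlation"]),
        group_perturbations={
            lang: {item_label(int(i)): float(v) for i, v in (pert or {}).items()}
            for lang, pert in cfg["group_perturbations"].items()
        },
        clinical_perturbation={item_label(int(i)): float(v)
                               for i, v in cfg["clinical"]["perturbation"].items()},
        k=int(cfg["k"]),
        efa_factors=int(cfg["efa_factors"]),
        cfa_reported_model=str(cfg["cfa_reported_model"]),
        n_median=int(cfg["n_median"]),
        n_sigma=float(cfg["n_sigma"]),
        n_range=tuple(cfg["n_range"]),
        reporting_mix={k: float(v) for k, v in cfg["reporting_mix"].items()},
        censor_threshold=float(cfg["censor_threshold"]),
        languages={k: int(v) for k, v in cfg["languages"].items()},
        english_clinical_samples=int(cfg["clinical"]["english_clinical_samples"]),
        other_clinical_rate=float(cfg["clinical"]["other_clinical_rate"]),
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


def _lambda_matrix(spec: PopulationSpec, scheme: ItemScheme,
                   offsets: dict[str, float]) -> np.ndarray:
    partition = scheme.partition(spec.partition)
    factors = list(partition)
    L = np.zeros((scheme.n_items, len(factors)))
    primary = scheme.primary_factor(spec.partition)
    for it, lam in spec.loadings.items():
        L[scheme.index[it], factors.index(primary[it])] = lam + offsets.get(it, 0.0)
    return L


def population_matrix(spec: PopulationSpec, group: str | None = None, *,
                      clinical: bool = False,
                      scheme: ItemScheme | None = None) -> np.ndarray:
    """Population correlation matrix for one group.

    ΛΦΛᵀ plus the residual-correlation overlay among reverse-keyed
    items, diagonal set to 1.  Group (and clinical) loading offsets are
    applied to the primary loadings before the product.
    """
    scheme = scheme or default_scheme()
    offsets = dict(spec.group_perturbations.get(group or "", {}))
    if clinical:
        for it, v in spec.clinical_perturbation.items():
            offsets[it] = offsets.get(it, 0.0) + v
    L = _lambda_matrix(spec, scheme, offsets)
    R = L @ spec.phi @ L.T
    if spec.residual_correlation:
        neg = sorted(scheme.negative_keyed)
        for a in range(len(neg)):
            for b in range(a + 1, len(neg)):
                i, j = scheme.index[neg[a]], scheme.index[neg[b]]
                R[i, j] += spec.residual_correlation
                R[j, i] = R[i, j]
    np.fill_diagonal(R, 1.0)
    if np.linalg.eigvalsh(R).min() <= 0:
        raise ValueError(
            f"population matrix for group {group!r} (clinical={clinical}) "
            "is not positive definite; reduce the perturbations")
    return R


def sample_study(R_pop: np.ndarray, n: int, seed: int) -> np.ndarray:
    """Pearson correlation matrix of n multivariate-normal draws from R_pop."""
    if n <= R_pop.shape[0] + 1:
        raise ValueError("n must exceed the number of items + 1")
    rng = np.random.default_rng(seed)
    C = np.linalg.cholesky(R_pop)
    X = rng.standard_normal((n, R_pop.shape[0])) @ C.T
    return np.corrcoef(X, rowvar=False)


def degrade_to_pattern(R_sample: np.ndarray, m: int, rotation: str = "varimax",
                       censor_threshold: float = 0.0, seed: int = 0) -> FactorSolution:
    """Reduce a sample matrix to a reported EFA pattern.

    Principal-axis extraction of m factors with the named rotation
    (``varimax`` orthogonal, ``quartimin`` oblique with factor
    correlations attached).  Loadings of magnitude below
    ``censor_threshold`` are marked censored (NaN), mimicking primary
    studies that suppress small loadings.
    """
    if m < 1:
        raise ValueError("need at least one factor")
    R_sample = np.asarray(R_sample, dtype=float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = Factor(corr=R_sample, n_factor=m, method="pa").fit()
        A = np.asarray(res.loadings)
    except Exception as exc:
        raise RuntimeError(f"principal-axis extraction failed (seed={seed}): {exc}") from exc
    if m == 1:
        L, phi = A, np.eye(1)
    elif rotation == "varimax":
        L, _ = rotate_factors(A, "varimax")
        phi = np.eye(m)
    elif rotation == "quartimin":
        L, T = rotate_factors(A, "quartimin")
        phi = T.T @ T
        d = np.sqrt(np.diag(phi))
        L = L * d
        phi = phi / np.outer(d, d)
        np.fill_diagonal(phi, 1.0)
    else:
        raise ValueError(f"unknown rotation {rotation!r}")
    L = L.copy()
    if censor_threshold > 0:
        L[np.abs(L) < censor_threshold] = np.nan
    return FactorSolution(loadings=L, phi=phi,
                          censor_threshold=censor_threshold or None)


def _cfa_pattern(R_sample: np.ndarray, n: int, scheme: ItemScheme,
                 partition: str, model_name: str | None) -> tuple[np.ndarray, np.ndarray]:
    """Reported CFA loadings and factor correlations for one sample.

    Emulates a primary study reporting the standardized solution of a
    fitted confirmatory model (by default the richest structure that
    matches the population: content factors plus overlays), obtained by
    unweighted least squares on the sample matrix — within one study no
    weight matrix exists.  Any residual correlations of the fitted model
    are dropped: a loading pattern cannot carry them, which is exactly
    the information loss reconstruction-based coding suffers.
    """
    from .cfa import fit_wls  # local import to avoid a cycle

    catalog = build_catalog(scheme)
    if model_name is not None:
        spec = catalog[model_name]
    else:
        partition_map = scheme.partition(partition)
        spec = next(s for s in catalog
                    if s.kind == "measurement" and not s.general_factor
                    and not s.method_items and not s.residual_pairs
                    and s.factors == partition_map)
    pooled = PooledCorrelation(R=R_sample, total_N=n,
                               acov=np.eye(scheme.n_items * (scheme.n_items - 1) // 2),
                               k=1)
    with warnings.catch_warnings():
        # small-n studies occasionally yield Heywood solutions; the report
        # is clipped to the admissible range below, as primary authors do
        warnings.simplefilter("ignore")
        fit = fit_wls(spec, pooled, scheme=scheme, weight="identity",
                      n_starts=1, with_indices=False)
    factors = list(fit.loadings.columns)
    L = fit.loadings[factors].to_numpy()
    Phi = fit.factor_corr.loc[factors, factors].to_numpy()
    return np.clip(L, -1.0, 1.0), Phi


def _truncated_lognormal(rng: np.random.Generator, median: float, sigma: float,
                         lo: float, hi: float, size: int) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = np.exp(np.log(median) + sigma * rng.standard_normal(size))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, size - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return np.round(out).astype(int)


def generate_corpus(spec: PopulationSpec,
                    scheme: ItemScheme | None = None) -> tuple[list[StudyRecord], dict]:
    """Generate k study records plus a truth record of the population.

    Sample sizes are lognormal (median ``n_median``, dispersion
    ``n_sigma``) truncated to ``n_range``; languages follow the
    configured counts; the source kind of each sample is multinomial
    with the configured reporting mix.  EFA patterns are oblique
    (quartimin) three-factor solutions censored at the configured
    threshold; CFA patterns are uncensored simple-structure solutions.
    """
    scheme = scheme or default_scheme()
    rng = np.random.default_rng(spec.seed)

    langs: list[str] = []
    counts = dict(spec.languages)
    if sum(counts.values()) != spec.k:
        raise ValueError("language counts must sum to k")
    for lang, cnt in counts.items():
        langs.extend([lang] * cnt)

    # clinical assignment: exact count for English, rate elsewhere
    eng_idx = [i for i, la in enumerate(langs) if la == "English"]
    clinical = np.zeros(spec.k, dtype=bool)
    if spec.english_clinical_samples:
        chosen = rng.choice(eng_idx, size=min(spec.english_clinical_samples, len(eng_idx)),
                            replace=False)
        clinical[chosen] = True
    for i, la in enumerate(langs):
        if la != "English":
            clinical[i] = rng.random() < spec.other_clinical_rate

    ns = _truncated_lognormal(rng, spec.n_median, spec.n_sigma,
                              spec.n_range[0], spec.n_range[1], spec.k)
    kinds = rng.choice(list(spec.reporting_mix), size=spec.k,
                       p=list(spec.reporting_mix.values()))

    pop_cache: dict[tuple[str, bool], np.ndarray] = {}
    records: list[StudyRecord] = []
    for i in range(spec.k):
        key = (langs[i], bool(clinical[i]))
        if key not in pop_cache:
            pop_cache[key] = population_matrix(spec, langs[i], clinical=clinical[i],
                                               scheme=scheme)
        sub = int(rng.integers(0, 2**31 - 1))
        R_s = sample_study(pop_cache[key], int(ns[i]), sub)
        sid = f"S{i + 1:03d}"
        common = dict(study_id=f"study{i + 1:03d}", sample_id=sid, n=int(ns[i]),
                      language=langs[i],
                      clinical_status="clinical" if clinical[i] else "nonclinical")
        if kinds[i] == "raw_correlations":
            rec = StudyRecord(**common, source_kind="raw_correlations", correlation=R_s)
        elif kinds[i] == "efa_pattern":
            sol = degrade_to_pattern(R_s, m=spec.efa_factors, rotation="quartimin",
                                     censor_threshold=spec.censor_threshold, seed=sub)
            rec = StudyRecord(**common, source_kind="efa_pattern", pattern=sol.loadings,
                              factor_corr=sol.phi, censor_threshold=spec.censor_threshold)
        else:
            L, Phi = _cfa_pattern(R_s, int(ns[i]), scheme, spec.partition,
                                  spec.cfa_reported_model)
            rec = StudyRecord(**common, source_kind="cfa_pattern", pattern=L,
                              factor_corr=Phi)
        records.append(rec.validate(scheme))

    truth = {
        "seed": spec.seed,
        "loadings": dict(spec.loadings),
        "phi": spec.phi.tolist(),
        "residual_correlation": spec.residual_correlation,
        "group_perturbations": {g: dict(p) for g, p in spec.group_perturbations.items()},
        "clinical_perturbation": dict(spec.clinical_perturbation),
        "partition": spec.partition,
        "k": spec.k,
        "total_N": int(ns.sum()),
    }
    return records, truth
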