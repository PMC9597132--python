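"""Meta-analytic evidence base: study records, validation, and I/O.

One record summarizes one sample of a primary study: either a full
20x20 Pearson correlation matrix, or a reported factor pattern (EFA or
CFA, possibly censored below a reporting threshold) with the factor
correlations needed to reconstruct item-level correlations.  A corpus
is stored on disk as a comma-delimited coding sheet plus one delimited
matrix file per sample — human-checkable and diff-friendly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .items import ItemScheme, default_scheme

__all__ = [
    "StudyRecord",
    "CorpusSummary",
    "CorpusValidationError",
    "read_corpus",
    "write_corpus",
    "summarize",
    "nearest_correlation",
]

SYMMETRY_TOL = 1e-8

SHEET_COLUMNS = [
    "study_id",
    "sample_id",
    "n",
    "language",
    "clinical_status",
    "source_kind",
    "matrix_file",
    "phi_file",
    "censor_threshold",
    "already_recoded",
]

SourceKind = Literal["raw_correlations", "efa_pattern", "cfa_pattern"]


class CorpusValidationError(ValueError):
    """Raised when a coding sheet row or matrix file fails validation."""


def _check_correlation(R: np.ndarray, *, what: str, repair: bool = False) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise CorpusValidationError(f"{what}: matrix is not square (shape {R.shape})")
    if np.abs(R - R.T).max() > SYMMETRY_TOL:
        raise CorpusValidationError(f"{what}: matrix not symmetric beyond tolerance {SYMMETRY_TOL}")
    R = (R + R.T) / 2.0
    if np.abs(np.diag(R) - 1.0).max() > SYMMETRY_TOL:
        raise CorpusValidationError(f"{what}: diagonal is not 1")
    np.fill_diagonal(R, 1.0)
    if np.abs(R).max() > 1.0 + SYMMETRY_TOL:
        raise CorpusValidationError(f"{what}: correlation outside [-1, 1]")
    np.clip(R, -1.0, 1.0, out=R)
    if np.linalg.eigvalsh(R).min() < -1e-10:
        # Reconstructed matrices can be indefinite; pooling usually restores
        # definiteness, so this is a warning (with optional repair), not an error.
        warnings.warn(f"{what}: correlation matrix not positive semidefinite", stacklevel=3)
        if repair:
            R = nearest_correlation(R)
    return R


def nearest_correlation(R: np.ndarray, *, eps: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest correlation matrix.

    Eigenvalue clipping followed by re-standardization; adequate for the
    mildly indefinite matrices that arise from censored patterns.
    """
    w, V = np.linalg.eigh((R + R.T) / 2.0)
    w = np.clip(w, eps, None)
    A = (V * w) @ V.T
    d = np.sqrt(np.diag(A))
    A = A / np.outer(d, d)
    np.fill_diagonal(A, 1.0)
    return A


@dataclass
class StudyRecord:
    """One sample's summary statistics and labels."""

    study_id: str
    sample_id: str
    n: int
    language: str
    clinical_status: Literal["clinical", "nonclinical"]
    source_kind: SourceKind
    correlation: np.ndarray | None = None
    pattern: np.ndarray | None = None          # 20 x m loadings, NaN = censored
    factor_corr: np.ndarray | None = None      # m x m, identity if orthogonal
    censor_threshold: float | None = None
    already_recoded: bool = True

    def validate(self, scheme: ItemScheme | None = None, *, repair: bool = False) -> "StudyRecord":
        scheme = scheme or default_scheme()
        p = scheme.n_items
        if self.n < p + 1:
            raise CorpusValidationError(
                f"sample {self.sample_id}: n too small (n={self.n}, need > {p})"
            )
        if self.clinical_status not in ("clinical", "nonclinical"):
            raise CorpusValidationError(
                f"sample {self.sample_id}: bad clinical_status {self.clinical_status!r}"
            )
        has_corr = self.correlation is not None
        has_pattern = self.pattern is not None
        if has_corr == has_pattern:
            raise CorpusValidationError(
                f"sample {self.sample_id}: exactly one of correlation/pattern required"
            )
        rec = self
        if has_corr:
            R = _check_correlation(self.correlation, what=f"sample {self.sample_id}", repair=repair)
            if R.shape[0] != p:
                raise CorpusValidationError(
                    f"sample {self.sample_id}: matrix is {R.shape[0]}x{R.shape[0]}, expected {p}"
                )
            rec = replace(rec, correlation=R)
        else:
            L = np.asarray(self.pattern, dtype=float)
            if L.ndim != 2 or L.shape[0] != p or L.shape[1] < 1:
                raise CorpusValidationError(
                    f"sample {self.sample_id}: pattern must be {p} x m, got {L.shape}"
                )
            finite = L[np.isfinite(L)]
            if finite.size and np.abs(finite).max() > 1.0 + SYMMETRY_TOL:
                raise CorpusValidationError(
                    f"sample {self.sample_id}: pattern loading outside [-1, 1]"
                )
            m = L.shape[1]
            if self.factor_corr is None:
                rec = replace(rec, pattern=L, factor_corr=np.eye(m))
            else:
                Phi = _check_correlation(self.factor_corr, what=f"sample {self.sample_id} (phi)")
                if Phi.shape[0] != m:
                    raise CorpusValidationError(
                        f"sample {self.sample_id}: factor_corr is {Phi.shape[0]}x{Phi.shape[0]}, "
                        f"pattern has {m} factors"
                    )
                rec = replace(rec, pattern=L, factor_corr=Phi)
        return rec


@dataclass(frozen=True)
class CorpusSummary:
    k: int
    total_N: int
    median_n: float
    language_counts: dict[str, int] = field(default_factory=dict)
    status_counts: dict[str, int] = field(default_factory=dict)
    source_counts: dict[str, int] = field(default_factory=dict)


def summarize(records: Sequence[StudyRecord]) -> CorpusSummary:
    """Descriptive summary of a corpus (k, total N, median n, label counts)."""
    if not records:
        raise ValueError("cannot summarize an empty corpus")
    ns = np.array([r.n for r in records])
    count = lambda key: dict(  # noqa: E731
        pd.Series([getattr(r, key) for r in records]).value_counts().sort_index()
    )
    return CorpusSummary(
        k=len(records),
        total_N=int(ns.sum()),
        median_n=float(np.median(ns)),
        language_counts={k: int(v) for k, v in count("language").items()},
        status_counts={k: int(v) for k, v in count("clinical_status").items()},
        source_counts={k: int(v) for k, v in count("source_kind").items()},
    )


# ---------------------------------------------------------------------------
# on-disk format

def _matrix_path(matrix_dir: Path, name: str) -> Path:
    path = matrix_dir / name
    if not path.exists():
        raise CorpusValidationError(f"missing matrix file {name!r} in {matrix_dir}")
    return path


def _write_matrix(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, float_format="%.17g")


def write_corpus(records: Sequence[StudyRecord], out_dir: str | Path,
                 scheme: ItemScheme | None = None) -> Path:
    """Write a coding sheet plus per-sample matrix files; returns the sheet path."""
    scheme = scheme or default_scheme()
    out_dir = Path(out_dir)
    matrix_dir = out_dir / "matrices"
    matrix_dir.mkdir(parents=True, exist_ok=True)
    labels = list(scheme.item_labels)
    rows = []
    for rec in records:
        if rec.correlation is not None:
            fname = f"{rec.sample_id}_r.csv"
            _write_matrix(pd.DataFrame(rec.correlation, index=labels, columns=labels),
                          matrix_dir / fname)
            phi_name = ""
        else:
            fname = f"{rec.sample_id}_pattern.csv"
            m = rec.pattern.shape[1]
            fnames = [f"F{j + 1}" for j in range(m)]
            _write_matrix(pd.DataFrame(rec.pattern, index=labels, columns=fnames),
                          matrix_dir / fname)
            phi_name = f"{rec.sample_id}_phi.csv"
            phi = rec.factor_corr if rec.factor_corr is not None else np.eye(m)
            _write_matrix(pd.DataFrame(phi, index=fnames, columns=fnames),
                          matrix_dir / phi_name)
        rows.append({
            "study_id": rec.study_id,
            "sample_id": rec.sample_id,
            "n": rec.n,
            "language": rec.language,
            "clinical_status": rec.clinical_status,
            "source_kind": rec.source_kind,
            "matrix_file": fname,
            "phi_file": phi_name,
            "censor_threshold": "" if rec.censor_threshold is None else rec.censor_threshold,
            "already_recoded": rec.already_recoded,
        })
    sheet = out_dir / "coding_sheet.csv"
    pd.DataFrame(rows, columns=SHEET_COLUMNS).to_csv(sheet, index=False)
    return sheet


def read_corpus(coding_sheet: str | Path, matrix_dir: str | Path | None = None,
                scheme: ItemScheme | None = None, *, repair: bool = False,
                strict: bool = True) -> list[StudyRecord]:
    """Read and validate a corpus.

    Rows that fail validation are collected and reported together; with
    ``strict=True`` (default) any problem raises, so nothing is silently
    dropped.  With ``strict=False`` the valid records are returned and
    problems are emitted as warnings.
    """
    scheme = scheme or default_scheme()
    sheet_path = Path(coding_sheet)
    matrix_dir = Path(matrix_dir) if matrix_dir is not None else sheet_path.parent / "matrices"
    df = pd.read_csv(sheet_path, dtype={"study_id": str, "sample_id": str})
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise CorpusValidationError(f"coding sheet missing columns: {missing}")

    records: list[StudyRecord] = []
    problems: list[str] = []
    for _, row in df.iterrows():
        try:
            kind = row["source_kind"]
            corr = pattern = phi = None
            path = _matrix_path(matrix_dir, str(row["matrix_file"]))
            mat = pd.read_csv(path, index_col=0, float_precision="round_trip")
            if kind == "raw_correlations":
                corr = mat.to_numpy(dtype=float)
            else:
                pattern = mat.to_numpy(dtype=float)
                phi_file = row.get("phi_file")
                if isinstance(phi_file, str) and phi_file:
                    phi = pd.read_csv(_matrix_path(matrix_dir, phi_file), index_col=0,
                                      float_precision="round_trip").to_numpy(dtype=float)
            thr = row.get("censor_threshold")
            rec = StudyRecord(
                study_id=str(row["study_id"]),
                sample_id=str(row["sample_id"]),
                n=int(row["n"]),
                language=str(row["language"]),
                clinical_status=str(row["clinical_status"]),
                source_kind=str(kind),
                correlation=corr,
                pattern=pattern,
                factor_corr=phi,
                censor_threshold=None if pd.isna(thr) or thr == "" else float(thr),
                already_recoded=bool(row.get("already_recoded", True)),
            ).validate(scheme, repair=repair)
            records.append(rec)
        except CorpusValidationError as exc:
            problems.append(str(exc))
    if problems:
        msg = "corpus validation failed for {} row(s):\n  - {}".format(
            len(problems), "\n  - ".join(problems))
        if strict:
            raise CorpusValidationError(msg)
        warnings.warn(msg, stacklevel=2)
    return records
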