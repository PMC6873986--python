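"""Data model for expression cohorts and on-disk readers/writers.

Conventions
-----------
* Expression matrices are features x samples.
* ``event == 1`` means the event was observed; ``event == 0`` means the
  sample is right-censored.  (Beware: some sources call this column a
  "censoring label" with the same 0/1 coding.)
* Survival times are in arbitrary but cohort-consistent units; the training
  method never compares times across cohorts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SIGNATURE_FORMAT_VERSION = 1


class DataError(ValueError):
    """Raised for malformed input data or invariant violations."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise DataError(f"duplicate {what}: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """A features x samples real-valued matrix with unique string ids."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = [str(x) for x in self.feature_ids]
        self.sample_ids = [str(x) for x in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise DataError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if self.values.size == 0:
            raise DataError("empty expression matrix")
        _check_unique(self.feature_ids, "feature id")
        _check_unique(self.sample_ids, "sample id")
        if not np.isfinite(self.values).all():
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                f"missing/non-finite expression value at feature "
                f"{self.feature_ids[r]!r}, sample {self.sample_ids[c]!r}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_features(self, ids: Sequence[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``ids`` in the given order."""
        index = {f: r for r, f in enumerate(self.feature_ids)}
        missing = [f for f in ids if f not in index]
        if missing:
            raise DataError(f"features not present: {missing[:5]}")
        rows = [index[f] for f in ids]
        return ExpressionMatrix(list(ids), list(self.sample_ids), self.values[rows, :])

    def subset_samples(self, ids: Sequence[str]) -> "ExpressionMatrix":
        index = {s: c for c, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise DataError(f"samples not present: {missing[:5]}")
        cols = [index[s] for s in ids]
        return ExpressionMatrix(list(self.feature_ids), list(ids), self.values[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class ClinicalTable:
    """Aligned vectors of sample id, survival time and event indicator."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(x) for x in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if not (len(self.sample_ids) == self.time.shape[0] == self.event.shape[0]):
            raise DataError("clinical columns have unequal lengths")
        _check_unique(self.sample_ids, "clinical sample id")
        if not np.isfinite(self.time).all() or (self.time <= 0).any():
            bad = [s for s, t in zip(self.sample_ids, self.time)
                   if not np.isfinite(t) or t <= 0]
            raise DataError(f"non-positive survival time for sample(s) {bad[:5]}")
        ev = np.asarray(self.event, dtype=float)
        if not np.isin(ev, (0.0, 1.0)).all():
            bad = [s for s, e in zip(self.sample_ids, ev) if e not in (0.0, 1.0)]
            raise DataError(f"event indicator not in {{0,1}} for sample(s) {bad[:5]}")
        self.event = ev.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, ids: Sequence[str]) -> "ClinicalTable":
        index = {s: r for r, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return ClinicalTable(list(ids), self.time[rows], self.event[rows])


@dataclass
class Cohort:
    """One study's expression matrix aligned to its survival outcomes."""

    name: str
    expression: ExpressionMatrix
    clinical: ClinicalTable

    def __post_init__(self) -> None:
        if self.expression.sample_ids != self.clinical.sample_ids:
            raise DataError(
                f"cohort {self.name!r}: expression and clinical sample ids differ "
                "in content or order"
            )
        if self.expression.n_samples < 2:
            raise DataError(f"cohort {self.name!r}: fewer than 2 samples")
        if self.clinical.n_events < 1:
            raise DataError(f"cohort {self.name!r}: no observed events")

    @property
    def n_samples(self) -> int:
        return self.expression.n_samples

    @property
    def feature_ids(self) -> list[str]:
        return self.expression.feature_ids

    def with_expression(self, expr: ExpressionMatrix) -> "Cohort":
        return Cohort(self.name, expr, self.clinical)


@dataclass
class CohortCollection:
    """K cohorts sharing one gene universe in identical order."""

    cohorts: list[Cohort]

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise DataError("empty cohort collection")
        _check_unique([c.name for c in self.cohorts], "cohort name")
        universe = self.cohorts[0].feature_ids
        for c in self.cohorts[1:]:
            if c.feature_ids != universe:
                raise DataError(
                    f"cohort {c.name!r} feature ids differ from the shared gene universe"
                )

    @property
    def gene_universe(self) -> list[str]:
        return list(self.cohorts[0].feature_ids)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.cohorts]

    def __len__(self) -> int:
        return len(self.cohorts)

    def __iter__(self):
        return iter(self.cohorts)

    def subset_genes(self, genes: Sequence[str]) -> "CohortCollection":
        return CohortCollection(
            [c.with_expression(c.expression.subset_features(genes)) for c in self.cohorts]
        )


@dataclass
class TrainedSignature:
    """A linear signature: ordered genes, coefficients, penalty, provenance.

    ``coefficients`` act on percentile-rank features; ``w @ x`` is a survival
    (protective) score and the reported risk score is its negation.
    """

    gene_ids: list[str]
    coefficients: np.ndarray
    lam: float
    feature_space: str = "percentile_rank"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 1 or len(self.gene_ids) != self.coefficients.shape[0]:
            raise DataError("coefficients length must equal gene_ids length")
        if not np.isfinite(self.coefficients).all():
            raise DataError("non-finite coefficient")
        self.lam = float(self.lam)
        if self.lam < 0:
            raise DataError("lambda must be nonnegative")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_matrix(path, transpose: bool = False) -> ExpressionMatrix:
    """Read a delimited features x samples matrix (samples x features if
    ``transpose``).  First column holds feature ids, header row sample ids.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if transpose:
        df = df.T
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DataError(f"{path}: empty matrix")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise DataError(f"{path}: non-numeric value at feature {row!r}, sample {col!r}")
        df[col] = coerced
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise DataError(f"{path}: missing value at feature {df.index[r]!r}, sample {df.columns[c]!r}")
    return ExpressionMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(float))


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    path = Path(path)
    expr.to_frame().to_csv(path, sep=_sep_for(path), index_label="feature_id")


def read_clinical_table(path) -> ClinicalTable:
    """Read a delimited table with columns sample_id, time, event (extras ignored)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing clinical column(s) {sorted(missing)}")
    time = pd.to_numeric(df["time"], errors="coerce")
    event = pd.to_numeric(df["event"], errors="coerce")
    if time.isna().any() or event.isna().any():
        raise DataError(f"{path}: non-numeric time or event value")
    return ClinicalTable(list(df["sample_id"].astype(str)), time.to_numpy(float), event.to_numpy(float))


def write_clinical_table(clin: ClinicalTable, path) -> None:
    path = Path(path)
    pd.DataFrame(
        {"sample_id": clin.sample_ids, "time": clin.time, "event": clin.event}
    ).to_csv(path, sep=_sep_for(path), index=False)


def assemble_cohort(expr: ExpressionMatrix, clin: ClinicalTable, name: str) -> Cohort:
    """Inner-join expression and clinical data on sample id.

    Samples present in only one input are dropped (count logged).  Expression
    columns are reordered to the clinical table's order, restricted to the
    intersection.
    """
    expr_set = set(expr.sample_ids)
    shared = [s for s in clin.sample_ids if s in expr_set]
    if not shared:
        raise DataError(f"cohort {name!r}: no samples shared between expression and clinical data")
    dropped = (expr.n_samples - len(shared)) + (clin.n_samples - len(shared))
    if dropped:
        log.info("cohort %s: dropped %d unmatched sample(s) at assembly", name, dropped)
    return Cohort(name, expr.subset_samples(shared), clin.subset(shared))


def write_signature(sig: TrainedSignature, path) -> None:
    """Serialize a signature to JSON (full float precision; human-diffable)."""
    doc = {
        "format_version": SIGNATURE_FORMAT_VERSION,
        "feature_space": sig.feature_space,
        "gene_ids": sig.gene_ids,
        "coefficients": [float(x) for x in sig.coefficients],
        "lambda": sig.lam,
        "provenance": sig.provenance,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_signature(path) -> TrainedSignature:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise DataError(f"{path}: malformed signature file ({exc})") from exc
    if not isinstance(doc, dict):
        raise DataError(f"{path}: malformed signature file")
    version = doc.get("format_version")
    if version != SIGNATURE_FORMAT_VERSION:
        raise DataError(f"{path}: unsupported signature format version {version!r}")
    for key in ("gene_ids", "coefficients", "lambda"):
        if key not in doc:
            raise DataError(f"{path}: signature file missing field {key!r}")
    return TrainedSignature(
        gene_ids=doc["gene_ids"],
        coefficients=np.asarray(doc["coefficients"], dtype=float),
        lam=doc["lambda"],
        feature_space=doc.get("feature_space", "percentile_rank"),
        provenance=doc.get("provenance", {}),
    )
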