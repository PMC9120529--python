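"""Cohort table I/O, exclusion filters, and train-statistics z-scoring.

A cohort is a wide, one-row-per-subject table: modality feature columns,
MMSE at months 0/6/12/24 as regression targets, and a 24-month diagnosis
label.  Preprocessing is complete-case: subjects with any missing target,
label, or feature are excluded rather than imputed, CSF analytes reported
outside their plausible assay range are excluded, and columns that leak the
label (ADAS, MoCA, CDR family) are removed before modelling.  Features are
standardized with means/variances estimated on the training partition only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import (
    CLASS_NAMES,
    DEFAULT_LEAKAGE_COLUMNS,
    LABEL_COLUMN,
    MMSE_COLUMNS,
    SUBJECT_COLUMN,
    ModalitySchema,
    SchemaError,
    one_hot_labels,
)

logger = logging.getLogger(__name__)

#: Plausible assay range for total tau (pg/mL); values outside are excluded.
DEFAULT_ANALYTE_BOUNDS: dict[str, tuple[float, float]] = {"TAU": (80.0, 1300.0)}


class CohortInputError(ValueError):
    """Malformed cohort input (duplicate ids, bad labels, ...)."""


@dataclass
class CohortTable:
    """Subject-by-feature cohort with longitudinal targets and labels.

    ``df`` holds one row per subject indexed by subject id; it may carry
    extra (non-schema) columns, e.g. leakage columns prior to removal.
    Feature access is always schema-ordered.
    """

    df: pd.DataFrame
    schema: ModalitySchema = field(default_factory=ModalitySchema)

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            dup = self.df.index[self.df.index.duplicated()][0]
            raise CohortInputError(f"duplicate subject id {dup!r}")
        missing = [c for c in self.required_columns(self.schema) if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")

    @staticmethod
    def required_columns(schema: ModalitySchema) -> list[str]:
        return list(schema.feature_names) + list(MMSE_COLUMNS) + [LABEL_COLUMN]

    # -- accessors -----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.df)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.df.index.to_numpy()

    def features(self) -> np.ndarray:
        """(n, p) feature matrix in schema fusion order."""
        return self.df[list(self.schema.feature_names)].to_numpy(dtype=float)

    def block(self, modality: str) -> np.ndarray:
        return self.df[list(self.schema.blocks[modality])].to_numpy(dtype=float)

    def mmse(self) -> np.ndarray:
        """(n, 4) MMSE matrix at months 0, 6, 12, 24."""
        return self.df[list(MMSE_COLUMNS)].to_numpy(dtype=float)

    def labels(self) -> np.ndarray:
        return self.df[LABEL_COLUMN].to_numpy(dtype=object)

    def one_hot(self) -> np.ndarray:
        return one_hot_labels(self.labels())

    def select(self, ids) -> "CohortTable":
        """Row subset by subject id, preserving order of ``ids``."""
        return replace(self, df=self.df.loc[list(ids)])

    def with_schema(self, schema: ModalitySchema) -> "CohortTable":
        return replace(self, df=self.df, schema=schema)


# ---------------------------------------------------------------------------
# reading / writing


def read_cohort(path: str | Path, schema: ModalitySchema | None = None) -> CohortTable:
    """Read a wide-format cohort CSV.

    Unparseable numeric cells are marked missing (NaN) and the row is kept;
    dropping happens in :func:`filter_complete_cases`.  Labels outside the
    four-class set are marked missing as well.

    Raises
    ------
    SchemaError
        If a required column is absent.
    CohortInputError
        If a subject id occurs twice.
    """
    schema = schema or ModalitySchema()
    df = pd.read_csv(path, dtype={SUBJECT_COLUMN: str})
    if SUBJECT_COLUMN not in df.columns:
        raise SchemaError(f"missing required column(s): ['{SUBJECT_COLUMN}']")
    missing = [c for c in CohortTable.required_columns(schema) if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df = df.set_index(SUBJECT_COLUMN)
    numeric_cols = [c for c in df.columns if c != LABEL_COLUMN]
    for c in numeric_cols:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    bad = ~df[LABEL_COLUMN].isin(CLASS_NAMES)
    if bad.any():
        df.loc[bad, LABEL_COLUMN] = np.nan
    return CohortTable(df=df, schema=schema)


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write the cohort back to CSV in the same dialect (UTF-8, comma)."""
    out = table.df.copy()
    out.insert(0, SUBJECT_COLUMN, out.index)
    out.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# exclusion filters


def filter_complete_cases(table: CohortTable) -> CohortTable:
    """Drop subjects missing any MMSE value, the 24-month label, or a feature."""
    cols = CohortTable.required_columns(table.schema)
    keep = table.df[cols].notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("complete-case filter removed %d of %d subjects", dropped, len(keep))
    if keep.sum() == 0:
        logger.warning("complete-case filter removed every subject")
    return replace(table, df=table.df.loc[keep])


def filter_analyte_range(
    table: CohortTable,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> CohortTable:
    """Exclude subjects whose CSF analytes fall outside plausible assay ranges.

    A subject is removed when any configured analyte is strictly below the
    lower bound or strictly above the upper bound (the closed interval is
    retained).  Missing analyte values are left to the complete-case filter.
    """
    bounds = DEFAULT_ANALYTE_BOUNDS if bounds is None else bounds
    keep = pd.Series(True, index=table.df.index)
    for col, (low, high) in bounds.items():
        if low >= high:
            raise ValueError(f"invalid range for {col}: low {low} >= high {high}")
        if col not in table.df.columns:
            logger.info("analyte %s not present; range filter skipped", col)
            continue
        v = table.df[col]
        out_of_range = ((v < low) | (v > high)) & v.notna()
        keep &= ~out_of_range
    dropped = int((~keep).sum())
    if dropped:
        logger.info("analyte-range filter removed %d subjects", dropped)
    return replace(table, df=table.df.loc[keep])


def drop_leakage_features(
    table: CohortTable,
    drop_list: tuple[str, ...] | list[str] = DEFAULT_LEAKAGE_COLUMNS,
) -> CohortTable:
    """Remove label-leaking columns (ADAS/MoCA/CDR family) from table and schema."""
    present = [c for c in drop_list if c in table.df.columns]
    absent = [c for c in drop_list if c not in table.df.columns]
    if absent:
        logger.info("leakage columns not present (ignored): %s", absent)
    df = table.df.drop(columns=present)
    schema = table.schema.drop_features(set(present))
    return CohortTable(df=df, schema=schema)


# ---------------------------------------------------------------------------
# z-scoring


@dataclass(frozen=True)
class NormalizationStats:
    """Per-feature train means and standard deviations (population sd)."""

    means: dict[str, float]
    stds: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            name: {"mean": self.means[name], "std": self.stds[name]} for name in self.means
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationStats":
        payload = json.loads(Path(path).read_text())
        return cls(
            means={k: v["mean"] for k, v in payload.items()},
            stds={k: v["std"] for k, v in payload.items()},
        )


def zscore_fit(train: CohortTable) -> NormalizationStats:
    """Estimate per-feature mean and sd on the training partition.

    Constant features get scale 1 (with a warning) so transformed values are
    exactly centred zeros.
    """
    means: dict[str, float] = {}
    stds: dict[str, float] = {}
    X = train.features()
    for j, name in enumerate(train.schema.feature_names):
        m = float(np.mean(X[:, j]))
        s = float(np.std(X[:, j]))  # population sd: variance of the training data
        if s == 0.0:
            logger.warning("feature %s is constant on the training data; scale set to 1", name)
            s = 1.0
        means[name] = m
        stds[name] = s
    return NormalizationStats(means=means, stds=stds)


def zscore_apply(table: CohortTable, stats: NormalizationStats) -> CohortTable:
    """Standardize schema features with (train) statistics.

    Raises
    ------
    SchemaError
        If the stats do not cover the table's schema features.
    """
    missing = [c for c in table.schema.feature_names if c not in stats.means]
    if missing:
        raise SchemaError(f"normalization stats missing feature(s): {missing}")
    df = table.df.copy()
    for name in table.schema.feature_names:
        df[name] = (df[name] - stats.means[name]) / stats.stds[name]
    return replace(table, df=df)


def preprocess(
    table: CohortTable,
    bounds: dict[str, tuple[float, float]] | None = None,
    drop_list: tuple[str, ...] | list[str] = DEFAULT_LEAKAGE_COLUMNS,
) -> CohortTable:
    """Full exclusion pipeline: analyte range, complete cases, leakage removal."""
    t = filter_analyte_range(table, bounds)
    t = filter_complete_cases(t)
    t = drop_leakage_features(t, drop_list)
    logger.info("preprocessing retained %d subjects", t.n_subjects)
    return t
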