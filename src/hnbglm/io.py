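"""Readers, writers and covariate encoding for microbiome count tables.

A count table is a feature x sample matrix of non-negative integer
counts with unique feature and sample identifiers; per-sample total
reads (library sizes) are the column sums unless supplied externally
(useful when the table was filtered upstream, since filtering changes
column sums but not the library that was sequenced).

Sample metadata are joined to the count table *by sample identifier*,
never by position.  Categorical covariates are expanded to
reference-coded indicators and missing values are imputed by the
column (or indicator) mean before modeling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class CountTable:
    """Feature x sample count matrix plus per-sample total reads."""

    counts: pd.DataFrame
    total_reads: pd.Series

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate feature IDs")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample IDs")
        vals = self.counts.to_numpy()
        if vals.size and (np.any(vals < 0) or np.any(vals != np.floor(vals))):
            raise ValueError("counts must be non-negative integers")
        self.total_reads = self.total_reads.reindex(self.counts.columns)
        if self.total_reads.isna().any() or (self.total_reads <= 0).any():
            raise ValueError("total reads must be positive for every sample")

    @classmethod
    def from_frame(cls, counts: pd.DataFrame,
                   total_reads: pd.Series | None = None) -> "CountTable":
        """Build a table, computing totals as column sums when absent and
        dropping samples whose total is zero (with a logged warning)."""
        counts = counts.copy()
        if total_reads is None:
            total_reads = counts.sum(axis=0)
            zero = total_reads[total_reads == 0].index
            if len(zero):
                logger.warning("dropping %d sample(s) with zero total reads: %s",
                               len(zero), ", ".join(map(str, zero[:5])))
                counts = counts.drop(columns=zero)
                total_reads = total_reads.drop(index=zero)
        return cls(counts=counts, total_reads=pd.Series(total_reads))

    @property
    def feature_ids(self):
        return list(self.counts.index)

    @property
    def sample_ids(self):
        return list(self.counts.columns)

    @property
    def shape(self):
        return self.counts.shape

    def feature_counts(self, feature_id) -> np.ndarray:
        return self.counts.loc[feature_id].to_numpy(dtype=float)

    def log_total_reads(self) -> np.ndarray:
        """Natural-log library sizes, the model offset."""
        return np.log(self.total_reads.to_numpy(dtype=float))

    def write(self, path, sep: str = "\t") -> None:
        self.counts.to_csv(path, sep=sep, index_label="feature_id")


def _sep_for(path, sep=None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).endswith(".csv") else "\t"


def read_count_table(path, orientation: str = "features_in_rows",
                     sep: str | None = None,
                     total_reads: pd.Series | None = None) -> CountTable:
    """Read a delimited count table (header row, first column = ID).

    ``orientation="samples_in_rows"`` transposes after reading.  Cells
    are validated as non-negative integers; the offending coordinate is
    reported on failure.
    """
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    try:
        df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    except pd.errors.ParserError as err:
        raise ValueError(f"cannot parse {path}: {err}") from err
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        if len(bad):
            raise ValueError(
                f"non-numeric value {df.loc[bad[0], col]!r} at "
                f"row {bad[0]!r}, column {col!r} in {path}")
        df[col] = coerced
    if orientation == "samples_in_rows":
        df = df.T
    return CountTable.from_frame(df, total_reads=total_reads)


def read_total_reads(path, sep: str | None = None) -> pd.Series:
    """Two-column table (sample ID, total reads) -> Series by sample."""
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    return df.iloc[:, 0]


def read_metadata(path, sep: str | None = None) -> pd.DataFrame:
    """Sample metadata: rows indexed by sample ID, arbitrary columns."""
    return pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)


@dataclass
class DesignMatrix:
    """Encoded design: intercept column first, then covariates.

    ``encoding`` records, per input column, the type, levels, reference
    level and imputation count, so reports can be traced back to the
    raw metadata.
    """

    matrix: np.ndarray
    names: list
    encoding: dict = field(default_factory=dict)
    has_intercept: bool = True

    @property
    def covariates(self) -> np.ndarray:
        return self.matrix[:, 1:] if self.has_intercept else self.matrix

    @property
    def covariate_names(self) -> list:
        return self.names[1:] if self.has_intercept else list(self.names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)


def encode_covariates(meta: pd.DataFrame, columns=None,
                      reference: dict | None = None) -> DesignMatrix:
    """Encode host characteristics into a model design matrix.

    Continuous columns pass through; categorical columns become
    reference-coded indicators (reference level = lexicographically
    first unless overridden).  Missing values are imputed by the column
    mean — for categoricals, the mean of each indicator — before
    fitting.  Single-level categoricals are dropped with a warning;
    all-missing columns are an error.
    """
    reference = reference or {}
    columns = list(columns) if columns is not None else list(meta.columns)
    missing = [c for c in columns if c not in meta.columns]
    if missing:
        raise KeyError(f"metadata columns not found: {missing}")

    blocks, names = [], []
    encoding = {}
    for col in columns:
        s = meta[col]
        if s.isna().all():
            raise ValueError(f"column {col!r} is entirely missing")
        n_missing = int(s.isna().sum())
        if pd.api.types.is_numeric_dtype(s):
            v = s.to_numpy(dtype=float)
            v = np.where(np.isnan(v), np.nanmean(v), v)
            blocks.append(v[:, None])
            names.append(col)
            encoding[col] = {"type": "continuous", "imputed": n_missing}
            continue
        levels = sorted(s.dropna().astype(str).unique())
        if len(levels) < 2:
            logger.warning("dropping single-level categorical column %r", col)
            encoding[col] = {"type": "dropped", "levels": levels}
            continue
        ref = str(reference.get(col, levels[0]))
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not found in {col!r}")
        enc_levels = [l for l in levels if l != ref]
        for level in enc_levels:
            ind = np.where(s.isna(), np.nan,
                           (s.astype(str) == level).astype(float))
            ind = np.where(np.isnan(ind), np.nanmean(ind), ind)
            blocks.append(ind[:, None])
            names.append(f"{col}[{level}]")
        encoding[col] = {"type": "categorical", "levels": levels,
                         "reference": ref, "imputed": n_missing}

    n = len(meta)
    mat = (np.hstack([np.ones((n, 1))] + blocks)
           if blocks else np.ones((n, 1)))
    return DesignMatrix(matrix=mat, names=["(Intercept)"] + names,
                        encoding=encoding)


def align_samples(table: CountTable, meta: pd.DataFrame) -> pd.DataFrame:
    """Reorder metadata rows to the count table's samples, by ID."""
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise KeyError(f"samples absent from metadata: {missing[:5]}")
    return meta.loc[table.sample_ids]
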