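"""Shared data model, table readers/writers, run configuration and logging.

Tables are features-in-rows, samples-in-columns TSV/CSV; comment lines
starting with ``#`` are ignored.  Time is an arbitrary real number in study
units (callers pre-convert dates).  Sample metadata links each sample to a
subject (biological replicate) and a time point, optionally a group.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("chronomix")

__all__ = [
    "ChronomixError",
    "ValidationError",
    "TableParseError",
    "LongitudinalCounts",
    "ContinuousBlock",
    "RunConfig",
    "read_counts",
    "read_table",
    "read_metadata",
    "write_matrix",
    "setup_logging",
]


class ChronomixError(Exception):
    """Base class for package errors."""


class ValidationError(ChronomixError, ValueError):
    """A data object violates its contract."""


class TableParseError(ChronomixError, ValueError):
    """A table on disk could not be parsed."""


def setup_logging(level: int = logging.INFO) -> None:
    """Emit structured ``stage | message`` log lines to stderr."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(name)s | %(levelname)s | %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


META_COLUMNS = ("sample_id", "subject_id", "time")


def _validate_meta(sample_meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in sample_meta.columns]
    if missing:
        raise ValidationError(f"sample metadata lacks required columns {missing}")
    meta = sample_meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    meta["subject_id"] = meta["subject_id"].astype(str)
    meta["time"] = pd.to_numeric(meta["time"], errors="raise").astype(float)
    if "group" not in meta.columns:
        meta["group"] = None
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicated sample ids in metadata: {dups}")
    return meta


def _check_samples(values: np.ndarray, feature_ids: Sequence[str], sample_meta: pd.DataFrame) -> None:
    if values.ndim != 2:
        raise ValidationError("value matrix must be two-dimensional (features x samples)")
    p, n = values.shape
    if len(feature_ids) != p:
        raise ValidationError(f"{len(feature_ids)} feature ids for {p} matrix rows")
    if len(set(feature_ids)) != p:
        counts = pd.Series(list(feature_ids)).value_counts()
        dups = counts[counts > 1].index.tolist()
        raise ValidationError(f"feature ids are not unique: {dups}")
    if len(sample_meta) != n:
        raise ValidationError(f"{len(sample_meta)} metadata records for {n} samples")
    if sample_meta["time"].nunique() < 2:
        raise ValidationError("at least 2 distinct time points are required")


def _sorted_by_subject_time(meta: pd.DataFrame) -> pd.DataFrame:
    return meta.sort_values(["subject_id", "time"], kind="mergesort").reset_index(drop=True)


@dataclass
class LongitudinalCounts:
    """Raw feature counts plus a sample -> (subject, time) mapping.

    ``counts`` is P features x N samples, non-negative integers; columns are
    ordered to match ``sample_meta`` rows (sorted by subject then time).
    """

    counts: np.ndarray
    feature_ids: list[str]
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.size and not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_meta = _validate_meta(self.sample_meta)
        _check_samples(self.counts, self.feature_ids, self.sample_meta)
        if self.counts.size and self.counts.min() < 0:
            r, c = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at feature {self.feature_ids[r]!r}, "
                f"sample {self.sample_meta['sample_id'].iloc[c]!r}"
            )
        order = _sorted_by_subject_time(self.sample_meta)
        idx = self.sample_meta.set_index("sample_id").index.get_indexer(order["sample_id"])
        self.counts = self.counts[:, idx]
        self.sample_meta = order

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.feature_ids, columns=self.sample_meta["sample_id"]
        )


@dataclass
class ContinuousBlock:
    """Continuous-valued omics block (e.g. log metabolite intensities)."""

    values: np.ndarray
    feature_ids: list[str]
    sample_meta: pd.DataFrame
    block_name: str = "block"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_meta = _validate_meta(self.sample_meta)
        _check_samples(self.values, self.feature_ids, self.sample_meta)
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValidationError(f"non-finite value in block {self.block_name!r}")
        order = _sorted_by_subject_time(self.sample_meta)
        idx = self.sample_meta.set_index("sample_id").index.get_indexer(order["sample_id"])
        self.values = self.values[:, idx]
        self.sample_meta = order

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_meta["sample_id"]
        )


@dataclass
class RunConfig:
    """Run-wide tunables shared across pipeline stages."""

    interpolation_grid_size: int = 9
    lowcount_threshold: float = 1e-4
    pseudo_count: float = 1.0
    silhouette_assign_threshold: float = 0.5
    bp_alpha: float = 0.05
    keepx_grid: list[int] = field(default_factory=lambda: [2, 4, 6, 8, 10])
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interpolation_grid_size < 2:
            raise ValidationError("interpolation_grid_size must be >= 2")
        if not 0 < self.lowcount_threshold < 1:
            raise ValidationError("lowcount_threshold must be in (0, 1)")
        if self.pseudo_count <= 0:
            raise ValidationError("pseudo_count must be positive")
        if not 0 < self.bp_alpha < 1:
            raise ValidationError("bp_alpha must be in (0, 1)")
        if any(k < 1 for k in self.keepx_grid):
            raise ValidationError("keepx_grid entries must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a features-in-rows table (first column = feature ids)."""
    path = Path(path)
    if not path.exists():
        raise TableParseError(f"table not found: {path}")
    try:
        df = pd.read_csv(path, sep=_sep_for(path), comment="#", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise TableParseError(f"could not parse {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TableParseError(f"metadata not found: {path}")
    meta = pd.read_csv(path, sep=_sep_for(path), comment="#")
    return _validate_meta(meta)


def read_counts(path: str | Path, meta_path: str | Path) -> LongitudinalCounts:
    """Read a count table and its sample metadata into a validated object.

    The count table must have a header row of sample ids and a first column
    of feature ids.  Samples are re-ordered by (subject_id, time).
    """
    df = read_table(path)
    meta = read_metadata(meta_path)
    missing = [s for s in df.columns if s not in set(meta["sample_id"])]
    if missing:
        raise ValidationError(f"metadata missing for sample(s): {missing}")
    meta = meta.set_index("sample_id").loc[list(df.columns)].reset_index()
    values = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            v = values[i, j]
            if not np.isfinite(v) or float(v) != int(v):
                raise TableParseError(
                    f"non-integer count {v!r} at row {i + 1} "
                    f"(feature {df.index[i]!r}), column {j + 1} ({df.columns[j]!r})"
                )
            if v < 0:
                raise TableParseError(
                    f"negative count {v!r} at row {i + 1} "
                    f"(feature {df.index[i]!r}), column {j + 1} ({df.columns[j]!r})"
                )
    return LongitudinalCounts(values.astype(np.int64), list(df.index), meta)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a labeled matrix as TSV (rows = features, columns = samples)."""
    if not isinstance(matrix, pd.DataFrame):
        raise ValidationError("write_matrix expects a labeled pandas DataFrame")
    path = Path(path)
    try:
        matrix.to_csv(path, sep="\t", index_label="feature_id")
    except OSError as exc:
        raise ChronomixError(f"cannot write {path}: {exc}") from exc
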