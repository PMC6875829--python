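"""Microbiome count preprocessing.

Three standard steps for compositional count tables:

* **low-count removal** — keep only features whose within-sample proportion
  strictly exceeds a threshold (default 0.01%) in at least one sample, to
  counteract sequencing errors;
* **total sum scaling (TSS)** — per-sample division by library size,
  producing proportions;
* **centered log-ratio transform (CLR)** — ``log(x_i / G(x))`` with ``G(x)``
  the sample geometric mean, mapping compositions into Euclidean space.
  CLR is scale-invariant, so TSS before CLR is optional.

Zeros are handled by adding a pseudo-count (default 1) to raw counts before
the log transform.  Natural logarithm throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chronomix.core_io import LongitudinalCounts, ValidationError, logger

__all__ = ["ClrMatrix", "low_count_filter", "tss", "clr"]


@dataclass
class ClrMatrix:
    """CLR-transformed abundances (P' features x N samples) with provenance."""

    values: np.ndarray
    feature_ids: list[str]
    sample_meta: pd.DataFrame
    removed_features: list[str] = field(default_factory=list)
    pseudo_count: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        col_sums = self.values.sum(axis=0)
        if self.values.size and np.max(np.abs(col_sums)) > 1e-10:
            raise ValidationError("CLR columns must sum to 0 within 1e-10")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_meta["sample_id"]
        )


def _proportions(counts: np.ndarray) -> np.ndarray:
    totals = counts.sum(axis=0, dtype=float)
    if np.any(totals <= 0):
        bad = np.where(totals <= 0)[0]
        raise ValidationError(f"sample column(s) {bad.tolist()} have zero total count")
    return counts / totals


def low_count_filter(data: LongitudinalCounts, threshold: float = 1e-4) -> LongitudinalCounts:
    """Drop features never exceeding ``threshold`` proportion in any sample.

    The inequality is strict: a feature whose best within-sample proportion
    equals the threshold exactly is removed.  Feature order is preserved.
    """
    if not 0 < threshold < 1:
        raise ValidationError("threshold must be in (0, 1)")
    props = _proportions(data.counts.astype(float))
    keep = (props > threshold).any(axis=1)
    if not keep.any():
        raise ValidationError(
            f"low-count filter at threshold {threshold} removed every feature; "
            "review the threshold"
        )
    kept_ids = [f for f, k in zip(data.feature_ids, keep) if k]
    logger.info(
        "preprocess | low_count_filter threshold=%g kept=%d removed=%d",
        threshold, int(keep.sum()), int((~keep).sum()),
    )
    return LongitudinalCounts(data.counts[keep], kept_ids, data.sample_meta)


def tss(data: LongitudinalCounts, pseudo_count: float = 0.0) -> np.ndarray:
    """Total-sum scaling: each sample column divided by its total count.

    A pseudo-count may be added first so that zero-total samples remain
    usable; each returned column sums to 1.
    """
    counts = data.counts.astype(float) + pseudo_count
    totals = counts.sum(axis=0)
    if np.any(totals <= 0):
        bad = data.sample_meta["sample_id"].iloc[np.where(totals <= 0)[0]].tolist()
        raise ValidationError(
            f"sample(s) {bad} have zero total count; set a pseudo_count"
        )
    return counts / totals


def clr(counts: LongitudinalCounts, pseudo_count: float = 1.0) -> ClrMatrix:
    """Centered log-ratio transform of a count table.

    Per sample x: ``clr(x)_i = ln(x_i + pc) - mean_j ln(x_j + pc)``.  Columns
    of the result sum to zero; the transform is invariant to sample-wise
    rescaling of the counts (with the pseudo-count scaled identically).
    """
    x = counts.counts.astype(float) + pseudo_count
    if np.any(x <= 0):
        raise ValidationError(
            "non-positive entries after pseudo-count offset; increase pseudo_count"
        )
    logx = np.log(x)
    values = logx - logx.mean(axis=0, keepdims=True)
    return ClrMatrix(
        values=values,
        feature_ids=list(counts.feature_ids),
        sample_meta=counts.sample_meta,
        pseudo_count=pseudo_count,
    )
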