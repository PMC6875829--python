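"""Post-hoc compositional validation with the proportionality distance.

Correlations between relative-abundance profiles are easily spurious.  The
proportionality distance

    phi_s(x, y) = var(x - y) / var(x + y)

on log-scale profiles is a composition-safe alternative: it is zero exactly
when the two raw-scale profiles are proportional (a constant shift on the
log scale), and grows as they diverge.  After clustering, the distance is
computed for every pair of modeled profiles; per cluster, the median of
within-cluster pair distances is compared with the median over pairs of one
member and every feature outside the cluster (the entire background set)
using a two-sided Wilcoxon rank-sum test.  Within-cluster pairs with
unusually large phi_s are flagged as possible spurious associations.

CLR-transformed profiles are already on the log scale; continuous blocks
get an extra log only when requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from chronomix.core_io import ValidationError, logger
from chronomix.cluster_reduce import ClusterAssignment
from chronomix.spline_model import ModeledMatrix

__all__ = ["ProportionalityReport", "phi_s", "pairwise_phi_s", "cluster_proportionality"]


@dataclass
class ProportionalityReport:
    """Pairwise phi_s matrix, per-cluster medians and Wilcoxon p-values."""

    pairwise: pd.DataFrame
    per_cluster: pd.DataFrame        # cluster, n_members, median_within, median_outside, wilcoxon_p
    flagged_pairs: pd.DataFrame      # within-cluster pairs above the reporting quantile

    def __post_init__(self) -> None:
        M = self.pairwise.to_numpy()
        if M.size:
            if np.nanmin(M) < -1e-12:
                raise ValidationError("phi_s must be non-negative")
            if not np.allclose(M, M.T, atol=1e-10, equal_nan=True):
                raise ValidationError("pairwise phi_s matrix must be symmetric")


def phi_s(x: np.ndarray, y: np.ndarray) -> float:
    """Proportionality distance var(x - y) / var(x + y) on log-scale profiles.

    Sample (n-1 denominator) variances; symmetric in its arguments.  When
    var(x + y) is zero the distance is undefined and NaN is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("phi_s expects two equal-length 1-D profiles")
    if x.size < 3:
        raise ValidationError("phi_s needs profiles of length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("phi_s requires finite values")
    denom = np.var(x + y, ddof=1)
    if denom < 1e-300:
        return float("nan")
    return float(np.var(x - y, ddof=1) / denom)


def pairwise_phi_s(values: np.ndarray, feature_ids: list[str]) -> pd.DataFrame:
    """Symmetric matrix of phi_s over profile columns (diagonal zero)."""
    P = values.shape[1]
    M = np.zeros((P, P))
    for i, j in combinations(range(P), 2):
        M[i, j] = M[j, i] = phi_s(values[:, i], values[:, j])
    return pd.DataFrame(M, index=feature_ids, columns=feature_ids)


def cluster_proportionality(
    X: ModeledMatrix,
    assignment: ClusterAssignment,
    log_input: bool = True,
    flag_quantile: float = 0.95,
) -> ProportionalityReport:
    """Within- versus outside-cluster proportionality, Table-style summary.

    ``log_input=True`` declares profiles already log-scale (e.g. CLR);
    otherwise they are log-transformed first, which requires positivity.
    """
    values = np.asarray(X.values, dtype=float)
    if not log_input:
        if np.any(values <= 0):
            bad = [X.feature_ids[p] for p in np.unique(np.argwhere(values <= 0)[:, 1])]
            raise ValidationError(f"non-positive profile value(s) in {bad}; cannot log")
        values = np.log(values)
    table = assignment.table.set_index("feature_id")
    ids = [f for f in X.feature_ids if f in table.index]
    if len(ids) != len(X.feature_ids):
        missing = set(X.feature_ids) - set(ids)
        raise ValidationError(f"assignment lacks features {sorted(missing)}")
    sel = table.loc[ids, "status"] != "unselected"
    ids = [f for f, s in zip(ids, sel) if s]
    cols = [X.feature_ids.index(f) for f in ids]
    vals = values[:, cols]
    pw = pairwise_phi_s(vals, ids)
    labels = (
        table.loc[ids, "component"]
        * table.loc[ids, "sign"].map({"+": 1, "-": -1})
    ).astype(int)

    M = pw.to_numpy()
    n = len(ids)
    rows = []
    flags = []
    within_all = []
    for lab in sorted(labels.unique(), key=lambda v: (abs(v), -np.sign(v))):
        members = np.flatnonzero((labels == lab).to_numpy())
        others = np.flatnonzero((labels != lab).to_numpy())
        within = np.array([M[i, j] for i, j in combinations(members, 2)])
        outside = np.array([M[i, j] for i in members for j in others])
        within = within[~np.isnan(within)]
        outside = outside[~np.isnan(outside)]
        if within.size:
            within_all.append(within)
        med_w = float(np.median(within)) if within.size else float("nan")
        med_o = float(np.median(outside)) if outside.size else float("nan")
        if within.size and outside.size:
            p = float(stats.mannwhitneyu(within, outside, alternative="two-sided").pvalue)
        else:
            p = float("nan")
        rows.append({
            "cluster": int(lab), "n_members": int(members.size),
            "median_within": med_w, "median_outside": med_o, "wilcoxon_p": p,
        })
    if within_all:
        cutoff = float(np.quantile(np.concatenate(within_all), flag_quantile))
        for lab in sorted(labels.unique(), key=lambda v: (abs(v), -np.sign(v))):
            members = np.flatnonzero((labels == lab).to_numpy())
            for i, j in combinations(members, 2):
                if not np.isnan(M[i, j]) and M[i, j] > cutoff:
                    flags.append({
                        "cluster": int(lab), "feature_a": ids[i], "feature_b": ids[j],
                        "phi_s": float(M[i, j]),
                    })
    per_cluster = pd.DataFrame(rows)
    flagged = pd.DataFrame(flags, columns=["cluster", "feature_a", "feature_b", "phi_s"])
    logger.info("proportionality | %d clusters, %d flagged pairs", len(rows), len(flags))
    return ProportionalityReport(pairwise=pw, per_cluster=per_cluster, flagged_pairs=flagged)
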