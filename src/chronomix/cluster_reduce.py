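"""Trajectory clustering with PCA and sparse PCA, tuned by silhouette.

Modeled trajectories (a T x P matrix of smooth profiles) are decomposed
into components; each feature is assigned to the component where its
loading is largest (PCA) or nonzero (sparse PCA), then sub-clustered by
the sign of that loading, giving up to 2H clusters — features grouped by
shared temporal shape, with "positive" and "negative" sub-clusters moving
in opposite directions.

Cluster quality is measured with the silhouette coefficient
``s(i) = (b(i) - a(i)) / max(a(i), b(i))`` where distances between two
profiles are ``1 - Spearman correlation`` (range [0, 2]: anticorrelated
profiles are maximally distant, as required for sign-split clusters).  The
silhouette drives both the choice of the number of components H and, for
sparse PCA, the number of features retained per component (keepX), picked
just before the first sudden decrease of the per-cluster average
silhouette along a keepX grid.

Profiles are centered and unit-variance scaled across the time grid before
clustering, so shape — not amplitude — drives cluster identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA as _SkPCA
from sklearn.metrics import silhouette_samples

from chronomix.core_io import ValidationError, logger
from chronomix.spline_model import ModeledMatrix

__all__ = [
    "ComponentDecomposition",
    "ClusterAssignment",
    "scale_profiles",
    "pca",
    "spca",
    "assign_clusters",
    "silhouette_profiles",
    "tune_components",
    "tune_keepx",
    "spearman_distance_matrix",
]


@dataclass
class ComponentDecomposition:
    """Scores t_h (T x H), loadings v_h (P x H) and per-component sparsity."""

    scores: np.ndarray
    loadings: np.ndarray
    keepx: list[int | str]
    explained_variance: np.ndarray
    method: str = "pca"

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.loadings, axis=0)
        if self.loadings.size and not np.allclose(norms, 1.0, atol=1e-8):
            raise ValidationError("loading vectors must have unit Euclidean norm")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class ClusterAssignment:
    """Feature -> (component, sign) clusters with silhouette diagnostics.

    ``table`` has one row per feature: component (1-based), sign ('+'/'-'),
    loading_value, silhouette, status (assigned / uncertain / misassigned /
    unselected).  Cluster labels are signed integers: +h / -h.
    """

    table: pd.DataFrame
    average_silhouette: float

    def labels(self, include_unselected: bool = False) -> pd.Series:
        t = self.table
        mask = (t["status"] != "unselected") | include_unselected
        return (t.loc[mask, "component"] * t.loc[mask, "sign"].map({"+": 1, "-": -1})).astype(int)


def _as_matrix(X: ModeledMatrix | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, ModeledMatrix):
        return np.asarray(X.values, dtype=float), list(X.feature_ids)
    X = np.asarray(X, dtype=float)
    return X, [f"feature_{i}" for i in range(X.shape[1])]


def scale_profiles(values: np.ndarray, scale: bool = True) -> np.ndarray:
    """Center (and unit-variance scale) each profile across the time grid."""
    out = values - values.mean(axis=0, keepdims=True)
    if scale:
        sd = values.std(axis=0, ddof=1, keepdims=True)
        if np.any(sd < 1e-12):
            bad = np.where(sd.ravel() < 1e-12)[0].tolist()
            raise ValidationError(f"constant profile(s) at column(s) {bad} cannot be scaled")
        out = out / sd
    return out


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    """Deterministic sign convention: largest-|entry| of each loading positive."""
    for h in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, h])))
        if loadings[j, h] < 0:
            loadings[:, h] *= -1
            scores[:, h] *= -1


def pca(X: ModeledMatrix | np.ndarray, H: int, scale: bool = True) -> ComponentDecomposition:
    """Principal component analysis of the T x P trajectory matrix."""
    values, feature_ids = _as_matrix(X)
    T, P = values.shape
    if not 1 <= H <= min(T - 1, P):
        raise ValidationError(f"H must be in [1, {min(T - 1, P)}]")
    if scale:
        sd = values.std(axis=0, ddof=1)
        if np.any(sd < 1e-12):
            bad = [feature_ids[j] for j in np.where(sd < 1e-12)[0]]
            raise ValidationError(f"constant feature(s) cannot be scaled: {bad}")
    Xs = scale_profiles(values, scale=scale)
    model = _SkPCA(n_components=H, svd_solver="full")
    scores = model.fit_transform(Xs)
    loadings = model.components_.T.copy()
    _fix_signs(loadings, scores)
    return ComponentDecomposition(
        scores=scores, loadings=loadings, keepx=["all"] * H,
        explained_variance=model.explained_variance_, method="pca",
    )


def soft_threshold_keep(v: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold so exactly ``keep`` entries stay nonzero.

    The threshold is the (keep+1)-th largest absolute value; remaining
    entries shrink toward zero by that amount: sign(x) (|x| - thr)_+.
    """
    if keep >= v.size:
        return v.copy()
    absv = np.abs(v)
    thr = np.partition(absv, -keep - 1)[-keep - 1]
    out = np.sign(v) * np.maximum(absv - thr, 0.0)
    # ties at the threshold can leave more than `keep` nonzeros; keep the
    # first `keep` in index order for determinism
    nz = np.flatnonzero(out)
    if nz.size > keep:
        order = np.argsort(-np.abs(out[nz]), kind="stable")
        out[nz[order[keep:]]] = 0.0
    return out


def spca(
    X: ModeledMatrix | np.ndarray,
    H: int,
    keepx: Sequence[int],
    scale: bool = True,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> ComponentDecomposition:
    """Sparse PCA by iterative soft-thresholding of the loading vectors.

    Per component: iterate v <- normalize(soft_threshold(X' t, keepx)),
    t <- X v until convergence, then deflate X by regression on the score.
    With ``keepx[h] = P`` the result equals plain PCA up to sign.
    """
    values, _ = _as_matrix(X)
    T, P = values.shape
    keepx = list(keepx)
    if len(keepx) != H:
        raise ValidationError("keepx must provide one value per component")
    if any(not 1 <= k <= P for k in keepx):
        raise ValidationError(f"keepx values must be in [1, {P}]")
    Xd = scale_profiles(values, scale=scale)
    scores = np.zeros((T, H))
    loadings = np.zeros((P, H))
    for h in range(H):
        _, _, Vt = np.linalg.svd(Xd, full_matrices=False)
        v = Vt[0]
        for it in range(max_iter):
            t = Xd @ v
            c = Xd.T @ t
            v_new = soft_threshold_keep(c, keepx[h])
            nrm = np.linalg.norm(v_new)
            if nrm < 1e-300:
                raise ValidationError(f"sPCA component {h + 1} collapsed to zero")
            v_new /= nrm
            if np.max(np.abs(v_new - v)) < tol:
                v = v_new
                break
            v = v_new
        else:
            raise ValidationError(
                f"sPCA component {h + 1} did not converge in {max_iter} iterations "
                f"(last change > {tol})"
            )
        t = Xd @ v
        scores[:, h] = t
        loadings[:, h] = v
        denom = float(t @ t)
        if denom > 1e-300:
            Xd = Xd - np.outer(t, (t @ Xd) / denom)
    _fix_signs(loadings, scores)
    ev = np.var(scores, axis=0, ddof=1)
    return ComponentDecomposition(
        scores=scores, loadings=loadings, keepx=keepx,
        explained_variance=ev, method="spca",
    )


def spearman_distance_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Spearman correlation between profile columns."""
    ranks = np.apply_along_axis(rankdata, 0, values)
    sd = ranks.std(axis=0)
    if np.any(sd < 1e-12):
        raise ValidationError("constant profile has undefined Spearman correlation")
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks.T)
    D = 1.0 - rho
    np.fill_diagonal(D, 0.0)
    return np.maximum((D + D.T) / 2.0, 0.0)


def silhouette_profiles(
    X: ModeledMatrix | np.ndarray, labels: Sequence[int]
) -> tuple[np.ndarray, float]:
    """Per-profile silhouettes under the Spearman distance, plus the average.

    Constant profiles (undefined correlation) are skipped with a warning
    and receive NaN.  Members of singleton clusters get silhouette 0.
    """
    values, _ = _as_matrix(X)
    labels = np.asarray(labels)
    if labels.size != values.shape[1]:
        raise ValidationError("one label per profile required")
    if np.unique(labels).size < 2:
        raise ValidationError("silhouette requires at least 2 clusters")
    sd = values.std(axis=0)
    ok = sd > 1e-12
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} constant profile(s) skipped in silhouette")
    sil = np.full(labels.size, np.nan)
    sub = values[:, ok]
    sub_labels = labels[ok]
    if np.unique(sub_labels).size < 2:
        raise ValidationError("fewer than 2 clusters remain after skipping constants")
    D = spearman_distance_matrix(sub)
    sizes = pd.Series(sub_labels).value_counts()
    if (sizes == 1).all():
        # every cluster is a singleton: each member scores 0 by convention
        sil[ok] = 0.0
    else:
        sil[ok] = silhouette_samples(D, sub_labels, metric="precomputed")
    return sil, float(np.nanmean(sil))


def assign_clusters(
    dec: ComponentDecomposition, X: ModeledMatrix | np.ndarray, scale: bool = True
) -> ClusterAssignment:
    """Assign features to sign-split component clusters and score them.

    PCA: each feature goes to the component with its largest absolute
    loading (ties -> earlier component).  Sparse PCA: each feature goes to
    the component where its loading is nonzero; features selected nowhere
    get status "unselected" and are excluded from the clusters.
    """
    values, feature_ids = _as_matrix(X)
    L = dec.loadings
    P, H = L.shape
    if P != values.shape[1]:
        raise ValidationError("decomposition and matrix disagree on feature count")
    comp = np.zeros(P, dtype=int)
    loading_val = np.zeros(P)
    selected = np.ones(P, dtype=bool)
    if dec.method == "spca":
        for p in range(P):
            nz = np.flatnonzero(L[p] != 0.0)
            if nz.size == 0:
                selected[p] = False
            else:
                comp[p] = nz[0] + 1
                loading_val[p] = L[p, nz[0]]
    else:
        comp = np.argmax(np.abs(L), axis=1) + 1
        loading_val = L[np.arange(P), comp - 1]
    sign = np.where(loading_val >= 0, "+", "-")

    labels = np.where(sign == "+", comp, -comp)
    sil = np.full(P, np.nan)
    if selected.sum() >= 2 and np.unique(labels[selected]).size >= 2:
        sil_sel, _ = silhouette_profiles(values[:, selected], labels[selected])
        sil[selected] = sil_sel
    status = np.where(
        ~selected, "unselected",
        np.where(np.isnan(sil), "uncertain",
                 np.where(sil > 0.5, "assigned",
                          np.where(sil >= 0, "uncertain", "misassigned"))),
    )
    table = pd.DataFrame({
        "feature_id": feature_ids,
        "component": comp,
        "sign": sign,
        "loading_value": loading_val,
        "silhouette": sil,
        "status": status,
    })
    table.loc[~selected, ["component"]] = 0
    scored = selected & ~np.isnan(sil)
    avg = float(np.mean(sil[scored])) if scored.any() else float("nan")
    return ClusterAssignment(table=table, average_silhouette=avg)


def tune_components(
    X: ModeledMatrix | np.ndarray, H_max: int, scale: bool = True
) -> tuple[int, pd.DataFrame]:
    """Choose the number of PCA components maximizing the average silhouette.

    Returns the chosen H (ties -> smaller H) and the full trace.
    """
    values, _ = _as_matrix(X)
    T, P = values.shape
    if not 1 <= H_max <= min(T - 1, P):
        raise ValidationError(f"H_max must be in [1, {min(T - 1, P)}]")
    rows = []
    for H in range(1, H_max + 1):
        dec = pca(values, H, scale=scale)
        assignment = assign_clusters(dec, values, scale=scale)
        rows.append({"H": H, "average_silhouette": assignment.average_silhouette})
    trace = pd.DataFrame(rows)
    best = int(trace.loc[trace["average_silhouette"].idxmax(), "H"])
    logger.info("cluster | tune_components chose H=%d", best)
    return best, trace


def _elbow(grid: Sequence[int], values: Sequence[float], delta: float) -> int:
    """Largest grid value before the first drop > delta from the running max.

    NaN silhouettes (degenerate clusterings) carry no information and are
    skipped.
    """
    running = -np.inf
    last_informative = grid[-1]
    for i, v in enumerate(values):
        if np.isnan(v):
            continue
        if running - v > delta and i > 0:
            return int(grid[i - 1])
        running = max(running, v)
        last_informative = grid[i]
    return int(last_informative)


def tune_keepx(
    X: ModeledMatrix | np.ndarray,
    H: int,
    grid: Sequence[int],
    delta: float = 0.05,
    scale: bool = True,
) -> tuple[list[int], pd.DataFrame]:
    """Tune the number of retained features per sparse-PCA component.

    For each component in turn (earlier components fixed at their chosen
    keepX), the per-cluster average silhouette of that component's two
    sign clusters is traced along the grid; keepX is set just before the
    first sudden decrease (absolute drop > ``delta`` from the running
    maximum), or at the grid maximum if no such drop occurs.
    """
    grid = sorted(int(g) for g in grid)
    if not grid:
        raise ValidationError("keepx grid is empty")
    values, _ = _as_matrix(X)
    if grid[-1] > values.shape[1]:
        raise ValidationError("keepx grid exceeds the number of features")
    chosen: list[int] = []
    rows = []
    for h in range(1, H + 1):
        trace_h = []
        for g in grid:
            keepx = chosen + [g]
            dec = spca(values, h, keepx, scale=scale)
            assignment = assign_clusters(dec, values, scale=scale)
            t = assignment.table
            mask = (t["component"] == h) & (t["status"] != "unselected")
            cluster_avgs = [
                t.loc[mask & (t["sign"] == s), "silhouette"].mean()
                for s in ("+", "-")
                if (mask & (t["sign"] == s)).any()
            ]
            finite = [v for v in cluster_avgs if not np.isnan(v)]
            val = float(np.mean(finite)) if finite else float("nan")
            trace_h.append(val)
            rows.append({"component": h, "keepx": g, "average_silhouette": val})
        chosen.append(_elbow(grid, trace_h, delta))
    trace = pd.DataFrame(rows)
    logger.info("cluster | tune_keepx chose keepx=%s", chosen)
    return chosen, trace
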