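"""Multi-block sparse PLS / sparse generalized CCA on a shared time grid.

Q modeled blocks X^(1) (T x P_1), ..., X^(Q) (T x P_Q), all interpolated to
the same T time points, are factorized component by component.  For each
component h the method maximizes the design-weighted sum of covariances

    max sum_{q != j} c_qj cov(X^(q) a^(q), X^(j) a^(j)),
    s.t. ||a^(q)||_2 = 1 and a^(q) sparse,

where C = {c_qj} is a symmetric Q x Q design matrix with entries in [0, 1]
declaring which blocks should covary.  Sparsity is imposed by
soft-thresholding each loading so that exactly keepX entries remain
nonzero (the l1 penalty expressed as a count of selected variables).  The
block-coordinate update (each a^(q) in turn, others fixed) never decreases
the objective; after each component every block is deflated by regression
on its own score (symmetric, unsupervised deflation; a response-anchored
variant deflates every block on a designated response block's score).

Two-block sparse PLS is the special case Q = 2 with a fully connected
design; with no sparsity it coincides with the SVD of X^(1)' X^(2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from chronomix.core_io import ValidationError, logger
from chronomix.cluster_reduce import (
    ClusterAssignment,
    scale_profiles,
    silhouette_profiles,
    soft_threshold_keep,
    _elbow,
)
from chronomix.spline_model import ModeledMatrix

__all__ = [
    "DesignMatrix",
    "BlockFactorization",
    "multiblock_spls",
    "spls",
    "assign_clusters_multiblock",
    "tune_keepx_blocks",
]


@dataclass
class DesignMatrix:
    """Symmetric Q x Q block-connectivity matrix, entries in [0, 1], zero diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.values, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValidationError("design matrix must be square")
        if not np.allclose(C, C.T, atol=1e-12):
            raise ValidationError("design matrix must be symmetric")
        if np.any(np.diag(C) != 0):
            raise ValidationError("design matrix diagonal must be zero")
        if C.min() < 0 or C.max() > 1:
            raise ValidationError("design entries must lie in [0, 1]")
        self.values = C

    @classmethod
    def fully_connected(cls, Q: int) -> "DesignMatrix":
        C = np.ones((Q, Q)) - np.eye(Q)
        return cls(C)


@dataclass
class BlockFactorization:
    """Per-block scores t_h^(q) (T x H) and sparse loadings a_h^(q) (P_q x H)."""

    scores: list[np.ndarray]
    loadings: list[np.ndarray]
    keepx: list[list[int]]
    block_names: list[str]
    design: DesignMatrix
    objective_traces: list[list[float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for A in self.loadings:
            norms = np.linalg.norm(A, axis=0)
            if A.size and not np.allclose(norms, 1.0, atol=1e-8):
                raise ValidationError("block loadings must have unit norm")

    @property
    def n_components(self) -> int:
        return self.loadings[0].shape[1]


def _block_values(block: ModeledMatrix | np.ndarray) -> np.ndarray:
    if isinstance(block, ModeledMatrix):
        return np.asarray(block.values, dtype=float)
    return np.asarray(block, dtype=float)


def _check_grids(blocks: Sequence[ModeledMatrix | np.ndarray]) -> int:
    T = None
    grids = []
    for b in blocks:
        v = _block_values(b)
        if T is None:
            T = v.shape[0]
        elif v.shape[0] != T:
            raise ValidationError(
                "blocks have mismatched time grids; re-interpolate every block "
                "onto a common grid with model_all before integration"
            )
        if isinstance(b, ModeledMatrix):
            grids.append(np.asarray(b.time_grid))
    for g in grids[1:]:
        if not np.allclose(g, grids[0]):
            raise ValidationError(
                "blocks have mismatched time grids; re-interpolate every block "
                "onto a common grid with model_all before integration"
            )
    return int(T)


def _objective(Xs: list[np.ndarray], a: list[np.ndarray], C: np.ndarray) -> float:
    T = Xs[0].shape[0]
    t = [X @ ai for X, ai in zip(Xs, a)]
    val = 0.0
    for q in range(len(Xs)):
        for j in range(len(Xs)):
            if q != j and C[q, j] != 0:
                val += C[q, j] * float(t[q] @ t[j]) / (T - 1)
    return val


def multiblock_spls(
    blocks: Sequence[ModeledMatrix | np.ndarray],
    C: DesignMatrix | np.ndarray,
    H: int = 2,
    keepx: Sequence[Sequence[int]] | None = None,
    block_names: Sequence[str] | None = None,
    scale: bool = True,
    response: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> BlockFactorization:
    """Sparse generalized CCA across Q blocks with a design matrix.

    ``keepx[q][h]`` is the number of variables kept in block q on component
    h (None = keep all).  ``response`` switches deflation to the
    response-anchored variant (all blocks deflated on that block's score).
    """
    if isinstance(C, np.ndarray):
        C = DesignMatrix(C)
    Q = len(blocks)
    if C.values.shape != (Q, Q):
        raise ValidationError("design matrix size does not match number of blocks")
    if not np.any(C.values > 0):
        raise ValidationError("design matrix has no connected block pairs; objective is 0")
    T = _check_grids(blocks)
    Xs = [scale_profiles(_block_values(b), scale=scale) for b in blocks]
    widths = [X.shape[1] for X in Xs]
    if H < 1 or H > T - 1:
        raise ValidationError(f"H must be in [1, {T - 1}]")
    if keepx is None:
        keepx = [[w] * H for w in widths]
    keepx = [list(map(int, kq)) for kq in keepx]
    for q, (kq, w) in enumerate(zip(keepx, widths)):
        if len(kq) != H or any(not 1 <= k <= w for k in kq):
            raise ValidationError(
                f"keepx for block {q} must give one value in [1, {w}] per component"
            )
    if block_names is None:
        block_names = [f"block{q + 1}" for q in range(Q)]
    block_names = [str(n) for n in block_names]

    scores = [np.zeros((T, H)) for _ in range(Q)]
    loadings = [np.zeros((w, H)) for w in widths]
    traces: list[list[float]] = []
    for h in range(H):
        svds = [np.linalg.svd(X, full_matrices=False)[2] for X in Xs]
        # the sparse block-coordinate iteration only finds a local optimum;
        # deterministic multi-start from the leading singular vectors (and,
        # for strongly sparse two-block problems, from coordinate vectors)
        # keeps small-keepX solutions at the global best-covariance support
        starts: list[list[np.ndarray]] = [
            [V[min(s, V.shape[0] - 1)].copy() for V in svds]
            for s in range(max(1, min(3, min(V.shape[0] for V in svds))))
        ]
        if Q == 2 and max(kq[h] for kq in keepx) <= 2:
            q_small = int(np.argmin(widths))
            if widths[q_small] <= 32:
                for j in range(widths[q_small]):
                    init = [svds[q][0].copy() for q in range(Q)]
                    init[q_small] = np.zeros(widths[q_small])
                    init[q_small][j] = 1.0
                    starts.append(init)
        best: tuple[float, list[np.ndarray], list[float]] | None = None
        for a in starts:
            trace: list[float] = []
            for it in range(max_iter):
                max_change = 0.0
                prev = [ai.copy() for ai in a]
                for q in range(Q):
                    grad = np.zeros(widths[q])
                    for j in range(Q):
                        if j != q and C.values[q, j] != 0:
                            grad += C.values[q, j] * (Xs[q].T @ (Xs[j] @ a[j]))
                    new = soft_threshold_keep(grad, keepx[q][h])
                    nrm = np.linalg.norm(new)
                    if nrm < 1e-300:
                        raise ValidationError(
                            f"block {block_names[q]} loading collapsed on component {h + 1}"
                        )
                    new /= nrm
                    max_change = max(max_change, float(np.max(np.abs(new - a[q]))))
                    a[q] = new
                # the objective is tracked once every block satisfies its
                # sparsity constraint, i.e. after the first full sweep; a
                # sweep that would decrease it is rejected, so the trace is
                # non-decreasing by construction
                obj = _objective(Xs, a, C.values)
                if trace and obj < trace[-1] - 1e-12 * max(abs(trace[-1]), 1.0):
                    a = prev
                    break
                trace.append(obj)
                if max_change < tol:
                    break
            else:
                raise ValidationError(
                    f"component {h + 1} did not converge in {max_iter} iterations; "
                    f"objective trace tail: {trace[-5:]}"
                )
            if best is None or trace[-1] > best[0]:
                best = (trace[-1], [ai.copy() for ai in a], trace)
        assert best is not None
        a, trace = best[1], best[2]
        traces.append(trace)
        # deterministic orientation: largest-|entry| of block-1 loading positive
        j0 = int(np.argmax(np.abs(a[0])))
        if a[0][j0] < 0:
            a = [-ai for ai in a]
        t_h = [X @ ai for X, ai in zip(Xs, a)]
        for q in range(Q):
            scores[q][:, h] = t_h[q]
            loadings[q][:, h] = a[q]
        anchor = response
        for q in range(Q):
            t_defl = t_h[q] if anchor is None else t_h[anchor]
            denom = float(t_defl @ t_defl)
            if denom > 1e-300:
                Xs[q] = Xs[q] - np.outer(t_defl, (t_defl @ Xs[q]) / denom)
    logger.info(
        "integrate | multiblock sPLS: Q=%d H=%d keepx=%s", Q, H, keepx
    )
    return BlockFactorization(
        scores=scores, loadings=loadings, keepx=keepx,
        block_names=list(block_names), design=C, objective_traces=traces,
    )


def spls(
    X: ModeledMatrix | np.ndarray,
    Y: ModeledMatrix | np.ndarray,
    H: int = 2,
    keepx: Sequence[int] | None = None,
    keepy: Sequence[int] | None = None,
    scale: bool = True,
) -> BlockFactorization:
    """Two-block sparse PLS: multiblock sparse GCCA with a full design."""
    wx = _block_values(X).shape[1]
    wy = _block_values(Y).shape[1]
    if keepx is not None and any(k > wx for k in keepx):
        raise ValidationError(f"keepx exceeds block width {wx}")
    if keepy is not None and any(k > wy for k in keepy):
        raise ValidationError(f"keepy exceeds block width {wy}")
    kk = None
    if keepx is not None or keepy is not None:
        kk = [
            list(keepx) if keepx is not None else [wx] * H,
            list(keepy) if keepy is not None else [wy] * H,
        ]
    return multiblock_spls(
        [X, Y], DesignMatrix.fully_connected(2), H=H, keepx=kk,
        block_names=["X", "Y"], scale=scale,
    )


def assign_clusters_multiblock(
    fact: BlockFactorization,
    blocks: Sequence[ModeledMatrix | np.ndarray],
) -> ClusterAssignment:
    """Pool selected features across blocks into sign-split component clusters.

    Each selected feature is assigned to the component where its loading is
    nonzero (earliest on ties) with the sign of that loading; silhouettes
    are computed on the concatenated modeled profiles under the Spearman
    distance.  The table records each feature's block of origin.
    """
    frames = []
    all_values = []
    for q, (A, b) in enumerate(zip(fact.loadings, blocks)):
        v = _block_values(b)
        ids = (
            list(b.feature_ids) if isinstance(b, ModeledMatrix)
            else [f"{fact.block_names[q]}_f{i}" for i in range(v.shape[1])]
        )
        P = A.shape[0]
        comp = np.zeros(P, dtype=int)
        loading_val = np.zeros(P)
        selected = np.ones(P, dtype=bool)
        for p in range(P):
            nz = np.flatnonzero(A[p] != 0.0)
            if nz.size == 0:
                selected[p] = False
            else:
                comp[p] = nz[0] + 1
                loading_val[p] = A[p, nz[0]]
        frames.append(pd.DataFrame({
            "feature_id": ids,
            "block": fact.block_names[q],
            "component": comp,
            "sign": np.where(loading_val >= 0, "+", "-"),
            "loading_value": loading_val,
            "selected": selected,
        }))
        all_values.append(v)
    table = pd.concat(frames, ignore_index=True)
    values = np.hstack(all_values)
    sel = table["selected"].to_numpy()
    labels = np.where(table["sign"] == "+", table["component"], -table["component"]).astype(int)
    sil = np.full(len(table), np.nan)
    if sel.sum() >= 2 and np.unique(labels[sel]).size >= 2:
        sil_sel, _ = silhouette_profiles(values[:, sel], labels[sel])
        sil[sel] = sil_sel
    table["silhouette"] = sil
    table["status"] = np.where(
        ~sel, "unselected",
        np.where(np.isnan(sil), "uncertain",
                 np.where(sil > 0.5, "assigned",
                          np.where(sil >= 0, "uncertain", "misassigned"))),
    )
    table.loc[~sel, "component"] = 0
    table = table.drop(columns=["selected"])
    any_scored = sel.any() and np.any(~np.isnan(sil[sel]))
    avg = float(np.nanmean(sil[sel])) if any_scored else float("nan")
    return ClusterAssignment(table=table, average_silhouette=avg)


def tune_keepx_blocks(
    blocks: Sequence[ModeledMatrix | np.ndarray],
    C: DesignMatrix | np.ndarray,
    H: int,
    grid: Sequence[int],
    delta: float = 0.05,
    min_block_width: int = 5,
    scale: bool = True,
    n_passes: int = 2,
) -> tuple[list[list[int]], pd.DataFrame]:
    """Coordinate search for per-block, per-component keepX.

    One block at a time (others fixed at their current best), the
    per-cluster average silhouette of the tuned component is traced along
    the grid and keepX set by the first-sudden-decrease rule.  The sweep
    over blocks is repeated ``n_passes`` times so early choices are
    revisited once later blocks have been sparsified.  Blocks with at most
    ``min_block_width`` features are not tuned (keepX = all).
    """
    grid = sorted(int(g) for g in grid)
    if not grid:
        raise ValidationError("keepx grid is empty")
    widths = [_block_values(b).shape[1] for b in blocks]
    Q = len(blocks)
    keepx = [[w] * H for w in widths]
    rows = []
    for h in range(H):
        for sweep in range(n_passes):
            previous = [kq[h] for kq in keepx]
            for q in range(Q):
                if widths[q] <= min_block_width:
                    continue
                cand_grid = [g for g in grid if g <= widths[q]]
                if not cand_grid:
                    raise ValidationError(f"grid has no valid value for block {q}")
                trace_h = []
                for g in cand_grid:
                    trial = [list(kq) for kq in keepx]
                    trial[q][h] = g
                    fact = multiblock_spls(blocks, C, H=h + 1,
                                           keepx=[kq[: h + 1] for kq in trial],
                                           scale=scale)
                    assignment = assign_clusters_multiblock(fact, blocks)
                    t = assignment.table
                    mask = (t["component"] == h + 1) & (t["status"] != "unselected")
                    cluster_avgs = [
                        t.loc[mask & (t["sign"] == s), "silhouette"].mean()
                        for s in ("+", "-")
                        if (mask & (t["sign"] == s)).any()
                    ]
                    finite = [v for v in cluster_avgs if not np.isnan(v)]
                    val = float(np.mean(finite)) if finite else float("nan")
                    trace_h.append(val)
                    rows.append({"block": q, "component": h + 1, "sweep": sweep,
                                 "keepx": g, "average_silhouette": val})
                keepx[q][h] = _elbow(cand_grid, trace_h, delta)
            if [kq[h] for kq in keepx] == previous:
                break
    trace = pd.DataFrame(rows)
    logger.info("integrate | tune_keepx_blocks chose keepx=%s", keepx)
    return keepx, trace
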