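"""Serial linear mixed-model spline (LMMS) fitting of feature trajectories.

Each feature's time course, observed across several subjects (biological
replicates), is fitted by four nested models of increasing complexity:

1. a straight line ``y = b0 + b1 t`` by ordinary least squares, assuming no
   individual variation;
2. a penalized spline: the line plus truncated basis functions whose
   coefficients ``u_k ~ N(0, s2_u)`` are random effects, fitted by REML —
   the estimated variance ratio controls the amount of smoothing;
3. model 2 plus a subject-specific random intercept ``a_i ~ N(0, s2_a)``;
4. model 3 plus a subject-specific random slope ``b_i ~ N(0, s2_b)``
   (intercept and slope independent).

Fitting is serial: model k+1 replaces model k only when its newly added
variance component is materially nonzero and the fit's MSE does not
increase ("variance-collapse" rule); a REML likelihood-ratio alternative
with a 50:50 mixture chi-square null is available via ``selection="lrt"``.

The population mean curve (fixed effects + spline effects, subject effects
set to zero) can then be evaluated on an arbitrary grid inside the observed
time interval, turning an N x P x T study into a T x P matrix of smooth
trajectories shared across data blocks.  No extrapolation is allowed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from chronomix.core_io import ValidationError, logger
from chronomix.preprocessing import ClrMatrix

__all__ = [
    "SplineBasisSpec",
    "SplineFit",
    "ModeledMatrix",
    "fit_feature",
    "predict",
    "model_all",
]

BasisKind = Literal["cubic_all_inner_knots", "penalized_truncated_line", "penalized_cubic"]

_LOG10_RATIO_BOUNDS = (-8.0, 12.0)
_MAX_QUANTILE_KNOTS = 7


@dataclass
class SplineBasisSpec:
    """Spline basis: kind plus interior knots (in scaled [0, 1] time).

    ``cubic_all_inner_knots`` places a truncated cubic at every inner
    observed time (suited to few time points, where the basis can
    interpolate); the penalized variants place truncated lines or cubics at
    interior quantiles of the observed times.
    """

    kind: BasisKind
    knots: np.ndarray
    t_min: float
    t_max: float

    @classmethod
    def from_times(cls, times: Sequence[float], kind: BasisKind = "cubic_all_inner_knots") -> "SplineBasisSpec":
        t = np.unique(np.asarray(times, dtype=float))
        if t.size < 2:
            raise ValidationError("need at least 2 distinct times for a spline basis")
        t_min, t_max = float(t[0]), float(t[-1])
        s = (t - t_min) / (t_max - t_min)
        if kind == "cubic_all_inner_knots":
            knots = s[1:-1]
        elif kind in ("penalized_truncated_line", "penalized_cubic"):
            if t.size < 4:
                raise ValidationError("penalized bases need >= 4 distinct time points")
            n_knots = min(t.size // 2, _MAX_QUANTILE_KNOTS)
            probs = (np.arange(1, n_knots + 1)) / (n_knots + 1)
            knots = np.quantile(s, probs)
        else:
            raise ValidationError(f"unknown basis kind {kind!r}")
        return cls(kind=kind, knots=np.asarray(knots, dtype=float), t_min=t_min, t_max=t_max)

    def _scale(self, times: np.ndarray) -> np.ndarray:
        return (times - self.t_min) / (self.t_max - self.t_min)

    def design(self, times: Sequence[float]) -> np.ndarray:
        """Spline design matrix Z (n x K) at the given (original-unit) times."""
        s = self._scale(np.asarray(times, dtype=float))
        if self.knots.size == 0:
            return np.empty((s.size, 0))
        d = s[:, None] - self.knots[None, :]
        if self.kind == "penalized_truncated_line":
            return np.maximum(d, 0.0)
        return np.maximum(d, 0.0) ** 3


@dataclass
class SplineFit:
    """Result of serial LMMS fitting for one feature."""

    model_class: int
    beta: np.ndarray                      # (intercept, slope) on original time
    spline_coeffs: np.ndarray             # BLUPs u_k (empty for class 1)
    spline_variance: float
    subject_ids: list[str]
    subject_intercepts: np.ndarray        # BLUPs a_i (class >= 3, else empty)
    subject_intercept_variance: float
    subject_slopes: np.ndarray            # BLUPs b_i (class 4, else empty)
    subject_slope_variance: float
    residual_variance: float
    mse: float
    bp_pvalue: float | None               # Breusch-Pagan p, class 1 only
    basis: SplineBasisSpec | None
    t_min: float = 0.0
    t_max: float = 1.0

    def __post_init__(self) -> None:
        for v in (self.spline_variance, self.subject_intercept_variance,
                  self.subject_slope_variance, self.residual_variance, self.mse):
            if v < 0:
                raise ValidationError("variances and MSE must be non-negative")
        if self.model_class == 1 and (self.spline_coeffs.size or self.subject_intercepts.size):
            raise ValidationError("class-1 fits carry no spline or subject effects")

    def to_dict(self) -> dict:
        return {
            "model_class": self.model_class,
            "beta": self.beta.tolist(),
            "spline_coeffs": self.spline_coeffs.tolist(),
            "spline_variance": self.spline_variance,
            "subject_intercept_variance": self.subject_intercept_variance,
            "subject_slope_variance": self.subject_slope_variance,
            "residual_variance": self.residual_variance,
            "mse": self.mse,
            "bp_pvalue": self.bp_pvalue,
        }


@dataclass
class ModeledMatrix:
    """Fitted trajectories on a shared grid: T time points x P features."""

    values: np.ndarray
    time_grid: np.ndarray
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if self.values.shape != (self.time_grid.size, len(self.feature_ids)):
            raise ValidationError("ModeledMatrix shape mismatch (T x P expected)")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValidationError("ModeledMatrix contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.T, index=self.feature_ids, columns=self.time_grid)


class _RemlProblem:
    """Profiled REML for y = X b + U g + e with per-block variance ratios.

    U stacks random-effect blocks column-wise; each block c shares one
    variance ratio lam_c = s2_c / s2_e.  All criterion evaluations use
    cross-products precomputed once, so a single evaluation costs a
    Cholesky factorization of a q x q matrix (q = total random columns).
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, blocks: list[np.ndarray]):
        self.y = y
        self.X = X
        self.blocks = blocks
        self.n, self.p = X.shape
        self.U = np.hstack(blocks) if blocks else np.empty((self.n, 0))
        self.sizes = [b.shape[1] for b in blocks]
        self.UtU = self.U.T @ self.U
        self.UtX = self.U.T @ X
        self.Uty = self.U.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.q = self.U.shape[1]

    def _ratios_to_diag(self, log10_ratios: np.ndarray) -> np.ndarray:
        lo, hi = _LOG10_RATIO_BOUNDS
        lam = 10.0 ** np.clip(log10_ratios, lo, hi)
        return np.repeat(lam, self.sizes)

    def neg2_reml(self, log10_ratios: np.ndarray) -> float:
        d = self._ratios_to_diag(np.asarray(log10_ratios, dtype=float))
        s = np.sqrt(d)
        M = np.eye(self.q) + (s[:, None] * self.UtU) * s[None, :]
        try:
            cho = cho_factor(M, lower=True)
        except np.linalg.LinAlgError:
            return np.inf
        logdet_V = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        sUtX = s[:, None] * self.UtX
        sUty = s * self.Uty
        XtViX = self.XtX - sUtX.T @ cho_solve(cho, sUtX)
        XtViy = self.Xty - sUtX.T @ cho_solve(cho, sUty)
        ytViy = self.yty - sUty @ cho_solve(cho, sUty)
        try:
            beta = np.linalg.solve(XtViX, XtViy)
        except np.linalg.LinAlgError:
            return np.inf
        rss = max(float(ytViy - 2 * beta @ XtViy + beta @ (XtViX @ beta)), 1e-300)
        sigma2 = rss / (self.n - self.p)
        sign, logdet_XtViX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf
        return (self.n - self.p) * math.log(sigma2) + logdet_V + logdet_XtViX

    def solve(self, log10_ratios: np.ndarray) -> dict:
        """Estimates (beta, BLUPs, variances, fitted values) at given ratios."""
        d = self._ratios_to_diag(np.asarray(log10_ratios, dtype=float))
        s = np.sqrt(d)
        M = np.eye(self.q) + (s[:, None] * self.UtU) * s[None, :]
        cho = cho_factor(M, lower=True)
        sUtX = s[:, None] * self.UtX
        sUty = s * self.Uty
        XtViX = self.XtX - sUtX.T @ cho_solve(cho, sUtX)
        XtViy = self.Xty - sUtX.T @ cho_solve(cho, sUty)
        ytViy = self.yty - sUty @ cho_solve(cho, sUty)
        beta = np.linalg.solve(XtViX, XtViy)
        rss = max(float(ytViy - 2 * beta @ XtViy + beta @ (XtViX @ beta)), 0.0)
        sigma2 = rss / max(self.n - self.p, 1)
        w = self.Uty - self.UtX @ beta
        gamma = d * (w - (self.UtU * s[None, :]) @ cho_solve(cho, s * w))
        fitted = self.X @ beta + self.U @ gamma
        resid = self.y - fitted
        out: dict = {
            "beta": beta,
            "gamma": gamma,
            "sigma2": float(sigma2),
            "mse": float(np.mean(resid**2)),
            "fitted": fitted,
        }
        offset = 0
        comps = []
        for lam_size, lam in zip(self.sizes, 10.0 ** np.clip(np.asarray(log10_ratios, dtype=float), *_LOG10_RATIO_BOUNDS)):
            comps.append(float(lam * sigma2))
            offset += lam_size
        out["component_variances"] = comps
        return out


def _bp_pvalue(residuals: np.ndarray, times: np.ndarray) -> float:
    """Breusch-Pagan p-value: n R^2 of squared residuals on time vs chi2(1)."""
    r2sq = residuals**2
    if np.var(r2sq) < 1e-300 or np.var(times) < 1e-300:
        return 1.0
    import statsmodels.api as sm

    exog = sm.add_constant(np.asarray(times, dtype=float))
    lm, lm_pvalue, _, _ = sm.stats.diagnostic.het_breuschpagan(residuals, exog)
    return float(lm_pvalue)


def _ols_line(y: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, resid, float(np.mean(resid**2))


def _subject_design(t: np.ndarray, subjects: np.ndarray, slopes: bool) -> tuple[np.ndarray, list[str]]:
    """Indicator (or indicator*t) columns, one per subject with >= 2 points.

    Subjects observed only once contribute to the fixed effects alone, as
    their random effect is unidentifiable.
    """
    ids, counts = np.unique(subjects, return_counts=True)
    usable = [str(i) for i, c in zip(ids, counts) if c >= 2]
    cols = np.zeros((t.size, len(usable)))
    for j, sid in enumerate(usable):
        mask = subjects == sid
        cols[mask, j] = t[mask] if slopes else 1.0
    return cols, usable


def fit_feature(
    values: Sequence[float],
    meta: pd.DataFrame,
    basis: SplineBasisSpec | str = "cubic_all_inner_knots",
    selection: Literal["variance", "lrt"] = "variance",
    lrt_alpha: float = 0.05,
    variance_rtol: float = 1e-8,
) -> SplineFit:
    """Serially fit models 1-4 to one feature's trajectory.

    Parameters
    ----------
    values : per-sample response values, aligned with ``meta`` rows.
    meta : DataFrame with at least ``subject_id`` and ``time`` columns.
    basis : basis kind or a prebuilt :class:`SplineBasisSpec`.
    selection : ``"variance"`` accepts a more complex model when its new
        variance component exceeds ``variance_rtol`` times the response
        variance and the MSE does not increase; ``"lrt"`` uses a REML
        likelihood-ratio test against a 50:50 chi-square mixture null.
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(meta["time"], dtype=float)
    subjects = np.asarray(meta["subject_id"]).astype(str)
    if y.size != t.size:
        raise ValidationError("values and metadata lengths differ")
    if np.unique(t).size < 2:
        raise ValidationError("all observation times are equal; design is singular")
    if isinstance(basis, str):
        basis = SplineBasisSpec.from_times(t, basis)
    t_min, t_max = basis.t_min, basis.t_max

    # --- model 1: straight line (OLS) ---------------------------------
    beta1, resid1, mse1 = _ols_line(y, t)
    bp = _bp_pvalue(resid1, t) if y.size >= 4 else None
    fit = SplineFit(
        model_class=1, beta=beta1, spline_coeffs=np.empty(0), spline_variance=0.0,
        subject_ids=[], subject_intercepts=np.empty(0), subject_intercept_variance=0.0,
        subject_slopes=np.empty(0), subject_slope_variance=0.0,
        residual_variance=mse1, mse=mse1, bp_pvalue=bp, basis=basis,
        t_min=t_min, t_max=t_max,
    )
    var_y = float(np.var(y))
    if mse1 <= max(1e-14 * max(var_y, 1.0), 1e-28):
        return fit  # a perfect line; nothing more complex can improve it
    vtol = variance_rtol * max(var_y, 1e-12)

    X = np.column_stack([np.ones_like(t), t])
    Z_raw = basis.design(t)
    if Z_raw.shape[1] == 0:
        return fit
    # column-normalize the random-effect design: the truncated-power basis
    # is badly conditioned and unit-norm columns keep the REML ridge stable
    z_scale = np.linalg.norm(Z_raw, axis=0)
    z_scale[z_scale < 1e-300] = 1.0
    Z = Z_raw / z_scale

    # noiseless shortcut: when the full unpenalized basis fits exactly, the
    # REML variance ratio diverges and the penalized spline converges to the
    # minimum-norm interpolant — return that limit directly
    B = np.hstack([X, Z])
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    rss0 = float(np.mean((y - B @ coef) ** 2))
    if y.size > B.shape[1] + 2 and rss0 <= max(1e-16 * max(var_y, 1.0), 1e-28):
        u = coef[2:] / z_scale
        return SplineFit(
            model_class=2, beta=coef[:2], spline_coeffs=u,
            spline_variance=float(np.var(coef[2:])) if coef[2:].size else 0.0,
            subject_ids=[], subject_intercepts=np.empty(0),
            subject_intercept_variance=0.0, subject_slopes=np.empty(0),
            subject_slope_variance=0.0, residual_variance=rss0, mse=rss0,
            bp_pvalue=None, basis=basis, t_min=t_min, t_max=t_max,
        )

    current = fit
    current_mse = mse1
    current_ll = None  # -2 REML of the current mixed model (models >= 2)

    def accept(new_ll: float | None, new_var: float, new_mse: float) -> bool:
        if selection == "lrt" and current_ll is not None and new_ll is not None:
            delta = max(current_ll - new_ll, 0.0)
            p = 0.5 * stats.chi2.sf(delta, df=1)
            return p < lrt_alpha
        return new_var > vtol and new_mse <= current_mse * (1 + 1e-9)

    # --- model 2: penalized spline ------------------------------------
    prob2 = _RemlProblem(y, X, [Z])
    if selection == "lrt":
        # the straight line is the zero-variance boundary of model 2
        current_ll = prob2.neg2_reml(np.array([_LOG10_RATIO_BOUNDS[0]]))
    res2 = optimize.minimize_scalar(
        lambda l: prob2.neg2_reml(np.array([l])), bounds=_LOG10_RATIO_BOUNDS,
        method="bounded", options={"xatol": 5e-2},
    )
    log_lam_u = float(res2.x)
    sol2 = prob2.solve(np.array([log_lam_u]))
    s2_u = sol2["component_variances"][0]
    fit2 = SplineFit(
        model_class=2, beta=sol2["beta"], spline_coeffs=sol2["gamma"] / z_scale,
        spline_variance=s2_u, subject_ids=[], subject_intercepts=np.empty(0),
        subject_intercept_variance=0.0, subject_slopes=np.empty(0),
        subject_slope_variance=0.0, residual_variance=sol2["sigma2"],
        mse=sol2["mse"], bp_pvalue=None, basis=basis, t_min=t_min, t_max=t_max,
    )
    if accept(float(res2.fun), s2_u, sol2["mse"]):
        current, current_mse, current_ll = fit2, sol2["mse"], float(res2.fun)
    if current_mse <= 1e-10 * max(var_y, 1e-12):
        return current  # essentially perfect; subject effects cannot help

    # --- models 3 and 4: subject random intercept, then slope ---------
    def _nm(problem: _RemlProblem, x0: np.ndarray, maxfev: int):
        # wide initial simplex: variance ratios live on a log scale, and the
        # default simplex is far too small to escape a flat boundary region
        simplex = [x0] + [x0 + 3.0 * e for e in np.eye(x0.size)]
        return optimize.minimize(
            problem.neg2_reml, x0, method="Nelder-Mead",
            options={"xatol": 1e-1, "fatol": 1e-4, "maxfev": maxfev,
                     "initial_simplex": np.asarray(simplex)},
        )

    Zi_raw, subj_ids = _subject_design(t, subjects, slopes=False)
    if len(subj_ids) >= 2:
        zi_scale = np.linalg.norm(Zi_raw, axis=0)
        zi_scale[zi_scale < 1e-300] = 1.0
        Zi = Zi_raw / zi_scale
        k = Z.shape[1]
        prob3 = _RemlProblem(y, X, [Z, Zi])
        res3 = _nm(prob3, np.array([log_lam_u, -6.0]), 100)
        sol3 = prob3.solve(res3.x)
        s2_a = sol3["component_variances"][1]
        if accept(float(res3.fun), s2_a, sol3["mse"]):
            current = SplineFit(
                model_class=3, beta=sol3["beta"],
                spline_coeffs=sol3["gamma"][:k] / z_scale,
                spline_variance=sol3["component_variances"][0],
                subject_ids=subj_ids,
                subject_intercepts=sol3["gamma"][k:] / zi_scale,
                subject_intercept_variance=s2_a,
                subject_slopes=np.empty(0), subject_slope_variance=0.0,
                residual_variance=sol3["sigma2"], mse=sol3["mse"],
                bp_pvalue=None, basis=basis, t_min=t_min, t_max=t_max,
            )
            current_mse, current_ll = sol3["mse"], float(res3.fun)

        Zs_raw, _ = _subject_design(t, subjects, slopes=True)
        zs_scale = np.linalg.norm(Zs_raw, axis=0)
        zs_scale[zs_scale < 1e-300] = 1.0
        Zs = Zs_raw / zs_scale
        prob4 = _RemlProblem(y, X, [Z, Zi, Zs])
        res4 = _nm(prob4, np.array([log_lam_u, res3.x[1], -6.0]), 130)
        sol4 = prob4.solve(res4.x)
        s2_b = sol4["component_variances"][2]
        if accept(float(res4.fun), s2_b, sol4["mse"]):
            m = Zi.shape[1]
            current = SplineFit(
                model_class=4, beta=sol4["beta"],
                spline_coeffs=sol4["gamma"][:k] / z_scale,
                spline_variance=sol4["component_variances"][0],
                subject_ids=subj_ids,
                subject_intercepts=sol4["gamma"][k: k + m] / zi_scale,
                subject_intercept_variance=sol4["component_variances"][1],
                subject_slopes=sol4["gamma"][k + m:] / zs_scale,
                subject_slope_variance=s2_b,
                residual_variance=sol4["sigma2"], mse=sol4["mse"],
                bp_pvalue=None, basis=basis, t_min=t_min, t_max=t_max,
            )
    return current


def predict(fit: SplineFit, times: Sequence[float]) -> np.ndarray:
    """Population-mean curve (subject effects zero) at the requested times.

    Raises on any time outside the fitted interval: no extrapolation.
    """
    times = np.asarray(times, dtype=float)
    tol = 1e-9 * max(abs(fit.t_min), abs(fit.t_max), 1.0)
    if times.size and (times.min() < fit.t_min - tol or times.max() > fit.t_max + tol):
        raise ValidationError(
            f"requested times outside fitted interval [{fit.t_min}, {fit.t_max}]; "
            "extrapolation is not supported"
        )
    out = fit.beta[0] + fit.beta[1] * times
    if fit.model_class >= 2 and fit.spline_coeffs.size:
        out = out + fit.basis.design(times) @ fit.spline_coeffs
    return out


def model_all(
    data: ClrMatrix | "ContinuousBlock",
    basis: SplineBasisSpec | str = "cubic_all_inner_knots",
    grid: Sequence[float] | int | None = None,
    selection: Literal["variance", "lrt"] = "variance",
) -> tuple[list[SplineFit | None], ModeledMatrix]:
    """Fit every feature and interpolate the mean curves onto a shared grid.

    ``grid`` may be an explicit sorted list of times, an integer number of
    equally spaced points over the observed interval, or None (default: one
    point per distinct observed time).  Unfittable features are skipped with
    a log entry (their fit slot is None and they are dropped from the
    matrix).
    """
    values = np.asarray(data.values, dtype=float)
    meta = data.sample_meta
    times = np.asarray(meta["time"], dtype=float)
    t_min, t_max = float(times.min()), float(times.max())
    if grid is None:
        grid = np.unique(times)
    elif isinstance(grid, int):
        grid = np.linspace(t_min, t_max, grid)
    else:
        grid = np.asarray(grid, dtype=float)
        if np.any(np.diff(grid) < 0):
            raise ValidationError("interpolation grid must be sorted")
        if grid.min() < t_min - 1e-12 or grid.max() > t_max + 1e-12:
            raise ValidationError("interpolation grid must lie within the observed interval")

    fits: list[SplineFit | None] = []
    cols: list[np.ndarray] = []
    kept_ids: list[str] = []
    class_counts: dict[int, int] = {}
    for p, fid in enumerate(data.feature_ids):
        try:
            fit = fit_feature(values[p], meta, basis=basis, selection=selection)
        except ValidationError:
            logger.warning("model | feature %s unfittable; skipped", fid)
            fits.append(None)
            continue
        fits.append(fit)
        cols.append(predict(fit, grid))
        kept_ids.append(fid)
        class_counts[fit.model_class] = class_counts.get(fit.model_class, 0) + 1
    logger.info("model | model-class counts: %s", dict(sorted(class_counts.items())))
    matrix = ModeledMatrix(
        values=np.column_stack(cols) if cols else np.empty((len(grid), 0)),
        time_grid=grid,
        feature_ids=kept_ids,
    )
    return fits, matrix
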