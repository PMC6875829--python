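"""Post-fit quality filtering of straight-line profiles.

A feature whose trajectory is best fitted by a simple straight line may
reflect genuine linear dynamics — or just highly noisy data.  Two filters
separate the two cases:

* a **Breusch-Pagan test** on the line's residuals: heteroscedastic
  residuals (p < alpha) indicate a poor straight-line fit and the profile
  is removed;
* an **MSE bound**: straight-line profiles whose MSE exceeds the maximum
  MSE of the more complex spline models (classes 2-4) are removed.  This
  second filter is only applied when straight lines dominate the fit set
  (by default, more than half of all fits), where the Breusch-Pagan test
  alone is not stringent enough.

Spline-fitted profiles (classes 2-4) are always kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from chronomix.core_io import ValidationError, logger
from chronomix.spline_model import SplineFit

__all__ = ["FilterReport", "breusch_pagan", "filter_profiles"]


@dataclass
class FilterReport:
    """Outcome of profile filtering: kept / removed feature ids and bounds."""

    kept: list[str]
    removed_bp: list[str]
    removed_mse: list[str]
    mse_bound: float | None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        groups = [set(self.kept), set(self.removed_bp), set(self.removed_mse)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValidationError("filter report groups must partition the input")


def breusch_pagan(residuals: Sequence[float], times: Sequence[float]) -> float:
    """Breusch-Pagan heteroscedasticity p-value for straight-line residuals.

    The LM statistic n*R^2 from regressing squared residuals on time is
    referred to a chi-square(1) distribution.  Constant residuals give
    p = 1 (no evidence of heteroscedasticity).
    """
    residuals = np.asarray(residuals, dtype=float)
    times = np.asarray(times, dtype=float)
    if residuals.size != times.size:
        raise ValidationError("residuals and times must have equal length")
    if residuals.size < 4:
        raise ValidationError("Breusch-Pagan test needs at least 4 observations")
    sq = residuals**2
    if np.var(sq) < 1e-300 or np.var(times) < 1e-300:
        return 1.0
    import statsmodels.api as sm

    exog = sm.add_constant(times)
    _, p, _, _ = sm.stats.diagnostic.het_breuschpagan(residuals, exog)
    return float(np.clip(p, 0.0, 1.0))


def filter_profiles(
    fits: Sequence[SplineFit],
    feature_ids: Sequence[str] | None = None,
    alpha: float = 0.05,
    use_mse_bound: bool | Literal["auto"] = "auto",
    auto_linear_fraction: float = 0.5,
) -> FilterReport:
    """Filter straight-line (class-1) fits; spline fits pass unconditionally.

    ``use_mse_bound`` may be True (always apply the MSE bound), False
    (never), or ``"auto"`` (apply only when the class-1 fraction exceeds
    ``auto_linear_fraction``).
    """
    fits = list(fits)
    if not fits:
        raise ValidationError("no fits to filter")
    if feature_ids is None:
        feature_ids = [f"feature_{i}" for i in range(len(fits))]
    if len(feature_ids) != len(fits):
        raise ValidationError("feature_ids and fits lengths differ")

    linear = [i for i, f in enumerate(fits) if f.model_class == 1]
    complex_mses = [f.mse for f in fits if f.model_class >= 2]
    mse_bound: float | None = max(complex_mses) if complex_mses else None

    apply_mse = bool(use_mse_bound) if use_mse_bound != "auto" else (
        len(linear) > auto_linear_fraction * len(fits)
    )
    if apply_mse and mse_bound is None:
        logger.warning("filter | no class 2-4 fits: MSE bound undefined, skipped")
        apply_mse = False

    kept, removed_bp, removed_mse = [], [], []
    for fid, fit in zip(feature_ids, fits):
        if fit.model_class >= 2:
            kept.append(str(fid))
        elif fit.bp_pvalue is not None and fit.bp_pvalue < alpha:
            removed_bp.append(str(fid))
        elif apply_mse and fit.mse > mse_bound:
            removed_mse.append(str(fid))
        else:
            kept.append(str(fid))
    logger.info(
        "filter | alpha=%g mse_bound=%s kept=%d removed_bp=%d removed_mse=%d",
        alpha, f"{mse_bound:.4g}" if apply_mse and mse_bound is not None else "off",
        len(kept), len(removed_bp), len(removed_mse),
    )
    return FilterReport(
        kept=kept, removed_bp=removed_bp, removed_mse=removed_mse,
        mse_bound=mse_bound if apply_mse else None, alpha=alpha,
    )
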