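"""Population age-trend model: cubic regression splines with knot-count search.

Each gene's expression profile y_i at ages t_i is modelled by a least-squares
cubic spline f(x) on transformed age x (log2 PCD by default, because
developmental change concentrates perinatally). Interior knots sit at
empirical quantiles of the distinct transformed ages. The number of knots k
is the smallest for which the in-sample mean squared error drops below the
noise-variance estimate sigma2_hat:

    (1/n) sum_i (y_i - f(x_i))^2 < sigma2_hat

where sigma2_hat is the mean of sample variances over sliding windows of 10
age-consecutive raw values. If no k up to max_knots satisfies the bound, it
is relaxed to 2*sigma2_hat and the fit flagged ``relaxed``; if even that
fails, the max-knot fit is returned (still flagged).

Goodness of fit is a leave-one-sample-out R^2: each point is predicted by a
model fitted (noise estimate and knot count re-selected) on the other n-1
points; R^2 = 1 - SS_pred/SS_tot is at most 1 and can go negative when the
model overfits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import BSpline

from .datatypes import ExpressionProfile

logger = logging.getLogger(__name__)

WINDOW_DEFAULT = 10
RELAX_FACTOR_DEFAULT = 2.0  # bound doubling: MSE < 2*sigma2_hat

AgeTransform = Literal["linear", "log2"]


def transform_age(ages_pcd: np.ndarray, transform: AgeTransform = "log2") -> np.ndarray:
    ages_pcd = np.asarray(ages_pcd, dtype=float)
    if transform == "log2":
        if np.any(ages_pcd <= 0):
            raise ValueError("ages must be strictly positive for log2 transform")
        return np.log2(ages_pcd)
    if transform == "linear":
        return ages_pcd.copy()
    raise ValueError(f"unknown age transform {transform!r}")


def estimate_noise_variance(values: np.ndarray, window: int = WINDOW_DEFAULT) -> float:
    """Mean of sample variances over sliding (stride-1) windows of age-sorted values.

    Computed on raw values with no local detrending, so steep trends inflate
    the estimate; that bias is part of the procedure's definition.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        raise ValueError(f"need >= 3 points to estimate noise variance, got {n}")
    if n < window:
        logger.warning(
            "only %d points for a window of %d; using a single full window", n, window
        )
        window = n
    windows = sliding_window_view(values, window)
    return float(np.mean(np.var(windows, axis=1, ddof=1)))


@dataclass
class TrendModel:
    """A fitted population trend for one expression profile."""

    gene: str
    region: str
    knot_ages: np.ndarray  # interior knots, original PCD units
    fitted: np.ndarray
    residuals: np.ndarray
    sigma2_hat: float
    mse: float
    n_knots: int
    relaxed: bool
    age_transform: AgeTransform
    degree: int
    r2_loo: float | None = None
    search_mse: dict[int, float] = field(default_factory=dict)
    _spline: BSpline | None = field(default=None, repr=False)

    def predict(self, ages_pcd: np.ndarray) -> np.ndarray:
        """Evaluate the fitted trend at new ages (PCD); extrapolates cubically."""
        if self._spline is None:
            raise ValueError("model has no stored spline")
        x = transform_age(np.asarray(ages_pcd, dtype=float), self.age_transform)
        return self._spline(x)


def _knot_vector(x: np.ndarray, k: int, degree: int) -> np.ndarray | None:
    """Boundary + quantile interior knot vector, or None when k is infeasible."""
    xmin, xmax = float(x.min()), float(x.max())
    unique_x = np.unique(x)
    if k == 0:
        interior = np.empty(0)
    else:
        qs = np.arange(1, k + 1) / (k + 1)
        interior = np.quantile(unique_x, qs)
        interior = interior[(interior > xmin) & (interior < xmax)]
        if len(interior) < k:
            return None  # too few distinct ages to place k distinct-quantile knots
    return np.concatenate(
        [[xmin] * (degree + 1), interior, [xmax] * (degree + 1)]
    )


def _ls_spline(x: np.ndarray, y: np.ndarray, t: np.ndarray, degree: int):
    design = BSpline.design_matrix(x, t, degree).toarray()
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    return BSpline(t, coef, degree, extrapolate=True), fitted


def fit_trend_spline(
    profile: ExpressionProfile,
    sigma2_hat: float | None = None,
    max_knots: int | None = None,
    age_transform: AgeTransform = "log2",
    window: int = WINDOW_DEFAULT,
    relax_factor: float = RELAX_FACTOR_DEFAULT,
    degree: int = 3,
    region: str = "",
) -> TrendModel:
    """Fit the trend spline with the minimal knot count meeting the noise bound."""
    y = profile.values
    n = profile.n
    if n < 8:
        raise ValueError(f"profile {profile.gene!r}: need >= 8 samples, got {n}")
    x = transform_age(profile.ages, age_transform)
    if np.ptp(x) == 0:
        raise ValueError(f"profile {profile.gene!r}: all ages identical")
    if sigma2_hat is None:
        sigma2_hat = estimate_noise_variance(y, window=window)
    if max_knots is None:
        max_knots = n // 4
    # exact interpolation is always accepted even when sigma2_hat == 0
    zero_tol = 1e-12 * max(float(np.var(y)), 1.0)

    fits: dict[int, tuple[BSpline, np.ndarray, float, np.ndarray]] = {}
    search_mse: dict[int, float] = {}
    chosen: int | None = None
    relaxed = False
    for k in range(max_knots + 1):
        t = _knot_vector(x, k, degree)
        if t is None:
            break
        spline, fitted = _ls_spline(x, y, t, degree)
        mse = float(np.mean((y - fitted) ** 2))
        fits[k] = (spline, fitted, mse, t)
        search_mse[k] = mse
        if mse < sigma2_hat or mse <= zero_tol:
            chosen = k
            break
    if chosen is None:
        for k in sorted(fits):
            if fits[k][2] < relax_factor * sigma2_hat:
                chosen = k
                relaxed = True
                break
    if chosen is None:
        chosen = max(fits)
        relaxed = True
        logger.warning(
            "profile %s: noise bound unsatisfiable even relaxed; "
            "returning %d-knot fit",
            profile.gene,
            chosen,
        )
    spline, fitted, mse, t = fits[chosen]
    interior = t[degree + 1 : -(degree + 1)]
    knot_ages = 2.0**interior if age_transform == "log2" else interior.copy()
    return TrendModel(
        gene=profile.gene,
        region=region or (profile.samples[0].region if profile.samples else ""),
        knot_ages=knot_ages,
        fitted=fitted,
        residuals=y - fitted,
        sigma2_hat=float(sigma2_hat),
        mse=mse,
        n_knots=chosen,
        relaxed=relaxed,
        age_transform=age_transform,
        degree=degree,
        search_mse=search_mse,
        _spline=spline,
    )


def detrend(profile: ExpressionProfile, **fit_kwargs) -> np.ndarray:
    """Residuals y_i - f(t_i) of the selected trend model, in sample order."""
    return fit_trend_spline(profile, **fit_kwargs).residuals


def loo_r2(
    profile: ExpressionProfile,
    refit_knots: bool = True,
    **fit_kwargs,
) -> float | None:
    """Leave-one-sample-out R^2 of the trend-model procedure.

    With ``refit_knots`` (default) each fold re-estimates the noise variance
    and re-selects the knot count on its n-1 points; the faster alternative
    freezes the knot count selected on the full data.
    """
    y = profile.values
    n = profile.n
    if n < 10:
        raise ValueError(f"need >= 10 samples for LOO R^2, got {n}")
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return None
    fixed_kwargs = dict(fit_kwargs)
    if not refit_knots:
        full = fit_trend_spline(profile, **fit_kwargs)
        fixed_kwargs["max_knots"] = full.n_knots
    preds = np.empty(n)
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        sub = ExpressionProfile(
            gene=profile.gene,
            values=y[keep],
            samples=[profile.samples[j] for j in keep],
        )
        model = fit_trend_spline(sub, **fixed_kwargs)
        preds[i] = model.predict(np.array([profile.ages[i]]))[0]
    ss_pred = float(np.sum((y - preds) ** 2))
    return 1.0 - ss_pred / ss_tot
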