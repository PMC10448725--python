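"""Slope fitting on correlation series and replicate aggregation."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import CorrelationSeries

#: relative quadratic-to-linear weight above which a fit is flagged
#: nonlinear; generous enough that correlated diffusive noise (which shows
#: a few percent apparent curvature) stays quiet while genuinely ballistic
#: input (curvature comparable to the slope) triggers
CURVATURE_WARN_THRESHOLD = 0.2

MIN_FIT_POINTS = 10


class NonlinearFitWarning(UserWarning):
    """The fitted window shows systematic curvature; the slope is suspect."""


class SingleReplicateWarning(UserWarning):
    """Only one replicate: the standard error is undefined."""


@dataclass(frozen=True)
class FitResult:
    slope: float            # units of series value per ps
    intercept: float
    slope_stderr: float
    r_squared: float
    n_points: int
    window: tuple
    curvature: float               # |c2| * span / max(|slope|, eps)
    curvature_significance: float  # |c2| / se(c2) from a quadratic fit

    @property
    def nonlinear(self) -> bool:
        """Systematic curvature: relatively large *and* statistically
        significant, so pure noise around a flat line does not trigger."""
        return (self.curvature > CURVATURE_WARN_THRESHOLD
                and self.curvature_significance > 4.0)


def fit_linear_slope(series: CorrelationSeries, t_min: float,
                     t_max: float) -> FitResult:
    """Unweighted ordinary least squares over lags in [t_min, t_max].

    The window bounds are inclusive and at least 10 lags must fall inside.
    A curvature diagnostic (quadratic coefficient relative to the linear one
    over the window span) flags systematically nonlinear input with a
    :class:`NonlinearFitWarning`; the slope is still returned.
    """
    mask = series.window_mask(t_min, t_max)
    t = series.lags[mask]
    y = series.values[mask]
    if t.size < MIN_FIT_POINTS:
        raise ValueError(
            f"fit window [{t_min}, {t_max}] ps contains {t.size} lags; "
            f"need at least {MIN_FIT_POINTS}")
    if np.ptp(t) == 0:
        raise ValueError("degenerate window: all lags equal")

    res = sps.linregress(t, y)
    span = float(np.ptp(t))
    if t.size > 3:
        coeffs, cov = np.polyfit(t, y, 2, cov=True)
        c2 = float(coeffs[0])
        se_c2 = float(np.sqrt(max(cov[0, 0], 0.0)))
    else:  # quadratic fit covariance needs n > 3
        c2 = float(np.polyfit(t, y, 2)[0])
        se_c2 = 0.0
    curvature = abs(c2) * span / max(abs(res.slope), 1e-300)
    if c2 == 0.0:
        significance = 0.0
    elif se_c2 == 0.0:
        significance = math.inf
    else:
        significance = abs(c2) / se_c2
    fit = FitResult(slope=float(res.slope), intercept=float(res.intercept),
                    slope_stderr=(float(res.stderr)
                                  if np.isfinite(res.stderr) else 0.0),
                    r_squared=float(res.rvalue) ** 2,
                    n_points=int(t.size), window=(float(t_min), float(t_max)),
                    curvature=float(curvature),
                    curvature_significance=float(significance))
    if fit.nonlinear:
        warnings.warn(
            f"systematic curvature in fit window [{t_min}, {t_max}] ps "
            f"(relative {curvature:.3g}, significance {significance:.3g}); "
            "the series is not linear here",
            NonlinearFitWarning, stacklevel=2)
    return fit


def combine_replicates(values) -> tuple:
    """Mean and standard error over independent replicate runs.

    The standard error is the sample (n-1) standard deviation divided by
    sqrt(n).  With a single replicate the scatter is undefined: the mean is
    returned with ``sem = nan`` and a :class:`SingleReplicateWarning`.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one replicate")
    mean = float(vals.mean())
    if vals.size == 1:
        warnings.warn("single replicate: standard error undefined",
                      SingleReplicateWarning, stacklevel=2)
        return mean, math.nan
    sem = float(vals.std(ddof=1) / math.sqrt(vals.size))
    return mean, sem
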