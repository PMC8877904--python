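"""Statistical layer: drift regressions, convergence fits, and calibration.

Three statistics carry the scientific questions:

* **Frequency drift.**  Ordinary least squares of peak frequency on
  insertion depth, with a two-sided t-test of the zero-slope null.
  p < 0.05 indicates the resonance shifts with depth — expected from the
  shortening free length of the implant beam.
* **Convergence / fixation.**  A nonlinear exponential fit
  ``y = y0 * exp(k * x)`` of peak energy on depth.  The untransformed-
  scale R^2 quantifies scatter: a well-fixated implant damps consistently
  and its peak energies hug the exponential trend (high R^2), whereas a
  loose, undersized one scatters (low R^2).  R^2 is used as a *relative*
  indicator between conditions; no absolute threshold is asserted.
* **Fit comparison.**  A variance-ratio F-test on the residuals of two
  fits, two-sided, with (n - 2) degrees of freedom on each side.

A logarithmic depth calibration ``ID = a * ln(PE / b)`` inverts the
exponential energy trend to predict insertion depth from peak energy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.stats

from .errors import DegenerateInputError, InsufficientDataError

__all__ = [
    "LinearFit",
    "ExpFit",
    "FTestResult",
    "CalibrationFit",
    "FixationContrast",
    "fit_linear",
    "fit_exponential",
    "fixation_contrast",
    "compare_fits_ftest",
    "ftest_from_residuals",
    "calibrate_depth",
]

log = logging.getLogger(__name__)


def _clean_pairs(x, y, positive_y: bool = False):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DegenerateInputError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    n_dropped_pos = 0
    if positive_y:
        pos = y > 0
        n_dropped_pos = int(np.sum(keep & ~pos))
        keep &= pos
    if n_dropped_pos:
        log.info("dropped %d non-positive y observations", n_dropped_pos)
    return x[keep], y[keep], n_dropped_pos


@dataclass(frozen=True)
class LinearFit:
    """OLS fit y = slope * x + intercept with the zero-slope test."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float  # two-sided, H0: slope = 0
    n: int
    residuals: np.ndarray = field(repr=False)

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass(frozen=True)
class ExpFit:
    """Nonlinear LS fit y = y0 * exp(k * x); R^2 on the original scale."""

    y0: float
    k: float
    r_squared: float
    n: int
    converged: bool
    residuals: np.ndarray = field(repr=False)
    r_squared_clipped: bool = False  # True when raw 1 - SSres/SStot < 0
    n_dropped: int = 0  # non-positive y observations excluded

    def predict(self, x):
        return self.y0 * np.exp(self.k * np.asarray(x, dtype=float))


@dataclass(frozen=True)
class FTestResult:
    """Two-sided variance-ratio comparison of two fits' residuals."""

    f_statistic: float
    p_value: float
    df: tuple[int, int]


@dataclass(frozen=True)
class FixationContrast:
    """Which of two convergence fits shows the higher goodness of fit."""

    better: str  # "a", "b" or "tie"
    r_squared_a: float
    r_squared_b: float

    @property
    def delta_r_squared(self) -> float:
        return self.r_squared_a - self.r_squared_b


@dataclass(frozen=True)
class CalibrationFit:
    """Logarithmic depth calibration ID = a * ln(PE / b)."""

    a: float  # mm per log-unit of peak energy
    b: float  # peak-energy scale at which predicted depth is zero
    r_squared: float
    n: int

    def predict_depth(self, pe):
        pe = np.asarray(pe, dtype=float)
        return self.a * np.log(pe / self.b)


def fit_linear(x, y) -> LinearFit:
    """Ordinary least squares with a two-sided t-test on the slope.

    Pairs with non-finite values are dropped.  Requires >= 3 pairs and
    non-degenerate x.  A constant y is handled explicitly: slope 0,
    R^2 = 0, p = 1 (the boundary case of a perfectly uninformative fit).
    """
    x, y, _ = _clean_pairs(x, y)
    if len(x) < 3:
        raise InsufficientDataError(f"linear fit needs >= 3 points, got {len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("x has zero variance")
    if np.ptp(y) == 0:
        resid = np.zeros_like(y)
        return LinearFit(0.0, float(y[0]), 0.0, 1.0, len(x), resid)
    res = scipy.stats.linregress(x, y)
    fitted = res.slope * x + res.intercept
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
        residuals=y - fitted,
    )


def _r_squared(y, fitted) -> tuple[float, bool]:
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return (1.0, False) if ss_res == 0 else (0.0, True)
    raw = 1.0 - ss_res / ss_tot
    if raw < 0:
        return 0.0, True
    return raw, False


def fit_exponential(x, y) -> ExpFit:
    """Nonlinear least squares of y = y0 * exp(k * x).

    Non-positive y values carry no information for this model and are
    dropped (with a logged count).  The optimizer is initialised from the
    log-linear regression of ln y on x, which is exact for noiseless
    exponential data; if it fails to converge the log-linear fallback is
    reported with ``converged=False``.  R^2 is 1 - SSres/SStot on the
    original (untransformed) scale, clipped at 0 with a flag.
    """
    x, y, n_dropped = _clean_pairs(x, y, positive_y=True)
    if len(x) < 3:
        raise InsufficientDataError(f"exponential fit needs >= 3 positive-y points, got {len(x)}")
    # log-linear initialisation
    if np.ptp(x) == 0:
        raise DegenerateInputError("x has zero variance")
    logy = np.log(y)
    k0, logy0 = np.polyfit(x, logy, 1)
    p0 = (math.exp(logy0), k0)
    converged = True
    try:
        import warnings

        with warnings.catch_warnings():
            # perfect fits make the covariance singular; irrelevant here
            warnings.simplefilter("ignore", scipy.optimize.OptimizeWarning)
            popt, _ = scipy.optimize.curve_fit(
                lambda xx, y0, k: y0 * np.exp(k * xx), x, y, p0=p0, maxfev=20000
            )
        y0_hat, k_hat = float(popt[0]), float(popt[1])
        if y0_hat <= 0 or not np.isfinite(y0_hat) or not np.isfinite(k_hat):
            raise RuntimeError("optimizer left the admissible region")
    except RuntimeError:
        converged = False
        y0_hat, k_hat = float(p0[0]), float(p0[1])
    fitted = y0_hat * np.exp(k_hat * x)
    r2, clipped = _r_squared(y, fitted)
    return ExpFit(
        y0=y0_hat,
        k=k_hat,
        r_squared=r2,
        n=len(x),
        converged=converged,
        residuals=y - fitted,
        r_squared_clipped=clipped,
        n_dropped=n_dropped,
    )


def fixation_contrast(fit_a: ExpFit, fit_b: ExpFit) -> FixationContrast:
    """Order two convergence fits by goodness of fit.

    The higher-R^2 condition is reported as better converged (proposed to
    indicate a higher degree of fixation); no absolute threshold is applied.
    """
    if fit_a.r_squared > fit_b.r_squared:
        better = "a"
    elif fit_b.r_squared > fit_a.r_squared:
        better = "b"
    else:
        better = "tie"
    return FixationContrast(better, fit_a.r_squared, fit_b.r_squared)


def ftest_from_residuals(resid_a, resid_b) -> FTestResult:
    """Two-sided variance-ratio F-test on two residual series.

    F is the larger residual variance over the smaller (each with n - 2
    model degrees of freedom subtracted); the two-sided p doubles the
    upper-tail probability.
    """
    resid_a = np.asarray(resid_a, dtype=float)
    resid_b = np.asarray(resid_b, dtype=float)
    if len(resid_a) < 3 or len(resid_b) < 3:
        raise InsufficientDataError("F-test needs >= 3 residuals on each side")
    df_a, df_b = len(resid_a) - 2, len(resid_b) - 2
    var_a = float(np.sum(resid_a**2)) / df_a
    var_b = float(np.sum(resid_b**2)) / df_b
    if var_a >= var_b:
        f_stat, dfn, dfd = (var_a / var_b if var_b > 0 else np.inf), df_a, df_b
    else:
        f_stat, dfn, dfd = var_b / var_a, df_b, df_a
    p = min(1.0, 2.0 * float(scipy.stats.f.sf(f_stat, dfn, dfd)))
    return FTestResult(f_statistic=float(f_stat), p_value=p, df=(dfn, dfd))


def compare_fits_ftest(fit_a, fit_b) -> FTestResult:
    """Variance-ratio F-test between the residuals of two fitted models."""
    return ftest_from_residuals(fit_a.residuals, fit_b.residuals)


def calibrate_depth(pe, insertion_depth) -> CalibrationFit:
    """Fit the logarithmic depth calibration ID = a * ln(PE / b).

    Equivalent to OLS of depth on ln(PE): slope a and intercept c give
    b = exp(-c / a).  Non-positive peak energies are dropped with a log
    message.  ``predict_depth`` inverts a peak-energy reading into an
    estimated insertion depth (mm).
    """
    pe, depth, _ = _clean_pairs(pe, insertion_depth, positive_y=False)
    pos = pe > 0
    if np.sum(~pos):
        log.info("dropped %d non-positive peak energies from calibration", int(np.sum(~pos)))
    pe, depth = pe[pos], depth[pos]
    if len(pe) < 3:
        raise InsufficientDataError("calibration needs >= 3 positive-PE pairs")
    lin = fit_linear(np.log(pe), depth)
    if lin.slope == 0:
        raise DegenerateInputError("depth does not vary with ln(PE); calibration undefined")
    a = lin.slope
    b = math.exp(-lin.intercept / a)
    return CalibrationFit(a=a, b=b, r_squared=lin.r_squared, n=lin.n)
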