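"""Regression, convergence, F-test, and calibration statistics."""

import numpy as np
import pytest
import scipy.stats

import broachtap as bt
from broachtap.errors import DegenerateInputError, InsufficientDataError
from broachtap.fit_stats import (
    calibrate_depth,
    compare_fits_ftest,
    fit_exponential,
    fit_linear,
    fixation_contrast,
    ftest_from_residuals,
)


def ols_normal_equations(x, y):
    """Independent closed-form OLS via the normal equations."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta[1], beta[0]  # slope, intercept


# ---------------------------------------------------------------- linear

def test_noiseless_linear_recovery():
    """Generating constants of a drift equation recovered exactly."""
    x = np.linspace(0, 25, 40)
    y = 0.1314 * x + 1420.0
    fit = fit_linear(x, y)
    assert fit.slope == pytest.approx(0.1314, rel=1e-10)
    assert fit.intercept == pytest.approx(1420.0, rel=1e-10)
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.p_value < 1e-10


def test_constant_y_boundary_behaviour():
    fit = fit_linear([1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0])
    assert fit.slope == 0.0
    assert fit.r_squared == 0.0
    assert fit.p_value == 1.0


def test_linear_fit_matches_normal_equations_on_random_instances(rng):
    """50 random instances agree with the closed-form solution to 1e-10."""
    for _ in range(50):
        n = rng.integers(5, 60)
        x = rng.normal(0, 3, n)
        y = rng.normal(0, 1, n) + rng.uniform(-2, 2) * x
        fit = fit_linear(x, y)
        slope, intercept = ols_normal_equations(x, y)
        assert fit.slope == pytest.approx(slope, rel=1e-10, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10, abs=1e-12)


def test_slope_confidence_coverage_under_gaussian_noise():
    """95% CI covers the generating slope in >= 93/100 seeds
    (sigma = 20 Hz, n = 70, slope 1.519 Hz/mm)."""
    x = np.linspace(0, 20, 70)
    covered = 0
    for seed in range(100):
        y = 1.519 * x + 3116 + np.random.default_rng(seed).normal(0, 20, 70)
        fit = fit_linear(x, y)
        se = np.sqrt(np.sum(fit.residuals**2) / (fit.n - 2) / np.sum((x - x.mean()) ** 2))
        half = scipy.stats.t.ppf(0.975, fit.n - 2) * se
        covered += (fit.slope - half) <= 1.519 <= (fit.slope + half)
    assert covered >= 93


def test_linear_fit_input_validation():
    with pytest.raises(InsufficientDataError):
        fit_linear([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(DegenerateInputError):
        fit_linear([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


# ----------------------------------------------------------- exponential

def test_noiseless_exponential_recovery():
    """Convergence-trend constants recovered to optimizer precision."""
    x = np.linspace(0, 25, 50)
    for y0, k in [(1044.0, -0.0826), (2041.0, -0.1519)]:
        fit = fit_exponential(x, y0 * np.exp(k * x))
        assert fit.converged
        assert fit.y0 == pytest.approx(y0, rel=1e-6)
        assert fit.k == pytest.approx(k, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0)


def test_exponential_on_noiseless_data_equals_log_domain_fit():
    x = np.linspace(0, 10, 20)
    y = 500.0 * np.exp(-0.07 * x)
    k_log, logy0 = np.polyfit(x, np.log(y), 1)
    fit = fit_exponential(x, y)
    assert fit.k == pytest.approx(k_log, rel=1e-9)
    assert fit.y0 == pytest.approx(np.exp(logy0), rel=1e-9)


def test_constant_y_gives_zero_rate():
    fit = fit_exponential([0.0, 1.0, 2.0, 3.0], [7.0, 7.0, 7.0, 7.0])
    assert fit.k == pytest.approx(0.0, abs=1e-12)
    assert fit.y0 == pytest.approx(7.0)


def test_nonpositive_y_dropped_with_count():
    x = np.arange(6.0)
    y = np.array([10.0, -1.0, 8.0, 0.0, 6.0, 5.0])
    fit = fit_exponential(x, y)
    assert fit.n == 4
    assert fit.n_dropped == 2


def test_all_nonpositive_y_raises():
    with pytest.raises(InsufficientDataError):
        fit_exponential([1.0, 2.0, 3.0], [-1.0, 0.0, -2.0])


def test_exponential_rate_recovery_under_lognormal_noise():
    """Median fitted k within 15% of truth (sigma_ln = 0.5, n = 70,
    k = -0.15) over 200 seeds."""
    x = np.linspace(0, 20, 70)
    ks = []
    for seed in range(200):
        rng = np.random.default_rng(seed)
        y = 1000 * np.exp(-0.15 * x) * np.exp(0.5 * rng.standard_normal(70))
        ks.append(fit_exponential(x, y).k)
    assert abs(np.median(ks) - (-0.15)) / 0.15 < 0.15


def test_r_squared_always_in_unit_interval(rng):
    x = np.linspace(0, 5, 30)
    for _ in range(20):
        y = np.abs(rng.normal(5, 4, 30)) + 0.01  # hostile, non-exponential data
        fit = fit_exponential(x, y)
        assert 0.0 <= fit.r_squared <= 1.0


# ------------------------------------------------------------ contrasts

def test_fixation_contrast_ordering():
    x = np.linspace(0, 20, 30)
    tight = fit_exponential(x, 2041 * np.exp(-0.1519 * x) * (1 + 0.01 * np.sin(x)))
    rng = np.random.default_rng(0)
    loose = fit_exponential(x, 491.6 * np.exp(-0.1399 * x) * np.exp(rng.normal(0, 1, 30)))
    result = fixation_contrast(tight, loose)
    assert result.better == "a"
    assert result.delta_r_squared > 0


def test_fixation_contrast_tie():
    x = np.linspace(0, 10, 20)
    fit = fit_exponential(x, 100 * np.exp(-0.1 * x))
    assert fixation_contrast(fit, fit).better == "tie"


# --------------------------------------------------------------- F-test

def test_identical_residuals_give_f_one_p_one():
    resid = np.array([1.0, -2.0, 0.5, 1.5, -1.0])
    result = ftest_from_residuals(resid, resid)
    assert result.f_statistic == pytest.approx(1.0)
    assert result.p_value == pytest.approx(1.0)


def test_four_to_one_variance_ratio_is_significant(rng):
    a = rng.normal(0, 2.0, 50)
    b = rng.normal(0, 1.0, 50)
    result = ftest_from_residuals(a, b)
    assert result.p_value < 0.01
    assert result.df == (48, 48)


def test_ftest_order_invariant(rng):
    a, b = rng.normal(0, 2, 30), rng.normal(0, 1, 40)
    r1 = ftest_from_residuals(a, b)
    r2 = ftest_from_residuals(b, a)
    assert r1.f_statistic == pytest.approx(r2.f_statistic)
    assert r1.p_value == pytest.approx(r2.p_value)


def test_ftest_pvalues_uniform_under_null():
    """Variance-ratio p-values on same-distribution Gaussian residual
    pairs pass a KS uniformity check (1000 draws, alpha = 0.01)."""
    pvals = []
    for seed in range(1000):
        rng = np.random.default_rng(seed)
        pvals.append(ftest_from_residuals(rng.normal(0, 1, 40), rng.normal(0, 1, 40)).p_value)
    ks = scipy.stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_compare_fits_uses_fit_residuals():
    x = np.linspace(0, 20, 40)
    rng = np.random.default_rng(3)
    fa = fit_exponential(x, 1000 * np.exp(-0.1 * x) + rng.normal(0, 40, 40))
    fb = fit_exponential(x, 1000 * np.exp(-0.1 * x) + rng.normal(0, 10, 40))
    result = compare_fits_ftest(fa, fb)
    assert result.f_statistic > 1
    assert result.p_value < 0.05


# ---------------------------------------------------------- calibration

def test_logarithmic_calibration_recovery():
    """ID = -7.7 ln(PE / 1532) recovered exactly from noiseless pairs."""
    pe = np.geomspace(100, 2000, 25)
    depth = -7.7 * np.log(pe / 1532.0)
    fit = calibrate_depth(pe, depth)
    assert fit.a == pytest.approx(-7.7, rel=1e-9)
    assert fit.b == pytest.approx(1532.0, rel=1e-9)
    assert fit.predict_depth(1532.0) == pytest.approx(0.0, abs=1e-9)


def test_calibration_round_trip_on_synthetic_energy_track(noiseless_fixated):
    """Depth predicted from a clean band-2 energy track matches the
    generating depths to well under 2 mm RMSE."""
    _, _, _, truth = noiseless_fixated
    advance = truth.depths - truth.config.initial_depth
    pe = truth.energies[:, 1]
    fit = calibrate_depth(pe, advance)
    rmse = np.sqrt(np.mean((fit.predict_depth(pe) - advance) ** 2))
    assert rmse < 2.0


def test_calibration_drops_nonpositive_pe():
    pe = np.array([-5.0, 100.0, 300.0, 900.0, 1500.0])
    depth = np.array([0.0, 21.0, 12.5, 4.1, 0.2])
    fit = calibrate_depth(pe, depth)
    assert fit.n == 4
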