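import math

import numpy as np
import pytest

from planktonmet.errors import SingularFitError
from planktonmet.pr_scaling import (ScalingFit, compare_fits,
                                    cross_region_bias, fit_pr,
                                    heterotrophy_threshold, predict_ncp,
                                    residual_sd_for_r_squared,
                                    round_threshold, simulate_slope_recovery,
                                    slope_vs_one_test)

NAST_FIT = ScalingFit(slope=0.76, intercept=28.25, se_slope=0.09,
                      se_intercept=5.0, r_squared=0.59, n=47,
                      residual_sd=12.0, region_label="NAST")
SATL_FIT = ScalingFit(slope=0.98, intercept=-8.56, se_slope=0.10,
                      se_intercept=6.0, r_squared=0.64, n=46,
                      residual_sd=12.0, region_label="SATL")


def test_exact_line_recovered():
    fit = fit_pr([0, 1, 2], [0, 1, 2])
    assert fit.slope == pytest.approx(1.0, abs=1e-12)
    assert fit.intercept == pytest.approx(0.0, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_fit_requires_three_points_and_p_variance():
    with pytest.raises(SingularFitError):
        fit_pr([0, 1], [0, 1])
    with pytest.raises(SingularFitError):
        fit_pr([2, 2, 2], [0, 1, 2])


def test_ols_matches_normal_equations_oracle():
    """fit_pr agrees with the brute-force normal-equations solution and
    the textbook standard-error formulas to 1e-10 relative."""
    rng = np.random.default_rng(2)
    p = rng.uniform(20, 120, 30)
    r = 0.8 * p + 20 + rng.normal(0, 10, 30)
    fit = fit_pr(p, r)
    X = np.column_stack([np.ones_like(p), p])
    beta = np.linalg.solve(X.T @ X, X.T @ r)
    resid = r - X @ beta
    s2 = resid @ resid / (len(p) - 2)
    cov = s2 * np.linalg.inv(X.T @ X)
    assert fit.intercept == pytest.approx(beta[0], rel=1e-10)
    assert fit.slope == pytest.approx(beta[1], rel=1e-10)
    assert fit.se_intercept == pytest.approx(math.sqrt(cov[0, 0]), rel=1e-10)
    assert fit.se_slope == pytest.approx(math.sqrt(cov[1, 1]), rel=1e-10)
    assert fit.residual_sd == pytest.approx(math.sqrt(s2), rel=1e-10)


def test_slope_vs_one():
    unity = ScalingFit(1.0, 0.0, 0.1, 1.0, 0.9, 20, 1.0)
    res = slope_vs_one_test(unity)
    assert res.t_statistic == 0.0 and res.p_value == 1.0

    res = slope_vs_one_test(NAST_FIT)
    assert res.t_statistic == pytest.approx((0.76 - 1) / 0.09, rel=1e-12)
    assert res.df == 45 and res.p_value < 0.05


def test_slope_vs_one_type_i_error_calibrated():
    """Data truly on the 1:1 line are rejected at about the nominal rate."""
    rng = np.random.default_rng(9)
    reject = 0
    reps = 2000
    for _ in range(reps):
        p = rng.uniform(20, 120, 30)
        r = p + rng.normal(0, 15, 30)
        if slope_vs_one_test(fit_pr(p, r)).p_value < 0.05:
            reject += 1
    assert reject / reps == pytest.approx(0.05, abs=0.015)


def test_compare_fits_identical_and_df():
    comp = compare_fits(NAST_FIT, NAST_FIT)
    assert comp["slope"].t_statistic == 0.0
    assert comp["intercept"].t_statistic == 0.0
    assert comp["slope"].df == 47 + 47 - 4

    tiny = ScalingFit(0.9, 1.0, 0.2, 2.0, 0.5, 3, 1.0)
    comp = compare_fits(tiny, SATL_FIT)
    assert comp["slope"].df == 3 + 46 - 4
    assert math.isfinite(comp["slope"].t_statistic)


def test_compare_fits_separates_regional_relationships():
    """Fits recovered from the two regional relations on synthetic data
    distinguish the regions: the slope test rejects far above the nominal
    5% rate and the intercept test rejects in most replicates.

    (At these n and R^2 the slope gap is ~1.5 standard errors, so slope
    power is moderate; the intercept gap of ~37 is ~3.7 s.e., so the
    intercept carries most of the discrimination.)"""
    rng = np.random.default_rng(4)
    slope_hits = intercept_hits = 0
    reps = 200
    for _ in range(reps):
        p1 = rng.uniform(19.8, 118.9, 47)
        r1 = 0.76 * p1 + 28.25 + rng.normal(
            0, residual_sd_for_r_squared(0.76, np.std(p1), 0.59), 47)
        p2 = rng.uniform(16.8, 103.4, 46)
        r2 = 0.98 * p2 - 8.56 + rng.normal(
            0, residual_sd_for_r_squared(0.98, np.std(p2), 0.64), 46)
        comp = compare_fits(fit_pr(p1, r1), fit_pr(p2, r2))
        slope_hits += comp["slope"].p_value < 0.05
        intercept_hits += comp["intercept"].p_value < 0.05
    assert slope_hits / reps > 0.2
    assert intercept_hits / reps >= 0.5


@pytest.mark.parametrize("slope,intercept,expected", [
    (0.76, 28.25, 117.708),
    (0.5, 10.0, 20.0),
])
def test_heterotrophy_threshold_values(slope, intercept, expected):
    fit = ScalingFit(slope, intercept, 0.1, 1.0, 0.6, 47, 1.0)
    thr = heterotrophy_threshold(fit)
    assert thr.interpretable
    assert thr.threshold_p == pytest.approx(expected, abs=0.01)


def test_heterotrophy_threshold_uninterpretable_branches():
    # negative crossing: never predicts heterotrophy at positive P
    thr = heterotrophy_threshold(SATL_FIT)
    assert thr.threshold_p is None and not thr.interpretable
    steep = ScalingFit(1.2, 5.0, 0.1, 1.0, 0.6, 10, 1.0)
    assert heterotrophy_threshold(steep).threshold_p is None


def test_round_threshold_conventions():
    assert round_threshold(117.708) == 117.7
    assert round_threshold(117.708, "nearest_ten") == 120.0


def test_predict_ncp_hand_values():
    unity = ScalingFit(1.0, 0.0, 0.1, 1.0, 0.9, 20, 1.0)
    assert predict_ncp(unity, 75.0) == 0.0
    assert predict_ncp(NAST_FIT, 60.0) == pytest.approx(-13.85)
    assert predict_ncp(SATL_FIT, 60.0) == pytest.approx(9.76)


def test_threshold_predicts_zero_ncp():
    for fit in (NAST_FIT, ScalingFit(0.5, 10.0, 0.1, 1.0, 0.6, 10, 1.0)):
        thr = heterotrophy_threshold(fit)
        assert predict_ncp(fit, thr.threshold_p) == pytest.approx(0.0,
                                                                  abs=1e-9)


def test_cross_region_bias():
    exact = [(p, predict_ncp(NAST_FIT, p)) for p in (30.0, 60.0, 90.0)]
    rep = cross_region_bias(NAST_FIT, exact)
    assert rep["mean_error"] == pytest.approx(0.0, abs=1e-12)
    assert rep["sign_misclassification"] == 0.0

    rep = cross_region_bias(NAST_FIT, [(68.3, 9.78)])
    assert rep["mean_error"] == pytest.approx(-21.6, abs=0.1)


def test_cross_gyre_prediction_misclassifies_metabolic_state():
    """The northern-gyre relation applied to southern-gyre-like data gets
    the sign of NCP wrong more often than not."""
    rng = np.random.default_rng(6)
    p = rng.uniform(16.8, 103.4, 500)
    sd = residual_sd_for_r_squared(0.98, np.std(p), 0.64)
    r = 0.98 * p - 8.56 + rng.normal(0, sd, 500)
    rep = cross_region_bias(NAST_FIT, list(zip(p, p - r)))
    assert rep["sign_misclassification"] > 0.5


def test_parameter_recovery_unbiased():
    """Slope and intercept estimated from data simulated at a known
    relationship show no bias beyond 2 Monte-Carlo standard errors."""
    rng = np.random.default_rng(13)
    slopes, intercepts = [], []
    for _ in range(500):
        p = rng.uniform(19.8, 118.9, 47)
        r = 0.76 * p + 28.25 + rng.normal(
            0, residual_sd_for_r_squared(0.76, np.std(p), 0.59), 47)
        pc = p - p.mean()
        b1 = pc @ (r - r.mean()) / (pc @ pc)
        slopes.append(b1)
        intercepts.append(r.mean() - b1 * p.mean())
    for est, truth in ((slopes, 0.76), (intercepts, 28.25)):
        est = np.asarray(est)
        mc_se = est.std(ddof=1) / math.sqrt(len(est))
        assert abs(est.mean() - truth) < 2 * mc_se + 1e-12


def test_simulate_slope_recovery_runs_seeded():
    a = simulate_slope_recovery(0.98, -8.56, 0.64, (16.8, 103.4), 46, 50,
                                np.random.default_rng(3))
    b = simulate_slope_recovery(0.98, -8.56, 0.64, (16.8, 103.4), 46, 50,
                                np.random.default_rng(3))
    assert a == b
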