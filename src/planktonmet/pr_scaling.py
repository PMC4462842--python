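"""P:R scaling relationships and what they predict about metabolic balance.

Depth-integrated respiration is regressed on depth-integrated gross
photosynthesis (ordinary least squares of R on P, the convention in which
such relationships are reported).  A fitted line R = b1 P + b0 with slope
below 1 crosses the 1:1 line at P* = b0 / (1 - b1): for P below P* the line
predicts net heterotrophy (R > P), so P* is the net-heterotrophy threshold.
A slope >= 1 (or a non-positive crossing) never predicts heterotrophy from
P alone.  Predicted NCP at a given P is P - (b1 P + b0) = (1 - b1) P - b0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateTestError, SingularFitError
from .region_stats import TwoSampleTest


@dataclass
class ScalingFit:
    """An OLS fit of R on P for one region (and optionally season)."""

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    r_squared: float
    n: int
    residual_sd: float
    region_label: str = ""

    def equation(self) -> str:
        sign = "+" if self.intercept >= 0 else "-"
        return (f"R = {self.slope:.2f} P {sign} {abs(self.intercept):.2f} "
                f"(R^2 = {self.r_squared:.2f}, n = {self.n})")


@dataclass
class ThresholdResult:
    """Net-heterotrophy threshold P* = intercept / (1 - slope), when the
    fitted line crosses the 1:1 line at positive P."""

    threshold_p: float | None
    interpretable: bool


def fit_pr(p_values, r_values, region_label: str = "") -> ScalingFit:
    """Ordinary least squares of R on P with parameter standard errors."""
    p = np.asarray(p_values, dtype=float)
    r = np.asarray(r_values, dtype=float)
    if len(p) != len(r):
        raise ValueError("p_values and r_values lengths differ")
    if len(p) < 3:
        raise SingularFitError(
            f"need >= 3 points to estimate residual variance, got {len(p)}")
    if np.ptp(p) == 0:
        raise SingularFitError("zero variance in P")
    res = sm.OLS(r, sm.add_constant(p)).fit()
    resid_sd = math.sqrt(res.ssr / res.df_resid) if res.df_resid > 0 else 0.0
    r2 = float(np.corrcoef(p, r)[0, 1] ** 2)
    return ScalingFit(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        se_slope=float(res.bse[1]), se_intercept=float(res.bse[0]),
        r_squared=r2, n=len(p), residual_sd=resid_sd,
        region_label=region_label)


def slope_vs_one_test(fit: ScalingFit) -> TwoSampleTest:
    """t test of the fitted slope against the 1:1 line, df = n - 2."""
    if fit.se_slope == 0:
        raise DegenerateTestError("slope standard error is zero")
    t = (fit.slope - 1.0) / fit.se_slope
    df = fit.n - 2
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TwoSampleTest(float(t), df, p, method="slope_vs_one")


def compare_fits(fit_a: ScalingFit, fit_b: ScalingFit
                 ) -> dict[str, TwoSampleTest]:
    """Normal-theory tests of slope and intercept differences between two
    independent fits, df = n_a + n_b - 4."""
    df = fit_a.n + fit_b.n - 4
    out = {}
    for name, (xa, sa), (xb, sb) in [
            ("slope", (fit_a.slope, fit_a.se_slope),
             (fit_b.slope, fit_b.se_slope)),
            ("intercept", (fit_a.intercept, fit_a.se_intercept),
             (fit_b.intercept, fit_b.se_intercept))]:
        se = math.hypot(sa, sb)
        if se == 0:
            raise DegenerateTestError(f"degenerate {name} standard errors")
        t = (xa - xb) / se
        out[name] = TwoSampleTest(float(t), df,
                                  2.0 * float(stats.t.sf(abs(t), df)),
                                  method="independent_fits")
    return out


def heterotrophy_threshold(fit: ScalingFit) -> ThresholdResult:
    """P at which the fitted line crosses the 1:1 line (None when the fit
    never predicts net heterotrophy at positive P)."""
    if fit.slope >= 1.0:
        return ThresholdResult(None, False)
    p_star = fit.intercept / (1.0 - fit.slope)
    if p_star <= 0:
        return ThresholdResult(None, False)
    return ThresholdResult(float(p_star), True)


def round_threshold(threshold_p: float, convention: str = "decimal") -> float:
    """Format a threshold: one decimal (default) or "~" nearest-ten."""
    if convention == "nearest_ten":
        return float(10 * round(threshold_p / 10.0))
    return float(round(threshold_p, 1))


def predict_ncp(fit: ScalingFit, p: float) -> float:
    """NCP predicted from P alone under the fitted relationship."""
    if p < 0:
        raise ValueError("p must be >= 0")
    return (1.0 - fit.slope) * p - fit.intercept


def cross_region_bias(fit: ScalingFit, observed) -> dict:
    """Bias of predicting one region's NCP with another region's fit.

    ``observed`` is a sequence of (P, NCP) pairs.  Returns mean error
    (predicted - observed), RMSE, the fraction of strict sign
    misclassifications, and the fraction of exact-zero observations
    (counted by neither side).
    """
    obs = np.asarray(list(observed), dtype=float)
    if obs.size == 0:
        raise ValueError("observed is empty")
    p, ncp = obs[:, 0], obs[:, 1]
    pred = (1.0 - fit.slope) * p - fit.intercept
    err = pred - ncp
    nonzero = (ncp != 0) & (pred != 0)
    mis = np.sign(pred) != np.sign(ncp)
    return {
        "mean_error": float(np.mean(err)),
        "rmse": float(np.sqrt(np.mean(err ** 2))),
        "sign_misclassification": float(np.mean(mis[nonzero]))
        if nonzero.any() else 0.0,
        "zero_fraction": float(np.mean(~nonzero)),
        "n": int(len(p)),
    }


def residual_sd_for_r_squared(slope: float, p_sd: float,
                              r_squared: float) -> float:
    """Residual s.d. giving an expected coefficient of determination
    ``r_squared`` when R = slope*P + intercept + e and sd(P) = ``p_sd``.

    From R^2 = var(slope*P) / (var(slope*P) + var(e)).
    """
    if not 0 < r_squared < 1:
        raise ValueError("r_squared must be in (0, 1)")
    return abs(slope) * p_sd * math.sqrt((1.0 - r_squared) / r_squared)


def simulate_slope_recovery(slope: float, intercept: float, r_squared: float,
                            p_range: tuple[float, float], n: int,
                            n_reps: int,
                            rng: np.random.Generator) -> float:
    """Mean OLS slope over ``n_reps`` synthetic datasets drawn from a known
    linear P:R relationship.

    P is uniform over ``p_range``; R adds Gaussian noise scaled so the
    expected R^2 matches ``r_squared``.  Used to check that the fitting is
    unbiased at published sample sizes.
    """
    lo, hi = p_range
    sd_res = residual_sd_for_r_squared(slope, (hi - lo) / math.sqrt(12.0),
                                       r_squared)
    slopes = np.empty(n_reps)
    for i in range(n_reps):
        p = rng.uniform(lo, hi, n)
        r = slope * p + intercept + rng.normal(0.0, sd_res, n)
        # closed-form OLS slope; avoids model-object overhead in the loop
        pc = p - p.mean()
        slopes[i] = float(pc @ (r - r.mean()) / (pc @ pc))
    return float(slopes.mean())
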