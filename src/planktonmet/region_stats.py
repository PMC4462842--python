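"""Regional summary statistics, two-sample comparisons, a Monte-Carlo
Lilliefors normality test, and the oxygen-to-carbon annual flux conversion.

Conventions follow the normal-theory style usual in at-sea metabolism work:
confidence intervals for means use the z multiplier (1.96 at 95%) by
default, two-sample comparisons use the Student pooled-variance t with
df = n1 + n2 - 2, and the fraction of net-heterotrophic observations counts
strictly negative values only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTestError, InsufficientDataError


@dataclass
class MetabolicSummary:
    """Table-style summary of a set of rates: mean, s.e.m., 95% CI, median,
    range, n and % of negative (net-heterotrophic) values."""

    mean: float
    sem: float
    ci_low: float
    ci_high: float
    median: float
    min: float
    max: float
    n: int
    pct_negative: float


@dataclass
class TwoSampleTest:
    t_statistic: float
    df: int
    p_value: float
    method: str = "student_pooled"


@dataclass
class CarbonFluxEstimate:
    """Annual carbon flux implied by a mean volumetric NCP sustained over a
    surface layer for a year, under a fixed respiratory quotient."""

    ncp_volumetric: float      # mmol O2 m-3 d-1
    layer_depth: float         # m
    respiratory_quotient: float
    annual_flux: float         # mol C m-2 yr-1


def summarize(values, ci_multiplier: float | None = None,
              alpha: float = 0.05) -> MetabolicSummary:
    """Summarise a list of rates.

    ``ci_multiplier`` defaults to the normal z quantile for ``alpha``
    (1.96 at 5%); pass e.g. ``stats.t.ppf(0.975, n-1)`` for a t interval.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise InsufficientDataError(f"need >= 2 values, got {n}")
    if ci_multiplier is None:
        ci_multiplier = float(stats.norm.ppf(1.0 - alpha / 2.0))
    mean = float(np.mean(x))
    sem = float(np.std(x, ddof=1) / math.sqrt(n))
    half = ci_multiplier * sem
    return MetabolicSummary(
        mean=mean, sem=sem, ci_low=mean - half, ci_high=mean + half,
        median=float(np.median(x)), min=float(np.min(x)),
        max=float(np.max(x)), n=n,
        pct_negative=float(100.0 * np.mean(x < 0)))


def two_sample_t(a, b) -> TwoSampleTest:
    """Student pooled-variance two-sample t test, df = n1 + n2 - 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("both samples need >= 2 values")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * np.var(a, ddof=1) + (n2 - 1) * np.var(b, ddof=1)) / df
    diff = float(np.mean(a) - np.mean(b))
    if sp2 == 0.0:
        if diff == 0.0:
            return TwoSampleTest(0.0, df, 1.0)
        return TwoSampleTest(math.copysign(math.inf, diff), df, 0.0)
    t = diff / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TwoSampleTest(float(t), df, p)


def two_sample_t_from_moments(mean1: float, sem1: float, n1: int,
                              mean2: float, sem2: float, n2: int
                              ) -> TwoSampleTest:
    """Pooled t reconstructed from printed summary statistics
    (mean, s.e.m., n per group)."""
    df = n1 + n2 - 2
    s1sq = (sem1 * math.sqrt(n1)) ** 2
    s2sq = (sem2 * math.sqrt(n2)) ** 2
    sp2 = ((n1 - 1) * s1sq + (n2 - 1) * s2sq) / df
    if sp2 == 0.0:
        raise DegenerateTestError("zero pooled variance")
    t = (mean1 - mean2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TwoSampleTest(float(t), df, p)


def lilliefors_statistic(values) -> float:
    """Kolmogorov-Smirnov D against a normal with estimated mean/sd."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    sd = np.std(x, ddof=1)
    if sd == 0.0:
        raise InsufficientDataError("constant sample: no variation")
    z = stats.norm.cdf((x - np.mean(x)) / sd)
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(i / n - z, z - (i - 1) / n)))


def lilliefors_null_distribution(n: int, mc_reps: int,
                                 rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo null distribution of the Lilliefors D for sample size n.

    Vectorised over replicates; each standard-normal sample is standardised
    by its own estimated mean and sd, exactly as the observed statistic.
    """
    samples = np.sort(rng.standard_normal((mc_reps, n)), axis=1)
    mu = samples.mean(axis=1, keepdims=True)
    sd = samples.std(axis=1, ddof=1, keepdims=True)
    z = stats.norm.cdf((samples - mu) / sd)
    i = np.arange(1, n + 1)
    return np.max(np.maximum(i / n - z, z - (i - 1) / n), axis=1)


def lilliefors_test(values, mc_reps: int = 10_000,
                    seed: int | np.random.Generator = 0
                    ) -> tuple[float, float]:
    """Lilliefors normality test with a seeded Monte-Carlo p-value.

    Returns ``(D, p)`` where p is the fraction of ``mc_reps`` null samples
    of the same size whose D reaches the observed one.  Bit-reproducible
    for a fixed seed.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise InsufficientDataError(f"need >= 4 values, got {len(x)}")
    d_obs = lilliefors_statistic(x)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    d_null = lilliefors_null_distribution(len(x), mc_reps, rng)
    return d_obs, float(np.mean(d_null >= d_obs))


def annualize_carbon(ncp_volumetric: float, layer_depth: float,
                     respiratory_quotient: float = 0.8
                     ) -> CarbonFluxEstimate:
    """Annual carbon flux from a mean volumetric NCP over a surface layer.

    flux [mol C m-2 yr-1] = NCP [mmol O2 m-3 d-1] x depth [m] x 365 x RQ
    / 1000, with RQ the respiratory quotient (mol CO2 per mol O2).
    """
    if layer_depth <= 0:
        raise ValueError("layer_depth must be positive")
    if not 0.5 < respiratory_quotient < 1.5:
        raise ValueError("respiratory_quotient outside (0.5, 1.5)")
    flux = ncp_volumetric * layer_depth * 365.0 * respiratory_quotient / 1000.0
    return CarbonFluxEstimate(ncp_volumetric, layer_depth,
                              respiratory_quotient, flux)


def regional_summary_table(df: pd.DataFrame,
                           value_cols: tuple[str, ...] = ("ncp", "p", "r"),
                           group_col: str = "province",
                           season_col: str | None = None) -> pd.DataFrame:
    """Summary table shaped like a regional rate table: one column per
    variable x province (x season), rows Mean, s.e.m., CI, Median, Range,
    n, % negative.

    ``df`` must carry the value columns plus the grouping column(s).
    """
    keys = [group_col] + ([season_col] if season_col else [])
    rows = {}
    for group, grp in df.groupby(keys, sort=True):
        if not isinstance(group, tuple):
            group = (group,)
        for col in value_cols:
            vals = grp[col].dropna()
            if len(vals) < 2:
                continue
            s = summarize(vals)
            name = " ".join([col.upper(), *map(str, group)])
            rows[name] = {
                "Mean": s.mean, "s.e.m.": s.sem,
                "95% CI low": s.ci_low, "95% CI high": s.ci_high,
                "Median": s.median, "Min": s.min, "Max": s.max,
                "n": s.n, "% negative": s.pct_negative,
            }
    return pd.DataFrame(rows)
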