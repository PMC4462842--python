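"""Volumetric metabolic rates from replicate bottle oxygen concentrations.

Rates follow the standard light/dark incubation arithmetic:

* NCP = mean([O2] light, 24 h) - mean([O2] zero-time)
* R   = mean([O2] zero-time)  - mean([O2] dark, 24 h)
* P   = NCP + R  (identically, so the identity holds to machine precision)

Standard errors treat the three treatment means as independent:
se_NCP = sqrt(sem_light^2 + sem_zero^2), se_R = sqrt(sem_zero^2 + sem_dark^2),
and se_P = sqrt(sem_light^2 + sem_dark^2) because P = light - dark and the
shared zero-time term cancels.  Rates are normalised to per-day using the
incubation duration (24 h gives a factor of 1).

Quality control mirrors common at-sea practice: a sample is flagged when P
or R is significantly negative (one-sided z criterion) or when any
treatment's replicate coefficient of variation is anomalously high; a whole
station is excluded when any of its depths is flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .data_io import OxygenReplicateSet
from .errors import InsufficientReplicationError

logger = logging.getLogger(__name__)

#: Replicate CV above this fraction counts as anomalously high variance
#: (10x the ~0.1% analytical CV the Winkler method achieves).
DEFAULT_CV_THRESHOLD = 0.01


@dataclass
class VolumetricRates:
    """NCP, R, P and their standard errors at one depth
    (mmol O2 m-3 d-1)."""

    station_id: str
    depth: float
    light_fraction: float
    ncp: float
    r: float
    p: float
    se_ncp: float
    se_r: float
    se_p: float
    n_zero: int
    n_light: int
    n_dark: int
    qc_flag: str = "keep"
    qc_reason: str = ""


def _check_replication(reps: OxygenReplicateSet) -> None:
    for name in ("zero_reps", "light_reps", "dark_reps"):
        if len(getattr(reps, name)) < 2:
            raise InsufficientReplicationError(
                f"station {reps.station_id} depth {reps.depth}: "
                f"{name} has fewer than 2 replicates")


def compute_rates(reps: OxygenReplicateSet) -> VolumetricRates:
    """Convert one replicate set to volumetric rates with uncertainties."""
    _check_replication(reps)
    per_day = 24.0 / reps.incubation_duration
    zm = float(np.mean(reps.zero_reps))
    lm = float(np.mean(reps.light_reps))
    dm = float(np.mean(reps.dark_reps))
    ncp = (lm - zm) * per_day
    r = (zm - dm) * per_day
    p = ncp + r  # exact identity by construction
    se_ncp, se_r, se_p = rate_uncertainty(reps)
    return VolumetricRates(
        station_id=reps.station_id, depth=reps.depth,
        light_fraction=reps.light_fraction,
        ncp=ncp, r=r, p=p, se_ncp=se_ncp, se_r=se_r, se_p=se_p,
        n_zero=len(reps.zero_reps), n_light=len(reps.light_reps),
        n_dark=len(reps.dark_reps))


def rate_uncertainty(reps: OxygenReplicateSet) -> tuple[float, float, float]:
    """Standard errors of NCP, R and P as differences of treatment means."""
    _check_replication(reps)
    per_day = 24.0 / reps.incubation_duration

    def sem(x):
        x = np.asarray(x, dtype=float)
        return float(np.std(x, ddof=1) / np.sqrt(len(x)))

    sz, sl, sd = (sem(reps.zero_reps), sem(reps.light_reps),
                  sem(reps.dark_reps))
    return (float(np.hypot(sl, sz)) * per_day,
            float(np.hypot(sz, sd)) * per_day,
            float(np.hypot(sl, sd)) * per_day)


def qc_evaluate(rates: VolumetricRates, reps: OxygenReplicateSet | None = None,
                alpha: float = 0.05,
                cv_threshold: float = DEFAULT_CV_THRESHOLD
                ) -> VolumetricRates:
    """Flag a sample for exclusion; never raises.

    Exclusion fires when P or R is significantly negative at level ``alpha``
    (rate + z(1-alpha/2) * se < 0) or, if the replicate set is supplied, when
    any treatment's replicate CV exceeds ``cv_threshold``.
    """
    z = float(stats.norm.ppf(1.0 - alpha / 2.0))
    reasons = []
    if rates.p + z * rates.se_p < 0:
        reasons.append("significant negative P")
    if rates.r + z * rates.se_r < 0:
        reasons.append("significant negative R")
    if reps is not None:
        for name in ("zero_reps", "light_reps", "dark_reps"):
            x = np.asarray(getattr(reps, name), dtype=float)
            cv = np.std(x, ddof=1) / np.mean(x)
            if cv > cv_threshold:
                reasons.append(
                    f"anomalous replicate variance ({name.split('_')[0]} "
                    f"CV {cv:.2%})")
    if reasons:
        return replace(rates, qc_flag="exclude", qc_reason="; ".join(reasons))
    return replace(rates, qc_flag="keep", qc_reason="")


def station_exclusion(depth_rates: list[VolumetricRates]
                      ) -> tuple[bool, list[dict]]:
    """Station-level QC: exclude the whole station if any depth is flagged.

    Returns ``(keep, report_rows)`` where each report row records the
    station and the reason that fired.
    """
    if not depth_rates:
        raise ValueError("station has no evaluated depths")
    report = [{"station_id": v.station_id, "depth_m": v.depth,
               "reason": v.qc_reason}
              for v in depth_rates if v.qc_flag == "exclude"]
    keep = not report
    if not keep:
        logger.warning("station %s excluded by QC: %s",
                       depth_rates[0].station_id, report[0]["reason"])
    return keep, report
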