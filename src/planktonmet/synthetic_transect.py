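"""Synthetic meridional-transect generator with known ground truth.

Emulates an AMT-style oxygen-metabolism survey: stations in the two
subtropical gyre bands (NAST, ~20-38 N; SATL, ~10-32 S) plus equatorial
stations outside the gyres, each with a CTD profile (tanh thermocline,
Gaussian deep chlorophyll maximum at the euphotic depth) and light/dark
bottle incubations at five light depths (97/33/14/7/1% of surface PAR) with
replicate Winkler-precision oxygen concentrations.

The generative model works at the integrated scale first, which is where
regional P:R structure is defined:

1. integrated gross photosynthesis P is drawn from a truncated normal per
   zone (gyre means 57.5 / 68.3 mmol O2 m-2 d-1, ranges 19.8-118.9 and
   16.8-103.4);
2. integrated respiration follows the zone's linear P:R relationship
   (NAST R = 0.76 P + 28.25; SATL R = 0.98 P - 8.56) plus a Gaussian
   residual scaled so the expected R^2 matches the zonal value (0.59 /
   0.64), redrawn until R falls in the zone's plausible range;
3. volumetric p(z) and r(z) distribute the integrals over the light depths
   using fixed vertical shape functions (piecewise linear in normalised
   depth, mild subsurface maxima) renormalised so that trapezoidal
   integration of the sampled values — surface extension included —
   reproduces the integrated truth exactly;
4. each bottle concentration is Normal around baseline +/- rate x 1 d, with
   analytical noise (CV 0.1% of ~210 mmol O2 m-3) in all treatments and an
   extra biological/experimental component in the incubated ones, tuned so
   the mean rate standard error is 0.18 mmol O2 m-3 d-1 at 5 replicates.

The vertical shape knots are solved so that the equal-weight mean of the
five standard sampling depths equals the depth-averaged rate; sampled
volumetric statistics are then directly comparable to integrated ones
divided by the euphotic depth.  All randomness flows from a single seed;
the same seed yields a byte-identical dataset.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .profile_integration import trapezoid_weights

#: Normalised depths z/Zeu of the default light fractions (ln f / ln 0.01).
_DEFAULT_FRACTIONS = (0.97, 0.33, 0.14, 0.07, 0.01)
#: Vertical shape knots (relative rate vs normalised depth) for P and R.
#: Surface values are solved so the five-depth sample mean equals the
#: depth-averaged value on the default grid (subsurface maximum at the
#: ~33% light depth, decline toward the 1% depth).
P_SHAPE_KNOTS = (0.70531, 1.1, 1.0, 0.8, 0.45)
R_SHAPE_KNOTS = (0.92042, 1.05, 1.0, 0.95, 0.8)


@dataclass(frozen=True)
class ZoneRateModel:
    """Integrated-scale rate statistics for one zone."""

    p_mean: float                 # mmol O2 m-2 d-1
    p_sd: float
    p_range: tuple[float, float]
    slope: float                  # R = slope * P + intercept
    intercept: float
    r_squared: float
    r_range: tuple[float, float]


@dataclass(frozen=True)
class ZoneHydrography:
    latitude_band: tuple[float, float]   # degrees N
    longitude_band: tuple[float, float]  # degrees E
    euphotic_mean: float                 # m
    euphotic_sd: float
    euphotic_range: tuple[float, float]
    thermocline_mean: float
    thermocline_sd: float
    thermocline_range: tuple[float, float]


@dataclass(frozen=True)
class TransectConfig:
    """Full configuration of the synthetic transect; ``seed`` is mandatory."""

    seed: int
    n_stations: dict[str, int] = field(default_factory=lambda: {
        "NAST": 47, "SATL": 46, "OTHER": 20})
    light_fractions: tuple[float, ...] = _DEFAULT_FRACTIONS
    n_replicates: int = 5
    baseline_o2: float = 210.0       # mmol O2 m-3
    analytical_cv: float = 0.001     # fraction of baseline
    biological_sd: float = 0.2943    # mmol O2 m-3 d-1 (see tuning script)
    incubation_hours: float = 24.0
    cruise_id: str = "SYNTH-01"
    start_date: _dt.date = _dt.date(2011, 9, 25)
    station_days: float = 0.5        # days between stations
    ctd_max_depth: float = 300.0
    ctd_step: float = 5.0
    rate_models: dict[str, ZoneRateModel] = field(default_factory=lambda: {
        "NAST": ZoneRateModel(57.5, 3.50 * np.sqrt(47), (19.8, 118.9),
                              0.76, 28.25, 0.59, (27.8, 121.2)),
        "SATL": ZoneRateModel(68.3, 3.13 * np.sqrt(46), (16.8, 103.4),
                              0.98, -8.56, 0.64, (6.7, 107.2)),
        "OTHER": ZoneRateModel(120.0, 30.0, (60.0, 220.0),
                               0.85, 5.0, 0.70, (10.0, 240.0)),
    })
    hydrography: dict[str, ZoneHydrography] = field(default_factory=lambda: {
        "NAST": ZoneHydrography((20.0, 38.0), (-45.0, -20.0),
                                112.0, 10.0, (108.0, 145.0),
                                125.0, 10.0, (108.0, 160.0)),
        "SATL": ZoneHydrography((-32.0, -10.0), (-35.0, -15.0),
                                112.0, 10.0, (108.0, 145.0),
                                125.0, 10.0, (108.0, 160.0)),
        "OTHER": ZoneHydrography((-5.0, 15.0), (-30.0, -15.0),
                                 60.0, 10.0, (35.0, 85.0),
                                 50.0, 12.0, (25.0, 80.0)),
    })

    def validate(self) -> None:
        f = np.asarray(self.light_fractions)
        if np.any(np.diff(f) >= 0):
            raise ConfigError("light_fractions must be strictly decreasing")
        if abs(f[-1] - 0.01) > 1e-12:
            raise ConfigError("light_fractions must end at 0.01 (1% PAR)")
        if self.analytical_cv < 0 or self.biological_sd < 0:
            raise ConfigError("noise parameters must be >= 0")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")
        for zone in self.n_stations:
            if zone not in self.rate_models or zone not in self.hydrography:
                raise ConfigError(f"zone {zone!r} lacks a model")


@dataclass
class TransectDataset:
    """Generated tables in the exchange schemas of :mod:`planktonmet.data_io`."""

    bottles: pd.DataFrame
    ctd: pd.DataFrame
    stations: pd.DataFrame


@dataclass
class GroundTruth:
    """True (noise-free) rates and hydrography per station and depth."""

    stations: pd.DataFrame  # zone, euphotic/thermocline/DCM depths, integrals
    levels: pd.DataFrame    # true volumetric p, r, ncp at each light depth


def default_amt_preset(seed: int = 0) -> TransectConfig:
    """The calibrated default configuration (subtropical-gyre survey).

    Station counts (47/46), light fractions, replicate count, euphotic mean
    112 m, oxygen baseline 210 mmol O2 m-3, analytical CV 0.1% and the
    zonal integrated-rate statistics are the survey conditions the
    generator emulates; ``biological_sd`` is the tuned noise component
    (scripts/tune_biological_sd.py).
    """
    return TransectConfig(seed=seed)


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _shape_values(z_norm: np.ndarray, knots: tuple[float, ...]) -> np.ndarray:
    z_knots = np.log(_DEFAULT_FRACTIONS) / np.log(0.01)
    return np.interp(z_norm, z_knots, knots)


def _distribute(integral: float, depths: np.ndarray, euphotic: float,
                knots: tuple[float, ...]) -> np.ndarray:
    """Volumetric values at ``depths`` whose trapezoidal integral (surface
    extension on) equals ``integral`` exactly."""
    s = _shape_values(depths / euphotic, knots)
    w, _ = trapezoid_weights(depths, euphotic)
    return integral * s / float(w @ s)


def generate_transect(config: TransectConfig
                      ) -> tuple[TransectDataset, GroundTruth]:
    """Generate a full synthetic transect and its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    f = np.asarray(config.light_fractions)
    z_norm = np.log(f) / np.log(0.01)
    per_day = config.incubation_hours / 24.0  # concentration change per rate

    bottle_rows, ctd_rows, station_rows = [], [], []
    truth_station_rows, truth_level_rows = [], []
    ctd_grid = np.arange(0.0, config.ctd_max_depth + config.ctd_step / 2,
                         config.ctd_step)

    station_index = 0
    for zone in ("NAST", "SATL", "OTHER"):
        n = config.n_stations.get(zone, 0)
        if n == 0:
            continue
        model = config.rate_models[zone]
        hydro = config.hydrography[zone]
        p_int = _truncnorm(rng, model.p_mean, model.p_sd, *model.p_range,
                           size=n)
        sd_res = (abs(model.slope) * np.std(p_int)
                  * np.sqrt((1 - model.r_squared) / model.r_squared))
        r_int = model.slope * p_int + model.intercept \
            + rng.normal(0.0, sd_res, n)
        bad = (r_int < model.r_range[0]) | (r_int > model.r_range[1])
        while bad.any():  # keep respiration inside the zone's plausible range
            r_int[bad] = (model.slope * p_int[bad] + model.intercept
                          + rng.normal(0.0, sd_res, int(bad.sum())))
            bad = (r_int < model.r_range[0]) | (r_int > model.r_range[1])
        euphotic = _truncnorm(rng, hydro.euphotic_mean, hydro.euphotic_sd,
                              *hydro.euphotic_range, size=n)
        thermo = _truncnorm(rng, hydro.thermocline_mean, hydro.thermocline_sd,
                            *hydro.thermocline_range, size=n)
        lat = rng.uniform(*hydro.latitude_band, n)
        lon = rng.uniform(*hydro.longitude_band, n)

        for i in range(n):
            station_index += 1
            sid = f"ST{station_index:03d}"
            date = config.start_date + _dt.timedelta(
                days=station_index * config.station_days)
            station_rows.append({
                "station_id": sid, "cruise_id": config.cruise_id,
                "latitude": lat[i], "longitude": lon[i],
                "date": date.isoformat()})

            depths = euphotic[i] * z_norm
            p_z = _distribute(p_int[i], depths, euphotic[i], P_SHAPE_KNOTS)
            r_z = _distribute(r_int[i], depths, euphotic[i], R_SHAPE_KNOTS)
            ncp_z = p_z - r_z
            truth_station_rows.append({
                "station_id": sid, "zone": zone, "latitude": lat[i],
                "euphotic_depth": euphotic[i],
                "thermocline_depth": thermo[i], "dcm_depth": euphotic[i],
                "p_int": p_int[i], "r_int": r_int[i],
                "ncp_int": p_int[i] - r_int[i]})

            sd_a = config.analytical_cv * config.baseline_o2
            sd_inc = np.hypot(sd_a, config.biological_sd * per_day)
            for j, z in enumerate(depths):
                truth_level_rows.append({
                    "station_id": sid, "depth_m": z, "light_fraction": f[j],
                    "p": p_z[j], "r": r_z[j], "ncp": ncp_z[j]})
                means = {
                    "zero": config.baseline_o2,
                    "light": config.baseline_o2 + ncp_z[j] * per_day,
                    "dark": config.baseline_o2 - r_z[j] * per_day}
                sds = {"zero": sd_a, "light": sd_inc, "dark": sd_inc}
                for treatment in ("zero", "light", "dark"):
                    o2 = rng.normal(means[treatment], sds[treatment],
                                    config.n_replicates)
                    for k, c in enumerate(o2):
                        bottle_rows.append({
                            "station_id": sid, "depth_m": z,
                            "light_fraction": f[j], "treatment": treatment,
                            "replicate_index": k + 1, "o2_mmol_m3": c})

            # CTD: tanh thermocline + Gaussian DCM at the euphotic depth
            t_noise = rng.normal(0.0, 0.02, len(ctd_grid))
            chl_amp = rng.uniform(0.25, 0.45)
            chl_noise = rng.normal(0.0, 0.003, len(ctd_grid))
            temp = (12.0 + 10.0 * (1.0 - np.tanh(
                (ctd_grid - thermo[i]) / 18.0)) / 2.0 + t_noise)
            chl = (0.05 + chl_amp * np.exp(
                -((ctd_grid - euphotic[i]) ** 2) / (2.0 * 20.0 ** 2))
                + chl_noise)
            for z, t, c in zip(ctd_grid, temp, chl):
                ctd_rows.append({"station_id": sid, "depth_m": z,
                                 "temperature_c": t, "chl_mg_m3": c})

    from .data_io import BOTTLE_COLUMNS, CTD_COLUMNS, STATION_COLUMNS
    dataset = TransectDataset(
        bottles=pd.DataFrame(bottle_rows, columns=BOTTLE_COLUMNS),
        ctd=pd.DataFrame(ctd_rows, columns=CTD_COLUMNS),
        stations=pd.DataFrame(station_rows, columns=STATION_COLUMNS))
    truth = GroundTruth(
        stations=pd.DataFrame(truth_station_rows, columns=[
            "station_id", "zone", "latitude", "euphotic_depth",
            "thermocline_depth", "dcm_depth", "p_int", "r_int", "ncp_int"]),
        levels=pd.DataFrame(truth_level_rows, columns=[
            "station_id", "depth_m", "light_fraction", "p", "r", "ncp"]))
    return dataset, truth
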