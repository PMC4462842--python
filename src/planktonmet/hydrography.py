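"""Thermocline and deep-chlorophyll-maximum detection, province
classification and astronomical-season assignment.

Subtropical gyre stations are identified hydrographically: a station belongs
to the North Atlantic (NAST) or South Atlantic (SATL) subtropical gyre when
both the thermocline and the deep chlorophyll maximum (DCM) lie deeper than
100 m and the station latitude falls inside the gyre band (defaults
20-38 N for NAST, 10-32 S for SATL).  Everything else is OTHER.

The thermocline is located as the depth of maximum |dT/dz| (centred finite
differences on the possibly irregular grid, after a 3-point running-mean
smooth); an alternative definition — the shallowest depth where temperature
drops 0.5 C below its 10 m value — is available via ``method="t05"``.
The DCM is the maximum of the 3-point-smoothed chlorophyll series.  Ties
break to the shallowest depth.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np

from .data_io import CTDProfile, StationMeta
from .errors import DegenerateProfileError, NoThermoclineError

#: Gyre membership requires thermocline and DCM deeper than this (m).
GYRE_DEPTH_THRESHOLD = 100.0
#: Latitude bands (degrees N) for the two gyre provinces.
NAST_BAND = (20.0, 38.0)
SATL_BAND = (-32.0, -10.0)
#: |dT/dz| below this is treated as isothermal (C m-1).
ISOTHERMAL_GRADIENT = 0.005


@dataclass(frozen=True)
class ProvinceAssignment:
    label: str               # NAST | SATL | OTHER
    thermocline_depth: float
    dcm_depth: float
    latitude: float


@dataclass(frozen=True)
class SeasonLabel:
    season: str                       # spring | summer | autumn | winter
    hemisphere_convention: str = "boreal"


def _smooth3(x: np.ndarray) -> np.ndarray:
    """3-point running mean; endpoints average the two available points."""
    x = np.asarray(x, dtype=float)
    s = x.copy()
    if len(x) >= 3:
        s[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
        s[0] = (x[0] + x[1]) / 2.0
        s[-1] = (x[-2] + x[-1]) / 2.0
    return s


def dcm_depth(profile: CTDProfile) -> float:
    """Depth of the (smoothed) chlorophyll maximum; ties to shallowest."""
    if len(profile.depths) < 5:
        raise DegenerateProfileError(
            f"station {profile.station_id}: need >= 5 chlorophyll levels")
    chl = _smooth3(profile.chlorophyll)
    if np.ptp(profile.chlorophyll) == 0:
        raise DegenerateProfileError(
            f"station {profile.station_id}: flat chlorophyll profile")
    return float(profile.depths[int(np.argmax(chl))])


def thermocline_depth(profile: CTDProfile, method: str = "maxgrad") -> float:
    """Thermocline depth from the temperature profile.

    ``"maxgrad"`` (default): depth of maximum |dT/dz| after smoothing.
    ``"t05"``: shallowest depth where T is 0.5 C below the value at 10 m.
    """
    z, t = profile.depths, profile.temperature
    if len(z) < 5 or (z[-1] - z[0]) < 150.0:
        raise DegenerateProfileError(
            f"station {profile.station_id}: need >= 5 temperature levels "
            "spanning >= 150 m")
    ts = _smooth3(t)
    if method == "maxgrad":
        grad = np.abs(np.gradient(ts, z))
        if grad.max() < ISOTHERMAL_GRADIENT:
            raise NoThermoclineError(
                f"station {profile.station_id}: max |dT/dz| "
                f"{grad.max():.4f} C/m; effectively isothermal")
        return float(z[int(np.argmax(grad))])
    if method == "t05":
        t10 = float(np.interp(10.0, z, ts))
        below = np.nonzero(ts <= t10 - 0.5)[0]
        if len(below) == 0:
            raise NoThermoclineError(
                f"station {profile.station_id}: no 0.5 C drop below "
                "the 10 m temperature")
        return float(z[below[0]])
    raise ValueError(f"unknown thermocline method {method!r}")


def classify_province(meta: StationMeta, thermocline_depth_m: float,
                      dcm_depth_m: float,
                      nast_band: tuple[float, float] = NAST_BAND,
                      satl_band: tuple[float, float] = SATL_BAND,
                      depth_threshold: float = GYRE_DEPTH_THRESHOLD
                      ) -> ProvinceAssignment:
    """Assign NAST/SATL/OTHER from latitude and the two criterion depths."""
    deep = (thermocline_depth_m > depth_threshold
            and dcm_depth_m > depth_threshold)
    lat = meta.latitude
    if deep and nast_band[0] <= lat <= nast_band[1]:
        label = "NAST"
    elif deep and satl_band[0] <= lat <= satl_band[1]:
        label = "SATL"
    else:
        label = "OTHER"
    return ProvinceAssignment(label, thermocline_depth_m, dcm_depth_m, lat)


# Astronomical season boundaries (month, day); the boundary day belongs to
# the season it starts.  Boreal convention regardless of hemisphere.
_SEASON_STARTS = [((3, 20), "spring"), ((6, 21), "summer"),
                  ((9, 22), "autumn"), ((12, 21), "winter")]


def assign_season(date: _dt.date) -> SeasonLabel:
    """Boreal astronomical season of a calendar date."""
    md = (date.month, date.day)
    season = "winter"  # before Mar 20
    for start, name in _SEASON_STARTS:
        if md >= start:
            season = name
    return SeasonLabel(season)
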