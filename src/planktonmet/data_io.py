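"""Shared data model and tabular I/O.

All exchange files are delimiter-separated text with a header row
(comma by default, tab via :class:`Dialect`).  Units are fixed across the
package: dissolved oxygen in mmol O2 m-3 (= umol L-1), depths in metres
positive down, light as a fraction of surface PAR in (0, 1], rates in
mmol O2 m-3 d-1 (volumetric) or mmol O2 m-2 d-1 (depth-integrated).

The bottle table schema is
``station_id, depth_m, light_fraction, treatment, replicate_index, o2_mmol_m3``
with ``treatment`` one of ``zero``/``light``/``dark`` (case-insensitive);
the CTD table is ``station_id, depth_m, temperature_c, chl_mg_m3``; the
station table is ``station_id, cruise_id, latitude, longitude, date``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, StructuralError

TREATMENTS = ("zero", "light", "dark")

BOTTLE_COLUMNS = [
    "station_id", "depth_m", "light_fraction", "treatment",
    "replicate_index", "o2_mmol_m3",
]
CTD_COLUMNS = ["station_id", "depth_m", "temperature_c", "chl_mg_m3"]
STATION_COLUMNS = ["station_id", "cruise_id", "latitude", "longitude", "date"]
RATES_COLUMNS = [
    "station_id", "depth_label", "depth_m", "light_fraction",
    "ncp", "r", "p", "se_ncp", "se_r", "se_p",
    "n_zero", "n_light", "n_dark", "qc_flag", "qc_reason",
]


@dataclass(frozen=True)
class Dialect:
    """Options for reading/writing the delimiter-separated exchange files.

    ``light_as_percent=True`` accepts files carrying light levels as
    percentages (divided by 100 on read).
    """

    delimiter: str = ","
    light_as_percent: bool = False


@dataclass(frozen=True)
class StationMeta:
    """Position and time of one station, used for province and season
    assignment."""

    station_id: str
    cruise_id: str
    latitude: float
    longitude: float
    date: _dt.date

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass
class OxygenReplicateSet:
    """Replicate O2 concentrations for one station/depth across the three
    treatments (zero-time, 24-h light, 24-h dark)."""

    station_id: str
    depth: float
    light_fraction: float
    zero_reps: list[float]
    light_reps: list[float]
    dark_reps: list[float]
    incubation_duration: float = 24.0  # hours

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError(f"depth {self.depth} must be >= 0")
        if not 0.0 < self.light_fraction <= 1.0:
            raise ValueError(
                f"light_fraction {self.light_fraction} outside (0, 1]")
        for name in ("zero_reps", "light_reps", "dark_reps"):
            reps = getattr(self, name)
            if len(reps) < 2:
                raise ValueError(f"{name} needs >= 2 replicates")
            if any(c <= 0 for c in reps):
                raise ValueError(f"{name} has non-positive concentration")
        if self.incubation_duration <= 0:
            raise ValueError("incubation_duration must be positive")


@dataclass
class CTDProfile:
    """Per-station vertical profile of temperature and chlorophyll,
    depths strictly increasing."""

    station_id: str
    depths: np.ndarray
    temperature: np.ndarray
    chlorophyll: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.chlorophyll = np.asarray(self.chlorophyll, dtype=float)
        if not (len(self.depths) == len(self.temperature)
                == len(self.chlorophyll)):
            raise ValueError("depth/temperature/chlorophyll lengths differ")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")


def _require_columns(df: pd.DataFrame, columns: Sequence[str],
                     path: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def bottle_sets_from_frame(df: pd.DataFrame, source: str = "<frame>"
                           ) -> list[OxygenReplicateSet]:
    """Group a bottle table (already in memory) into one
    :class:`OxygenReplicateSet` per (station, depth).

    Raises ``ValueError`` (with the offending row number) for an unknown
    treatment and :class:`StructuralError` when a station/depth lacks one of
    the three treatments.  Row order is irrelevant.
    """
    if df.empty:
        return []
    treatment = df["treatment"].astype(str).str.strip().str.lower()
    bad = ~treatment.isin(TREATMENTS)
    if bad.any():
        row = int(df.index[bad][0]) + 2  # header is line 1
        raise ValueError(
            f"{source}: line {row}: treatment "
            f"{df['treatment'][bad].iloc[0]!r} not in {TREATMENTS}")
    df = df.assign(treatment=treatment)

    out: list[OxygenReplicateSet] = []
    for (station, depth), grp in df.groupby(["station_id", "depth_m"],
                                            sort=True):
        reps = {t: grp.loc[grp["treatment"] == t, "o2_mmol_m3"]
                     .astype(float).tolist()
                for t in TREATMENTS}
        for t in TREATMENTS:
            if not reps[t]:
                raise StructuralError(
                    f"{source}: station {station!r} depth {depth} lacks "
                    f"'{t}' treatment")
        out.append(OxygenReplicateSet(
            station_id=str(station), depth=float(depth),
            light_fraction=float(grp["light_fraction"].iloc[0]),
            zero_reps=reps["zero"], light_reps=reps["light"],
            dark_reps=reps["dark"]))
    return out


def read_bottle_table(path, dialect: Dialect = Dialect()
                      ) -> list[OxygenReplicateSet]:
    """Read a bottle-replicate table into one :class:`OxygenReplicateSet`
    per (station, depth).

    Raises :class:`SchemaError` for missing columns, ``ValueError`` for an
    unknown treatment, :class:`StructuralError` for a missing treatment.
    """
    df = pd.read_csv(path, sep=dialect.delimiter)
    _require_columns(df, BOTTLE_COLUMNS, str(path))
    if dialect.light_as_percent and not df.empty:
        df["light_fraction"] = df["light_fraction"] / 100.0
    return bottle_sets_from_frame(df, source=str(path))


def ctd_profiles_from_frame(df: pd.DataFrame) -> list[CTDProfile]:
    """Per-station CTD profiles from an in-memory table, sorted by depth
    with duplicate depths collapsed by the mean."""
    out = []
    for station, grp in df.groupby("station_id", sort=True):
        grp = (grp.groupby("depth_m", as_index=False)
                  [["temperature_c", "chl_mg_m3"]].mean()
                  .sort_values("depth_m"))
        out.append(CTDProfile(str(station),
                              grp["depth_m"].to_numpy(),
                              grp["temperature_c"].to_numpy(),
                              grp["chl_mg_m3"].to_numpy()))
    return out


def read_ctd_table(path, dialect: Dialect = Dialect()) -> list[CTDProfile]:
    """Read a CTD table into per-station profiles (see
    :func:`ctd_profiles_from_frame`)."""
    df = pd.read_csv(path, sep=dialect.delimiter)
    _require_columns(df, CTD_COLUMNS, str(path))
    for col in ("depth_m", "temperature_c", "chl_mg_m3"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().sum() > df[col].isna().sum():
            row = int(df.index[coerced.isna() & df[col].notna()][0]) + 2
            raise ValueError(f"{path}: line {row}: non-numeric {col}")
        df[col] = coerced
    return ctd_profiles_from_frame(df)


def read_station_table(path, dialect: Dialect = Dialect()
                       ) -> list[StationMeta]:
    """Read station metadata; dates must be ISO (YYYY-MM-DD)."""
    df = pd.read_csv(path, sep=dialect.delimiter)
    _require_columns(df, STATION_COLUMNS, str(path))
    ids = df["station_id"].astype(str)
    if ids.duplicated().any():
        raise StructuralError(
            f"{path}: duplicate station_id {ids[ids.duplicated()].iloc[0]!r}")
    return [StationMeta(str(r.station_id), str(r.cruise_id),
                        float(r.latitude), float(r.longitude),
                        _dt.date.fromisoformat(str(r.date)))
            for r in df.itertuples()]


def write_rates_table(rates: pd.DataFrame, path,
                      dialect: Dialect = Dialect()) -> None:
    """Write a rates table (volumetric rows plus per-station rows whose
    ``depth_label`` is ``"integrated"``). Round-trips through
    :func:`read_rates_table` to better than 6 significant figures."""
    df = pd.DataFrame(rates, columns=RATES_COLUMNS if rates is None or
                      len(rates) == 0 else rates.columns)
    df.to_csv(path, sep=dialect.delimiter, index=False, float_format="%.10g")


def read_rates_table(path, dialect: Dialect = Dialect()) -> pd.DataFrame:
    df = pd.read_csv(path, sep=dialect.delimiter)
    _require_columns(df, ["station_id", "depth_label", "ncp", "r", "p"],
                     str(path))
    return df


def write_table(df: pd.DataFrame, path, dialect: Dialect = Dialect()) -> None:
    """Generic writer used for CTD/station/ground-truth tables."""
    df.to_csv(path, sep=dialect.delimiter, index=False, float_format="%.10g")
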