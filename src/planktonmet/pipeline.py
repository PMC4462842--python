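"""End-to-end orchestration: bottle tables -> volumetric rates -> QC ->
station profiles -> euphotic-zone integrals -> province/season labels ->
regional summaries and P:R fits.

This is the glue the CLI and the reproduction script drive; each stage is a
thin call into the corresponding module so every step stays individually
testable.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bottle_rates, hydrography, profile_integration, region_stats
from . import pr_scaling
from .data_io import (OxygenReplicateSet, StationMeta, bottle_sets_from_frame,
                      ctd_profiles_from_frame)
from .errors import DegenerateProfileError

logger = logging.getLogger(__name__)


@dataclass
class PipelineResults:
    volumetric: pd.DataFrame       # one row per station/depth, QC flags set
    integrated: pd.DataFrame       # one row per retained station
    classification: pd.DataFrame   # province + season per station
    qc_report: pd.DataFrame        # excluded stations and reasons
    fits: dict[str, pr_scaling.ScalingFit] = field(default_factory=dict)
    summaries: pd.DataFrame | None = None


def volumetric_table(sets: list[OxygenReplicateSet], alpha: float = 0.05,
                     cv_threshold: float = bottle_rates.DEFAULT_CV_THRESHOLD
                     ) -> pd.DataFrame:
    """Compute QC-evaluated volumetric rates for every replicate set."""
    rows = []
    for reps in sets:
        v = bottle_rates.qc_evaluate(bottle_rates.compute_rates(reps), reps,
                                     alpha=alpha, cv_threshold=cv_threshold)
        rows.append({
            "station_id": v.station_id, "depth_label": "volumetric",
            "depth_m": v.depth, "light_fraction": v.light_fraction,
            "ncp": v.ncp, "r": v.r, "p": v.p,
            "se_ncp": v.se_ncp, "se_r": v.se_r, "se_p": v.se_p,
            "n_zero": v.n_zero, "n_light": v.n_light, "n_dark": v.n_dark,
            "qc_flag": v.qc_flag, "qc_reason": v.qc_reason})
    return pd.DataFrame(rows)


def apply_station_qc(volumetric: pd.DataFrame
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mark whole stations excluded when any depth fails QC.

    Returns the table with a ``station_keep`` column plus the QC report.
    """
    report_rows = []
    keep = {}
    for sid, grp in volumetric.groupby("station_id", sort=True):
        flagged = grp[grp["qc_flag"] == "exclude"]
        keep[sid] = flagged.empty
        for _, row in flagged.iterrows():
            report_rows.append({"station_id": sid, "depth_m": row.depth_m,
                                "reason": row.qc_reason})
            logger.warning("QC exclusion: station %s depth %.1f m: %s",
                           sid, row.depth_m, row.qc_reason)
    out = volumetric.assign(
        station_keep=volumetric["station_id"].map(keep))
    return out, pd.DataFrame(report_rows,
                             columns=["station_id", "depth_m", "reason"])


def integrate_stations(volumetric: pd.DataFrame,
                       metas: dict[str, StationMeta],
                       surface_extension: bool = True) -> pd.DataFrame:
    """Build a profile per retained station and integrate it.

    The euphotic depth is taken as the depth of the deepest (1% light)
    sample of the station.
    """
    rows = []
    kept = (volumetric[volumetric["station_keep"]]
            if "station_keep" in volumetric.columns else volumetric)
    for sid, grp in kept.groupby("station_id", sort=True):
        grp = grp.sort_values("depth_m")
        levels = [bottle_rates.VolumetricRates(
            station_id=sid, depth=r.depth_m, light_fraction=r.light_fraction,
            ncp=r.ncp, r=r.r, p=r.p, se_ncp=r.se_ncp, se_r=r.se_r,
            se_p=r.se_p, n_zero=int(r.n_zero), n_light=int(r.n_light),
            n_dark=int(r.n_dark)) for r in grp.itertuples()]
        if len(levels) < 3:
            logger.warning("station %s has <3 depths; not integrated", sid)
            continue
        meta = metas.get(sid) or StationMeta(sid, "", 0.0, 0.0,
                                             _dt.date(2000, 1, 1))
        profile = profile_integration.StationProfile(
            meta=meta, levels=levels, euphotic_depth=levels[-1].depth)
        integ = profile_integration.integrate_trapezoid(
            profile, surface_extension=surface_extension)
        logger.info("station %s integrated to %.1f m", sid,
                    integ.integration_depth)
        rows.append({
            "station_id": sid, "depth_label": "integrated",
            "depth_m": integ.integration_depth, "light_fraction": np.nan,
            "ncp": integ.ncp_int, "r": integ.r_int, "p": integ.p_int,
            "se_ncp": integ.sd_ncp_int, "se_r": integ.sd_r_int,
            "se_p": integ.sd_p_int, "n_zero": np.nan, "n_light": np.nan,
            "n_dark": np.nan, "qc_flag": "keep", "qc_reason": ""})
    return pd.DataFrame(rows)


def classify_stations(ctd: pd.DataFrame, stations: pd.DataFrame
                      ) -> pd.DataFrame:
    """Province and season labels for every station with a CTD profile."""
    metas = {str(r.station_id): StationMeta(
        str(r.station_id), str(r.cruise_id), float(r.latitude),
        float(r.longitude), _dt.date.fromisoformat(str(r.date)))
        for r in stations.itertuples()}
    rows = []
    for profile in ctd_profiles_from_frame(ctd):
        meta = metas.get(profile.station_id)
        if meta is None:
            continue
        try:
            tc = hydrography.thermocline_depth(profile)
            dcm = hydrography.dcm_depth(profile)
        except DegenerateProfileError as exc:
            logger.warning("station %s: %s; labelled OTHER",
                           profile.station_id, exc)
            tc, dcm = np.nan, np.nan
        assignment = hydrography.classify_province(
            meta, tc if np.isfinite(tc) else 0.0,
            dcm if np.isfinite(dcm) else 0.0)
        rows.append({
            "station_id": profile.station_id, "province": assignment.label,
            "thermocline_depth": tc, "dcm_depth": dcm,
            "latitude": meta.latitude,
            "season": hydrography.assign_season(meta.date).season})
    return pd.DataFrame(rows, columns=[
        "station_id", "province", "thermocline_depth", "dcm_depth",
        "latitude", "season"])


def run_pipeline(bottles: pd.DataFrame, ctd: pd.DataFrame,
                 stations: pd.DataFrame, alpha: float = 0.05,
                 cv_threshold: float = bottle_rates.DEFAULT_CV_THRESHOLD,
                 surface_extension: bool = True) -> PipelineResults:
    """Run every stage on in-memory tables and collect the results."""
    sets = bottle_sets_from_frame(bottles)
    vol = volumetric_table(sets, alpha=alpha, cv_threshold=cv_threshold)
    if vol.empty:
        empty = vol
        return PipelineResults(vol, empty, classify_stations(ctd, stations),
                               pd.DataFrame(columns=["station_id", "depth_m",
                                                     "reason"]))
    vol, qc_report = apply_station_qc(vol)
    metas = {str(r.station_id): StationMeta(
        str(r.station_id), str(r.cruise_id), float(r.latitude),
        float(r.longitude), _dt.date.fromisoformat(str(r.date)))
        for r in stations.itertuples()}
    integrated = integrate_stations(vol, metas,
                                    surface_extension=surface_extension)
    classification = classify_stations(ctd, stations)

    labels = classification.set_index("station_id")["province"]
    seasons = classification.set_index("station_id")["season"]
    vol = vol.assign(province=vol["station_id"].map(labels),
                     season=vol["station_id"].map(seasons))
    if not integrated.empty:
        integrated = integrated.assign(
            province=integrated["station_id"].map(labels),
            season=integrated["station_id"].map(seasons))

    fits = {}
    for province, grp in integrated.groupby("province"):
        if province in ("NAST", "SATL") and len(grp) >= 3:
            fits[province] = pr_scaling.fit_pr(grp["p"], grp["r"],
                                               region_label=str(province))
    summaries = None
    kept = vol[vol["station_keep"]]
    if not kept.empty:
        summaries = region_stats.regional_summary_table(
            kept.dropna(subset=["province"]))
    return PipelineResults(vol, integrated, classification, qc_report,
                           fits=fits, summaries=summaries)
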