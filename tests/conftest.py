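import datetime as dt

import numpy as np
import pytest

from planktonmet.bottle_rates import VolumetricRates
from planktonmet.data_io import StationMeta
from planktonmet.profile_integration import StationProfile
from planktonmet.synthetic_transect import default_amt_preset, generate_transect


@pytest.fixture(scope="session")
def default_transect():
    """One default-preset synthetic transect plus ground truth (seed 0)."""
    return generate_transect(default_amt_preset(0))


@pytest.fixture(scope="session")
def small_transect():
    """A reduced transect for fast end-to-end tests."""
    from dataclasses import replace
    cfg = replace(default_amt_preset(3),
                  n_stations={"NAST": 5, "SATL": 5, "OTHER": 3})
    return generate_transect(cfg)


def make_profile(depths, ncp, r, se=0.0, euphotic_depth=None,
                 station_id="S1"):
    """Build a StationProfile from plain arrays; se applies to all rates."""
    depths = np.asarray(depths, dtype=float)
    ncp = np.asarray(ncp, dtype=float)
    r = np.asarray(r, dtype=float)
    se = np.broadcast_to(np.asarray(se, dtype=float), depths.shape)
    if euphotic_depth is None:
        euphotic_depth = float(depths[-1])
    frac = np.linspace(0.97, 0.01, len(depths))
    levels = [VolumetricRates(
        station_id=station_id, depth=float(z), light_fraction=float(f),
        ncp=float(n), r=float(rr), p=float(n + rr),
        se_ncp=float(s), se_r=float(s), se_p=float(s),
        n_zero=5, n_light=5, n_dark=5)
        for z, f, n, rr, s in zip(depths, frac, ncp, r, se)]
    meta = StationMeta(station_id, "C1", 25.0, -30.0, dt.date(2011, 10, 1))
    return StationProfile(meta=meta, levels=levels,
                          euphotic_depth=euphotic_depth)
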