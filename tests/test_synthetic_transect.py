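from dataclasses import replace

import numpy as np
import pytest

from planktonmet.bottle_rates import compute_rates
from planktonmet.data_io import bottle_sets_from_frame
from planktonmet.errors import ConfigError
from planktonmet.pipeline import run_pipeline
from planktonmet.profile_integration import trapezoid_weights
from planktonmet.synthetic_transect import (TransectConfig,
                                            default_amt_preset,
                                            generate_transect)


def test_preset_reflects_survey_design():
    cfg = default_amt_preset(0)
    assert cfg.light_fractions == (0.97, 0.33, 0.14, 0.07, 0.01)
    assert cfg.n_stations["NAST"] == 47 and cfg.n_stations["SATL"] == 46
    assert 4 <= cfg.n_replicates <= 6
    assert cfg.hydrography["NAST"].euphotic_mean == 112.0


@pytest.mark.parametrize("bad", [
    dict(light_fractions=(0.97, 0.33, 0.5, 0.01)),   # not decreasing
    dict(light_fractions=(0.97, 0.33, 0.14)),        # does not end at 1%
    dict(analytical_cv=-0.1),
    dict(n_replicates=1),
    dict(n_stations={"NAST": 3, "UNKNOWN": 2}),
])
def test_config_invariants_rejected(bad):
    with pytest.raises(ConfigError):
        replace(default_amt_preset(0), **bad).validate()


def test_zero_stations_yield_empty_schema_valid_dataset():
    cfg = replace(default_amt_preset(0),
                  n_stations={"NAST": 0, "SATL": 0, "OTHER": 0})
    dataset, truth = generate_transect(cfg)
    assert dataset.bottles.empty and dataset.ctd.empty
    assert list(dataset.bottles.columns)[:2] == ["station_id", "depth_m"]
    assert truth.stations.empty


def test_same_seed_is_bit_reproducible_and_seeds_differ():
    d1, t1 = generate_transect(default_amt_preset(42))
    d2, t2 = generate_transect(default_amt_preset(42))
    assert d1.bottles.equals(d2.bottles)
    assert d1.ctd.equals(d2.ctd)
    assert d1.stations.equals(d2.stations)
    assert t1.stations.equals(t2.stations)
    d3, _ = generate_transect(default_amt_preset(43))
    assert not d1.bottles.equals(d3.bottles)


def test_noise_free_generation_recovers_truth_exactly():
    cfg = replace(default_amt_preset(5),
                  n_stations={"NAST": 3, "SATL": 3, "OTHER": 1},
                  analytical_cv=0.0, biological_sd=0.0)
    dataset, truth = generate_transect(cfg)
    levels = truth.levels.set_index(["station_id", "depth_m"])
    for reps in bottle_sets_from_frame(dataset.bottles):
        v = compute_rates(reps)
        t = levels.loc[(reps.station_id, reps.depth)]
        assert v.ncp == pytest.approx(t["ncp"], abs=1e-9)
        assert v.r == pytest.approx(t["r"], abs=1e-9)
        assert v.se_ncp == pytest.approx(0.0, abs=1e-9)


def test_truth_levels_integrate_to_truth_integrals():
    """The vertical distribution is constructed to be exactly
    trapezoid-consistent: integrating true volumetric rates recovers the
    true integrals to 1e-6 relative."""
    _, truth = generate_transect(replace(
        default_amt_preset(7), n_stations={"NAST": 5, "SATL": 5, "OTHER": 2}))
    st = truth.stations.set_index("station_id")
    for sid, grp in truth.levels.groupby("station_id"):
        grp = grp.sort_values("depth_m")
        w, _ = trapezoid_weights(grp["depth_m"].to_numpy(),
                                 st.loc[sid, "euphotic_depth"])
        assert w @ grp["p"].to_numpy() == pytest.approx(
            st.loc[sid, "p_int"], rel=1e-6)
        assert w @ grp["r"].to_numpy() == pytest.approx(
            st.loc[sid, "r_int"], rel=1e-6)
        assert w @ grp["ncp"].to_numpy() == pytest.approx(
            st.loc[sid, "ncp_int"], rel=1e-6, abs=1e-8)


def test_truth_is_internally_consistent():
    _, truth = generate_transect(replace(
        default_amt_preset(11), n_stations={"NAST": 4, "SATL": 4,
                                            "OTHER": 2}))
    np.testing.assert_allclose(truth.stations["ncp_int"],
                               truth.stations["p_int"]
                               - truth.stations["r_int"], rtol=1e-12)
    np.testing.assert_allclose(truth.levels["ncp"],
                               truth.levels["p"] - truth.levels["r"],
                               rtol=1e-9, atol=1e-12)
    assert (truth.levels["r"] > 0).all()
    assert (truth.levels["p"] > 0).all()


def test_pipeline_estimates_unbiased_against_truth():
    """Measured integrated NCP minus true integrated NCP has no systematic
    offset beyond 2 Monte-Carlo standard errors (20 seeds)."""
    errors = []
    for seed in range(20):
        dataset, truth = generate_transect(default_amt_preset(seed))
        st = truth.stations.set_index("station_id")
        per_station = {}
        for reps in bottle_sets_from_frame(dataset.bottles):
            v = compute_rates(reps)
            per_station.setdefault(reps.station_id, []).append(
                (reps.depth, v.ncp))
        for sid, rows in per_station.items():
            rows.sort()
            z = np.array([d for d, _ in rows])
            ncp = np.array([n for _, n in rows])
            w, _ = trapezoid_weights(z, st.loc[sid, "euphotic_depth"])
            errors.append(w @ ncp - st.loc[sid, "ncp_int"])
    errors = np.asarray(errors)
    mc_se = errors.std(ddof=1) / np.sqrt(len(errors))
    assert abs(errors.mean()) < 2 * mc_se
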