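import numpy as np
import pandas as pd
import pytest
from scipy.spatial import ConvexHull

from gpgraze import metrics as gm
from conftest import make_day_fixes


def shoelace(points):
    x, y = points[:, 0], points[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


# ------------------------------------------------------------ daily metrics
def test_horizontal_distance_3_4_5():
    day = make_day_fixes([0, 3], [0, 4])
    assert gm.daily_distance_metrics(day)["dist_ho"] == pytest.approx(5.0)


def test_vertical_distance_and_gain_hand_sums():
    day = make_day_fixes([0, 1, 2, 3], [0, 0, 0, 0], elevations=[100, 110, 105, 120])
    out = gm.daily_distance_metrics(day)
    assert out["dist_ve"] == pytest.approx(30.0)   # 10 + 5 + 15
    assert out["ele_gain"] == pytest.approx(25.0)  # 10 + 15
    stats_ = gm.daily_elevation_slope_stats(day)
    assert stats_["ele_range"] == pytest.approx(20.0)


def test_stationary_day_zero_distances():
    day = make_day_fixes([5, 5, 5], [5, 5, 5], elevations=[300, 300, 300])
    out = gm.daily_distance_metrics(day)
    assert out["dist_ho"] == out["dist_ve"] == out["ele_gain"] == 0


def test_distance_requires_two_fixes():
    with pytest.raises(ValueError):
        gm.daily_distance_metrics(make_day_fixes([0], [0]))


def test_constant_slope_collapses_statistics():
    day = make_day_fixes(np.arange(4.0), np.zeros(4), slopes=np.full(4, 10.0))
    s = gm.daily_elevation_slope_stats(day)
    assert s["slope_mean"] == s["slope_max"] == s["slope85"] == s["slope15"] == 10.0


def test_quantiles_use_linear_interpolation():
    slopes = np.arange(1.0, 101.0)
    day = make_day_fixes(np.arange(100.0), np.zeros(100), slopes=slopes)
    s = gm.daily_elevation_slope_stats(day)
    assert s["slope85"] == pytest.approx(85.15)
    assert s["slope15"] == pytest.approx(15.85)
    assert s["slope15"] <= s["slope85"] <= s["slope_max"]


# ------------------------------------------------------------------- hulls
def test_square_path_one_hectare():
    day = make_day_fixes([0, 100, 100, 0], [0, 0, 100, 100])
    assert gm.daily_home_range_mcp(day) == pytest.approx(1.0)


def test_triangle_half_hectare():
    day = make_day_fixes([0, 100, 0], [0, 0, 100])
    assert gm.daily_home_range_mcp(day) == pytest.approx(0.5)


def test_collinear_day_is_missing():
    day = make_day_fixes([0, 50, 100], [0, 0, 0])
    assert np.isnan(gm.daily_home_range_mcp(day))
    assert np.isnan(gm.daily_tortuosity(100.0, gm.daily_home_range_mcp(day)))


def test_hull_area_matches_shoelace_oracle_on_random_instances():
    rng = np.random.default_rng(12345)
    for _ in range(1000):
        pts = rng.uniform([0, 0], [200, 100], size=(50, 2))
        day = make_day_fixes(pts[:, 0], pts[:, 1])
        hull = ConvexHull(pts)
        oracle_ha = shoelace(pts[hull.vertices]) / 1e4
        assert gm.daily_home_range_mcp(day) == pytest.approx(oracle_ha, rel=1e-9)


def test_point_inside_hull_does_not_change_area():
    rng = np.random.default_rng(3)
    pts = rng.uniform(0, 100, size=(20, 2))
    day = make_day_fixes(pts[:, 0], pts[:, 1])
    base = gm.daily_home_range_mcp(day)
    centroid = pts.mean(axis=0)
    day2 = make_day_fixes(
        np.append(pts[:, 0], centroid[0]), np.append(pts[:, 1], centroid[1])
    )
    assert gm.daily_home_range_mcp(day2) == pytest.approx(base)


def test_tortuosity_formula_and_linearity():
    assert gm.daily_tortuosity(400.0, 1.0) == pytest.approx(400.0)
    assert gm.daily_tortuosity(800.0, 1.0) == pytest.approx(2 * gm.daily_tortuosity(400.0, 1.0))


def test_square_day_tortuosity_from_perimeter():
    day = make_day_fixes([0, 100, 100, 0, 0], [0, 0, 100, 100, 0])
    d = gm.daily_distance_metrics(day)["dist_ho"]
    hr = gm.daily_home_range_mcp(day)
    assert gm.daily_tortuosity(d, hr) == pytest.approx(400.0)


# ------------------------------------------------ invariance property checks
def test_translation_and_scale_behaviour():
    rng = np.random.default_rng(9)
    pts = rng.uniform(0, 200, size=(30, 2))
    day = make_day_fixes(pts[:, 0], pts[:, 1])
    d0 = gm.daily_distance_metrics(day)["dist_ho"]
    h0 = gm.daily_home_range_mcp(day)
    shifted = make_day_fixes(pts[:, 0] + 1e5, pts[:, 1] - 4.2e4)
    assert gm.daily_distance_metrics(shifted)["dist_ho"] == pytest.approx(d0)
    assert gm.daily_home_range_mcp(shifted) == pytest.approx(h0)
    c = 3.0
    scaled = make_day_fixes(c * pts[:, 0], c * pts[:, 1])
    assert gm.daily_distance_metrics(scaled)["dist_ho"] == pytest.approx(c * d0)
    assert gm.daily_home_range_mcp(scaled) == pytest.approx(c**2 * h0)
    assert gm.daily_tortuosity(
        c * d0, gm.daily_home_range_mcp(scaled)
    ) == pytest.approx(gm.daily_tortuosity(d0, h0) / c)


# ------------------------------------------------- herd-relative and centred
def _daily_row(**kw):
    base = dict(cow_id="a", farm_id="f", genotype="AB", date="2020-06-01",
                n_fixes=100, dist_ho=4000.0, dist_ve=10.0, ele_range=50.0,
                ele_gain=20.0, ele_mean=400.0, ele85=420.0, ele15=380.0,
                slope_mean=10.0, slope_max=20.0, slope_min=2.0, slope85=15.0,
                slope15=5.0, hr_mcp=10.0, sp_tortuosity=400.0,
                ele_min=350.0, ele_max=450.0,
                ele_mean_farm=0.0, ele85_farm=20.0, ele15_farm=-20.0,
                adj_dist_ho=3500.0, adj_ele_mean=450.0,
                rel_ele_range=0.5, rel_ele_mean=0.5, rel_slope_range=1.0)
    base.update(kw)
    return base


def test_adjusted_metric_formulas():
    daily = pd.DataFrame([
        _daily_row(cow_id="a", dist_ho=4000.0, ele_mean=400.0, ele_min=300.0, ele_max=500.0),
        _daily_row(cow_id="b", dist_ho=3800.0, ele_mean=350.0, ele_min=300.0, ele_max=400.0),
    ])
    out = gm.adjusted_and_relative_metrics(daily)
    a = out.loc[out.cow_id == "a"].iloc[0]
    b = out.loc[out.cow_id == "b"].iloc[0]
    assert a.adj_dist_ho == pytest.approx(4000 - 3800 + 3500)
    assert b.adj_dist_ho == pytest.approx(3500.0)  # the herd-min cow anchors at 3500
    assert a.adj_ele_mean == pytest.approx(400 - 300 + 350)
    assert a.rel_ele_mean == pytest.approx((400 - 300) / 200)
    assert a.rel_ele_range == pytest.approx(50 / 200)
    assert a.rel_slope_range == pytest.approx((20 - 2) / (20 - 2))


def test_single_cow_farm_day_has_no_relative_metrics():
    daily = pd.DataFrame([_daily_row()])
    out = gm.adjusted_and_relative_metrics(daily)
    assert out[["adj_dist_ho", "rel_ele_mean", "rel_slope_range"]].isna().all().all()


def test_farm_centred_values_sum_to_zero():
    daily = pd.DataFrame([
        _daily_row(cow_id="a", ele_mean=400.0, ele85=410.0, ele15=390.0),
        _daily_row(cow_id="b", ele_mean=600.0, ele85=610.0, ele15=590.0),
    ])
    out = gm.farm_centred_metrics(daily)
    assert sorted(out.ele_mean_farm.tolist()) == [-100.0, 100.0]
    assert out.ele_mean_farm.sum() == pytest.approx(0.0, abs=1e-9)


def test_single_cow_day_self_centres_to_zero():
    out = gm.farm_centred_metrics(pd.DataFrame([_daily_row()]))
    assert out.ele_mean_farm.iloc[0] == 0.0


def test_centring_recomputed_after_cohort_change():
    daily = pd.DataFrame([
        _daily_row(cow_id="a", ele_mean=400.0),
        _daily_row(cow_id="b", ele_mean=600.0),
        _daily_row(cow_id="c", ele_mean=800.0),
    ])
    full = gm.farm_centred_metrics(daily)
    reduced = gm.farm_centred_metrics(daily, cohort_cow_ids=["a", "b"])
    # brute-force grand means: 600 over all, 500 over {a, b}
    assert full.loc[full.cow_id == "a", "ele_mean_farm"].iloc[0] == pytest.approx(-200.0)
    assert reduced.loc[reduced.cow_id == "a", "ele_mean_farm"].iloc[0] == pytest.approx(-100.0)


# --------------------------------------------------------------- aggregation
def test_cow_profile_has_35_variables():
    assert len(gm.PROFILE_VARIABLES) == 35
    assert len(gm.DAILY_METRICS) == 18
    assert len(gm.CV_METRICS) == 17
    assert "ele_mean_farm_cv" not in gm.PROFILE_VARIABLES


def test_cv_hand_computation():
    rows = []
    for i, (d1, d2) in enumerate([(1.0, 3.0)]):
        for day, v in enumerate((d1, d2)):
            rows.append(_daily_row(date=f"2020-06-{day + 1:02d}", dist_ho=v))
    daily = pd.DataFrame(rows)
    prof = gm.aggregate_cow(daily, min_days=2)
    assert prof["dist_ho"] == pytest.approx(2.0)
    assert prof["dist_ho_cv"] == pytest.approx(np.sqrt(2) / 2)


def test_constant_metric_has_zero_cv():
    daily = pd.DataFrame(
        [_daily_row(date=f"2020-06-{d:02d}") for d in range(1, 9)]
    )
    prof = gm.aggregate_cow(daily, min_days=7)
    assert prof["dist_ho_cv"] == 0.0


def test_aggregation_requires_min_days():
    daily = pd.DataFrame([_daily_row(date=f"2020-06-{d:02d}") for d in range(1, 4)])
    with pytest.raises(ValueError, match="valid days"):
        gm.aggregate_cow(daily, min_days=7)


def test_days_missing_a_metric_omitted_from_that_metric_only():
    rows = [_daily_row(date=f"2020-06-{d:02d}") for d in range(1, 9)]
    rows[0]["hr_mcp"] = np.nan
    rows[0]["sp_tortuosity"] = np.nan
    daily = pd.DataFrame(rows)
    prof = gm.aggregate_cow(daily, min_days=7)
    assert prof["hr_mcp"] == pytest.approx(10.0)
    assert prof["dist_ho"] == pytest.approx(4000.0)


# ---------------------------------------------------------------- transforms
def test_transform_map_matches_variable_list():
    assert set(gm.TRANSFORM_MAP) == set(gm.PROFILE_VARIABLES)
    assert gm.TRANSFORM_MAP["dist_ho"] == "sqrt"
    assert gm.TRANSFORM_MAP["hr_mcp"] == "log"
    assert gm.TRANSFORM_MAP["adj_ele_mean"] == "square"
    assert gm.TRANSFORM_MAP["rel_ele_range"] == "cbrt"
    assert gm.TRANSFORM_MAP["ele_range"] == "identity"


def test_transform_examples_and_roundtrip():
    df = pd.DataFrame({"rel_ele_range": [8.0], "ele_range": [123.0], "hr_mcp": [10.0]})
    out, log = gm.apply_transforms(df, {"rel_ele_range": "cbrt", "ele_range": "identity", "hr_mcp": "log"})
    assert out.rel_ele_range.iloc[0] == pytest.approx(2.0)
    assert out.ele_range.iloc[0] == 123.0  # identity passes through
    assert log == []
    for name in ("log", "sqrt", "cbrt", "square", "identity"):
        x = np.array([0.3, 1.7, 42.0])
        y = gm._FORWARD[name](x)
        assert np.allclose(gm.inverse_transform(y, name), x, atol=1e-9)


def test_log_of_nonpositive_policies():
    df = pd.DataFrame({"hr_mcp": [0.0, 1.0, 4.0]})
    with pytest.raises(ValueError, match="non-positive"):
        gm.apply_transforms(df, {"hr_mcp": "log"}, on_invalid="error")
    out, log = gm.apply_transforms(df, {"hr_mcp": "log"}, on_invalid="offset")
    assert log[0]["action"] == "offset"
    assert np.isfinite(out.hr_mcp).all()
    df_neg = pd.DataFrame({"ele85_farm_cv": [-0.5, 1.0]})
    out2, log2 = gm.apply_transforms(df_neg, {"ele85_farm_cv": "log"}, on_invalid="skip")
    assert log2[0]["action"] == "skipped"
    assert out2.ele85_farm_cv.tolist() == [-0.5, 1.0]


# ------------------------------------------------------------ end-to-end-ish
def test_profiles_from_simulated_herd(small_herd):
    from gpgraze.qc import qc_herd

    fixes, truth, terrains, config = small_herd
    clean, _, _, _ = qc_herd(fixes, terrains, fix_interval_s=config.fix_interval_s)
    daily = gm.adjusted_and_relative_metrics(gm.compute_daily_metrics(clean))
    prof = gm.compute_cow_profiles(daily)
    var_cols = [c for c in prof.columns if c in gm.PROFILE_VARIABLES]
    assert len(var_cols) == 35
    assert len(prof) == len(truth)
    # relative metrics live on the unit interval
    assert prof.rel_ele_mean.dropna().between(0, 1).all()
    assert (prof[["dist_ho", "dist_ve", "ele_gain", "hr_mcp"]] >= 0).all().all()
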