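"""Vegetation indices, accuracy metrics, PICS diagnostics, trends, and the
site-level GPP comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lcspp.grids import GridSpec, periods_list
from lcspp.io import make_dataset
from lcspp.validate import (
    aggregate_site_daily,
    area_weighted_mean,
    growing_season_mask,
    low_signal_mask,
    nse,
    pics_diagnostics,
    r2,
    rmse,
    site_gpp_comparison,
    trend_ols,
    trend_theil_sen_mk,
    vegetation_indices,
)


def test_vegetation_index_arithmetic():
    out = vegetation_indices(np.array([0.05]), np.array([0.45]),
                             rad=np.array([200.0]))
    assert out["ndvi"][0] == pytest.approx(0.8)
    assert out["nirv"][0] == pytest.approx(0.36)
    assert out["nirvp"][0] == pytest.approx(72.0)
    zero = vegetation_indices(np.array([0.3]), np.array([0.3]))
    assert zero["ndvi"][0] == 0.0 and zero["kndvi"][0] == 0.0 and zero["nirv"][0] == 0.0
    undef = vegetation_indices(np.array([0.0]), np.array([0.0]))
    assert np.isnan(undef["ndvi"][0])


def test_kndvi_unit_argument_identity():
    red, nir = np.array([0.1]), np.array([0.5])
    sigma = (nir - red) / 2.0
    out = vegetation_indices(red, nir, kndvi_sigma=sigma)
    assert out["kndvi"][0] == pytest.approx(np.tanh(1.0))


@given(st.floats(0.01, 0.9), st.floats(0.01, 0.9))
@settings(max_examples=100, deadline=None)
def test_kndvi_default_sigma_equals_tanh_ndvi_squared(red, nir):
    out = vegetation_indices(np.array([red]), np.array([nir]))
    assert out["kndvi"][0] == pytest.approx(np.tanh(out["ndvi"][0] ** 2), abs=1e-12)


def test_accuracy_metrics_hand_computed():
    obs = np.array([1.0, 2.0, 3.0])
    pred = np.array([2.0, 2.0, 2.0])
    assert rmse(pred, obs) == pytest.approx(np.sqrt(2 / 3))
    assert nse(pred, obs) == pytest.approx(0.0)
    perfect = nse(obs, obs), rmse(obs, obs), r2(obs, obs)
    assert perfect == (pytest.approx(1.0), pytest.approx(0.0), pytest.approx(1.0))
    with pytest.raises(ValueError, match="zero variance"):
        nse(pred, np.array([2.0, 2.0, 2.0]))


def _annual_cube(values_by_year, grid):
    """Cube whose PICS series takes a constant value per year."""
    years = sorted(values_by_year)
    pers = periods_list(years[0], len(years))
    vals = np.empty((len(pers),) + grid.shape, dtype=np.float32)
    for i, p in enumerate(pers):
        vals[i] = values_by_year[p.year]
    ds = make_dataset(grid, pers, {"red": vals, "nir": vals})
    return ds


def test_pics_diagnostics_constant_series(small_grid):
    ds = _annual_cube({y: 0.4 for y in range(1990, 1996)}, small_grid)
    diag = pics_diagnostics(ds, [(0, 0), (1, 1)],
                            switch_times=["1993-01-01"])
    # tolerance set by float32 storage of the 0.4 series
    assert diag.max_abs_anomaly_pct("red") == pytest.approx(0.0, abs=1e-4)
    assert diag.discontinuities_pct["red"]["1993-01-01"] == pytest.approx(0.0, abs=1e-4)


def test_pics_diagnostics_recovers_injected_step(small_grid):
    vals = {y: 0.4 for y in range(1990, 1996)}
    for y in (1993, 1994, 1995):
        vals[y] = 0.4 * 1.05  # +5% of the mean after the switch
    ds = _annual_cube(vals, small_grid)
    diag = pics_diagnostics(ds, [(0, 0)], switch_times=["1993-01-01"])
    step = diag.discontinuities_pct["red"]["1993-01-01"]
    assert step == pytest.approx(100 * 0.02 / 0.41, rel=0.05)  # ~4.9%


def test_pics_global_correlation_null(small_grid):
    """Independent PICS and global anomaly series: p > 0.05 in >= 90% of
    seeded replicates."""
    rng = np.random.default_rng(123)
    n_ok = 0
    reps = 20
    for _ in range(reps):
        vals = {1990 + i: 0.4 + rng.normal(0, 0.004) for i in range(10)}
        ds = _annual_cube(vals, small_grid)
        diag = pics_diagnostics(
            ds, [(0, 0)],
            global_anomalies={"red": rng.normal(0, 1, 10)})
        r_val, p_val = diag.global_correlation["red"]
        n_ok += p_val > 0.05
    assert n_ok >= 0.9 * reps


def test_trends_on_noiseless_line():
    years = np.arange(1990, 2002)
    y = 2.0 * (years - 1990) + 5.0
    ols = trend_ols(years, y)
    ts = trend_theil_sen_mk(years, y)
    assert ols.slope_per_decade == pytest.approx(20.0, abs=1e-10)
    assert ts.slope_per_decade == pytest.approx(20.0, abs=1e-10)
    assert ols.p_value < 1e-6 and ts.p_value < 0.05


def test_mk_ties_only_series():
    years = np.arange(1990, 2000)
    res = trend_theil_sen_mk(years, np.full(10, 3.0))
    assert res.p_value == 1.0 and res.slope_per_decade == 0.0


def test_mk_minimum_length():
    with pytest.raises(ValueError):
        trend_theil_sen_mk(np.arange(5), np.arange(5.0))


def test_growing_season_strict_threshold():
    ta = np.array([[[10.0]], [[5.0]], [[4.0]]])  # 3 "months"
    mask = growing_season_mask(ta)
    assert mask[0, 0, 0] and not mask[1, 0, 0] and not mask[2, 0, 0]


def test_area_weighted_mean_constancy():
    lat = np.array([60.0, 30.0, 0.0])
    field = np.full((5, 3, 4), 0.7)
    out = area_weighted_mean(field, lat)
    np.testing.assert_allclose(out, 0.7, atol=1e-12)
    mask = np.zeros((3, 4), dtype=bool)
    mask[0, :] = True
    np.testing.assert_allclose(area_weighted_mean(field, lat, mask), 0.7)


def test_low_signal_mask_boundary():
    clim = np.array([0.02, 0.03, 0.05])
    np.testing.assert_array_equal(low_signal_mask(clim), [False, True, True])


def _site_table(qc_low_periods=(), n_periods=48, seed=0, proxy_noise=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    pers = periods_list(2001, n_periods // 24)
    for site, lc in [("S1", "DBF"), ("S2", "DBF"), ("S3", "DBF")]:
        gpp = rng.uniform(1, 10, n_periods)
        for i, p in enumerate(pers):
            rows.append({
                "site": site, "landcover": lc, "year": p.year, "poy": p.ordinal,
                "gpp": gpp[i],
                "perfect": gpp[i],
                "noisy": gpp[i] + rng.normal(0, 2.0 + proxy_noise),
                "qc": 0.5 if (p.year, p.ordinal) in qc_low_periods else 0.9,
            })
    return pd.DataFrame(rows)


def test_site_qc_filter_drops_exactly_the_low_periods():
    low = {(2001, 3), (2001, 10), (2002, 5)}
    df = _site_table(qc_low_periods=low)
    comp, _ = site_gpp_comparison(df, ["perfect"])
    assert (comp["n_periods"] == 48 - len(low)).all()
    comp_all, _ = site_gpp_comparison(_site_table(), ["perfect"])
    assert (comp_all["n_periods"] == 48).all()  # QC == 0.9 everywhere: nothing dropped


def test_perfect_proxy_beats_noisy_proxy():
    df = _site_table(seed=3)
    comp, tests = site_gpp_comparison(df, ["perfect", "noisy"])
    assert np.allclose(comp["r2_perfect"], 1.0)
    assert (comp["r2_noisy"] < 1.0).all()
    row = tests.iloc[0]
    assert row["p_one_tailed_a_beats_b"] < 0.05


def test_identical_proxies_give_null_comparison():
    df = _site_table(seed=4)
    df["perfect2"] = df["perfect"]
    _, tests = site_gpp_comparison(df, ["perfect", "perfect2"])
    assert tests.iloc[0]["p_two_tailed"] == 1.0


def test_era_split_requires_minimum_years():
    df = _site_table(n_periods=96, seed=5)  # 2001-2004: only 2 years per era
    comp, _ = site_gpp_comparison(df, ["perfect"], era_split_year=2003,
                                  min_years_per_era=3)
    assert comp.empty
    comp2, _ = site_gpp_comparison(df, ["perfect"], era_split_year=2003,
                                   min_years_per_era=2)
    assert set(comp2["era"]) == {"pre", "post"}


def test_aggregate_site_daily_biweekly_means():
    import datetime as dt
    days = [dt.date(2001, 1, d) for d in range(1, 32)]
    df = pd.DataFrame({
        "site": "S1", "date": days,
        "gpp": [1.0] * 15 + [3.0] * 16,
        "qc": [1.0] * 15 + [0.5] * 16,
    })
    out = aggregate_site_daily(df, ["gpp"])
    a = out[(out["poy"] == 1)].iloc[0]
    b = out[(out["poy"] == 2)].iloc[0]
    assert a["gpp"] == pytest.approx(1.0) and a["qc"] == pytest.approx(1.0)
    assert b["gpp"] == pytest.approx(3.0) and b["qc"] == pytest.approx(0.5)
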