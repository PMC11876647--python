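"""Windowed linear calibration, residual network, and gap filling."""

import numpy as np
import pytest

from lcspp import crosscal
from lcspp.crosscal import (
    FILL_HANTS,
    FILL_MISSING,
    FILL_OBSERVED,
    FILL_SEASONAL,
    HantsConfig,
    apply_windowed_linear,
    compute_residual,
    fit_windowed_linear,
    hants_gapfill,
    hants_series,
    seasonal_mean_fill,
    train_residual_model,
)
from lcspp.grids import GridSpec, periods_list
from lcspp.io import make_dataset
from lcspp.synthetic import simulate_covariates


def _pair_of_cubes(shape=(8, 8), n_years=3, m=1.0, c=0.0, seed=5):
    """Reference cube with spatial+seasonal structure; drifting = (ref-c)/m."""
    grid = GridSpec.from_bounds(42.0, 0.0, *shape, 0.05)
    pers = periods_list(2000, n_years)
    nt = len(pers)
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.05, 0.5, shape)
    amp = rng.uniform(0.2, 1.0, shape) * 0.1
    truth = base[None] + amp[None] * np.sin(2 * np.pi * np.arange(nt) / 24)[:, None, None]
    ref = make_dataset(grid, pers, {"red": truth, "nir": truth})
    ref["sensor"] = ("time", np.zeros(nt, int))
    drift = make_dataset(grid, pers, {"red": (truth - c) / m, "nir": (truth - c) / m})
    drift["sensor"] = ("time", np.zeros(nt, int))
    return grid, drift, ref, truth


def test_noiseless_affine_map_inverted_exactly():
    _, drift, ref, truth = _pair_of_cubes(m=1.07, c=-0.013)
    lm = fit_windowed_linear(drift, ref, groups={0: "g"}, per_period=False)
    assert np.nanmax(np.abs(lm.slope["red"]["g"] - 1.07)) < 1e-8
    assert np.nanmax(np.abs(lm.intercept["red"]["g"] + 0.013)) < 1e-8
    out = apply_windowed_linear(drift, lm)
    assert np.nanmax(np.abs(out["red"].values - truth)) < 1e-6  # float32 storage
    gamma = compute_residual(out, ref)
    assert np.nanmax(np.abs(gamma["gamma_red"].values)) < 1e-6


def test_identity_map_recovered():
    _, drift, ref, _ = _pair_of_cubes(m=1.0, c=0.0)
    lm = fit_windowed_linear(drift, ref, groups={0: "g"}, per_period=False)
    assert np.nanmax(np.abs(lm.slope["nir"]["g"] - 1.0)) < 1e-8
    assert np.nanmax(np.abs(lm.intercept["nir"]["g"])) < 1e-8


def test_edge_pixels_use_clipped_window():
    grid, drift, ref, truth = _pair_of_cubes(m=1.05, c=0.01)
    lm = fit_windowed_linear(drift, ref, groups={0: "g"}, per_period=False)
    # corner pixel is fitted from its clipped 3x3 neighborhood and still exact
    assert lm.slope["red"]["g"][0, 0, 0] == pytest.approx(1.05, abs=1e-8)
    assert (lm.flag["red"]["g"] != 2).all()


def test_residual_mean_zero_with_intercept():
    """OLS orthogonality: gamma averages to ~0 over the fit sample."""
    _, drift, ref, _ = _pair_of_cubes()
    rng = np.random.default_rng(0)
    noisy = drift.copy(deep=True)
    noisy["red"] = (("time", "lat", "lon"),
                    (drift["red"].values + rng.normal(0, 0.01, drift["red"].shape))
                    .astype(np.float32))
    lm = fit_windowed_linear(noisy, ref, groups={0: "g"}, per_period=False,
                             aggregate_years=False, center_anchor=False)
    out = apply_windowed_linear(noisy, lm)
    gamma = compute_residual(out, ref)
    assert abs(np.nanmean(gamma["gamma_red"].values)) < 2e-4


def test_constant_offset_residual():
    _, drift, ref, _ = _pair_of_cubes()
    shifted = drift.copy(deep=True)
    shifted["red"] = drift["red"] + 0.01
    gamma = compute_residual(shifted, ref)
    np.testing.assert_allclose(gamma["gamma_red"].values, -0.01, atol=1e-6)


# --- residual network ------------------------------------------------------

@pytest.fixture(scope="module")
def residual_setup():
    grid = GridSpec.from_bounds(42.0, 0.0, 10, 10, 0.05)
    met = simulate_covariates(grid, 2000, 3, seed=3)
    pers = periods_list(2000, 3)
    nt = len(pers)
    rng = np.random.default_rng(4)
    lin = make_dataset(grid, pers, {"red": rng.uniform(0.05, 0.5, (nt, 10, 10)),
                                    "nir": rng.uniform(0.1, 0.6, (nt, 10, 10))})
    lin["sensor"] = ("time", np.zeros(nt, int))
    return grid, met, lin, nt


def _gamma_cube(lin, values):
    gam = lin[[]].copy()
    gam["gamma_red"] = (("time", "lat", "lon"), values)
    gam["gamma_nir"] = (("time", "lat", "lon"), values)
    gam["sensor"] = lin["sensor"]
    return gam


def test_residual_model_recovers_linear_function_of_aod(residual_setup):
    grid, met, lin, nt = residual_setup
    gamma_true = 0.05 * (met["aod"].values - 0.2)
    model = train_residual_model(_gamma_cube(lin, gamma_true), met, lin,
                                 max_epochs=300, seed=0)
    feats, _ = crosscal._residual_feature_table(lin, met, lin["time"].values)
    pred = model.predict(feats.reshape(-1, 7))["red"].reshape(gamma_true.shape)
    r2 = 1 - np.mean((pred - gamma_true) ** 2) / gamma_true.var()
    assert r2 > 0.99


def test_residual_model_null_target(residual_setup):
    grid, met, lin, nt = residual_setup
    model = train_residual_model(_gamma_cube(lin, np.zeros((nt, 10, 10))),
                                 met, lin, max_epochs=100, seed=0)
    feats, _ = crosscal._residual_feature_table(lin, met, lin["time"].values)
    pred = model.predict(feats.reshape(-1, 7))["red"]
    assert abs(pred.mean()) < 1e-3


def test_residual_model_permutation_null(residual_setup):
    grid, met, lin, nt = residual_setup
    gamma_true = 0.05 * (met["aod"].values - 0.2)
    rng = np.random.default_rng(9)
    permuted = rng.permutation(gamma_true.ravel()).reshape(gamma_true.shape)
    model = train_residual_model(_gamma_cube(lin, permuted), met, lin,
                                 max_epochs=100, seed=0)
    feats, _ = crosscal._residual_feature_table(lin, met, lin["time"].values)
    pred = model.predict(feats.reshape(-1, 7))["red"].reshape(permuted.shape)
    r2 = 1 - np.mean((pred - permuted) ** 2) / permuted.var()
    assert r2 < 0.2


# --- gap filling -----------------------------------------------------------

def test_seasonal_mean_fill_rules(small_grid):
    pers = periods_list(1993, 3)
    nt = len(pers)
    vals = np.full((nt,) + small_grid.shape, np.nan, dtype=np.float32)
    for i, p in enumerate(pers):
        vals[i] = {1993: 0.3, 1994: 0.7, 1995: 0.5}[p.year]
    # period 10 of 1994 missing -> mean(0.3, 0.5) = 0.4
    vals[24 + 9] = np.nan
    # period 3 of the first year missing -> next-year value alone (0.7)
    vals[2] = np.nan
    cube = make_dataset(small_grid, pers, {"red": vals, "nir": vals})
    out = seasonal_mean_fill(cube)
    assert out["red"].values[24 + 9, 0, 0] == pytest.approx(0.4)
    assert out["red"].values[2, 0, 0] == pytest.approx(0.7)
    assert out["red_fill"].values[24 + 9, 0, 0] == FILL_SEASONAL
    assert (out["red_fill"].values[25] == FILL_OBSERVED).all()
    # no-gap input is the identity
    full = make_dataset(small_grid, pers,
                        {"red": np.ones_like(vals), "nir": np.ones_like(vals)})
    out2 = seasonal_mean_fill(full)
    np.testing.assert_array_equal(out2["red"].values, full["red"].values)


def test_hants_recovers_pure_harmonics_exactly():
    t = np.arange(96)
    w = 2 * np.pi * t / 24
    series = 0.3 + 0.1 * np.cos(w) + 0.04 * np.sin(w) + 0.03 * np.sin(2 * w)
    rng = np.random.default_rng(7)
    gaps = rng.choice(96, 28, replace=False)  # ~30% deleted
    y = series.copy()
    y[gaps] = np.nan
    filled, fit, keep = hants_series(y)
    assert np.max(np.abs(filled[gaps] - series[gaps])) < 1e-8
    # valid observations are never altered
    kept = np.isfinite(y)
    np.testing.assert_array_equal(filled[kept], y[kept])


def test_hants_constant_series():
    y = np.full(48, 0.42)
    y[[5, 30]] = np.nan
    filled, fit, keep = hants_series(y)
    np.testing.assert_allclose(filled, 0.42, atol=1e-10)


def test_hants_rejects_low_outlier_without_perturbing_fit():
    t = np.arange(96)
    w = 2 * np.pi * t / 24
    series = 0.3 + 0.1 * np.cos(w) + 0.03 * np.sin(2 * w)
    y = series.copy()
    y[40] -= 0.2
    filled, fit, keep = hants_series(y)
    assert not keep[40]
    assert np.max(np.abs(fit - series)) < 1e-6
    assert filled[40] == pytest.approx(series[40], abs=1e-6)


def test_hants_insufficient_points_left_unfilled():
    y = np.full(48, np.nan)
    y[:4] = 0.3
    filled, fit, keep = hants_series(y)  # needs 2*3+1 = 7 points
    assert np.isnan(filled[10])


def test_fill_provenance_partition(small_grid):
    pers = periods_list(1993, 4)
    nt = len(pers)
    rng = np.random.default_rng(11)
    t = np.arange(nt)
    base = 0.3 + 0.1 * np.cos(2 * np.pi * t / 24)
    vals = np.tile(base[:, None, None], (1,) + small_grid.shape).astype(np.float32)
    # a two-year-long gap at one pixel defeats the seasonal fill there
    vals[20:68, 0, 0] = np.nan
    vals[30, 1, 1] = np.nan  # isolated gap: seasonal fill handles it
    cube = make_dataset(small_grid, pers, {"red": vals, "nir": vals})
    out = hants_gapfill(seasonal_mean_fill(cube))
    prov = out["red_fill"].values
    assert set(np.unique(prov)) <= {FILL_OBSERVED, FILL_SEASONAL, FILL_HANTS,
                                    FILL_MISSING}
    assert prov[30, 1, 1] == FILL_SEASONAL
    # periods whose adjacent years are both missing fall through to HANTS
    assert (prov[20:24, 0, 0] == FILL_HANTS).all()
    assert (prov[24:48, 0, 0] == FILL_SEASONAL).all()
    assert np.isfinite(out["red"].values).all()
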