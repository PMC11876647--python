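"""Scene generator: injected artifacts are recoverable, noise laws hold."""

import dataclasses
import datetime as dt

import numpy as np
import pytest

from lcspp.grids import GridSpec
from lcspp.synthetic import (
    ArtifactInjection,
    SceneConfig,
    SensorEpoch,
    SensorEpochTable,
    SifTruthModel,
    SurfaceTruthModel,
    simulate_covariates,
    simulate_daily_reflectance,
    simulate_site_gpp,
    simulate_soundings,
)


def _null_injection(epochs):
    ids = [e.sensor_id for e in epochs.epochs]
    return ArtifactInjection(
        sza_drift_max={s: 0.0 for s in ids},
        a1_true={"red": 0.0, "nir": 0.0},
        delta_true={s: {"red": 0.0, "nir": 0.0} for s in ids},
        noise_sd=0.0,
        gap_probability=0.0,
        sza_jitter_sd=0.0,
        met_response={b: {} for b in ("red", "nir")},
    )


@pytest.fixture(scope="module")
def tiny_setup():
    grid = GridSpec.from_bounds(42.0, 0.0, 6, 6, 0.05)
    truth = SurfaceTruthModel.random(grid, seed=3, pics_pixels=[(0, 0), (3, 3)],
                                     base_year=2000)
    epochs = SensorEpochTable([
        SensorEpoch("A", dt.date(2000, 1, 1), dt.date(2001, 12, 31), drifts=True),
        SensorEpoch("B", dt.date(2002, 1, 1), dt.date(2003, 12, 31), drifts=False,
                    reference=True),
    ])
    met = simulate_covariates(grid, 2000, 4, seed=4)
    return grid, truth, epochs, met


def test_null_injection_streams_identical(tiny_setup):
    grid, truth, epochs, met = tiny_setup
    scene = simulate_daily_reflectance(
        truth, _null_injection(epochs), epochs, met, seed=5,
        reference_start=epochs.start)
    np.testing.assert_allclose(scene.drifting.red, scene.reference.red, atol=1e-7)
    np.testing.assert_allclose(scene.drifting.nir, scene.reference.nir, atol=1e-7)


def test_pics_truth_is_flat_and_bright(tiny_setup):
    _, truth, _, _ = tiny_setup
    pics = truth.pics_mask
    assert pics.sum() == 2
    assert np.all(truth.amp1["red"][pics] == 0)
    assert np.all(truth.trend["nir"][pics] == 0)
    assert np.all(truth.mean["red"][pics] > 0.3)
    dates = np.array([dt.date(2000, 1, 1), dt.date(2000, 7, 1)], dtype=object)
    ref = truth.reflectance(dates)
    assert np.allclose(ref["red"][0][pics], ref["red"][1][pics], atol=1e-6)


def test_injected_offset_recovered_at_pics(tiny_setup):
    grid, truth, epochs, met = tiny_setup
    inj = dataclasses.replace(
        _null_injection(epochs),
        delta_true={"A": {"red": 0.02, "nir": 0.0},
                    "B": {"red": 0.0, "nir": 0.0}},
    )
    scene = simulate_daily_reflectance(truth, inj, epochs, met, seed=6,
                                       reference_start=epochs.start)
    pics = np.nonzero(truth.pics_mask)
    in_a = scene.drifting.sensor_index == 0
    dates_a = scene.drifting.dates[in_a]
    truth_a = truth.reflectance(dates_a)["red"][:, pics[0], pics[1]]
    obs_a = scene.drifting.red[in_a][:, pics[0], pics[1]]
    assert abs(float(np.mean(obs_a - truth_a)) - 0.02) < 1e-3


def test_gap_probability_binomial(tiny_setup):
    grid, truth, epochs, met = tiny_setup
    inj = dataclasses.replace(_null_injection(epochs), gap_probability=0.5)
    scene = simulate_daily_reflectance(truth, inj, epochs, met, seed=7,
                                       reference_start=epochs.start)
    frac = scene.drifting.valid[:1000].mean()
    assert abs(frac - 0.5) < 0.05


def test_epoch_table_contracts():
    with pytest.raises(ValueError, match="contiguous"):
        SensorEpochTable([
            SensorEpoch("A", dt.date(2000, 1, 1), dt.date(2000, 12, 30), drifts=True),
            SensorEpoch("B", dt.date(2001, 1, 1), dt.date(2001, 12, 31),
                        drifts=False, reference=True),
        ])
    with pytest.raises(ValueError, match="reference"):
        SensorEpochTable([
            SensorEpoch("A", dt.date(2000, 1, 1), dt.date(2000, 12, 31),
                        drifts=True, reference=True),
            SensorEpoch("B", dt.date(2001, 1, 1), dt.date(2001, 12, 31), drifts=False),
        ])


def test_reference_epoch_must_be_clean():
    cfg = SceneConfig()
    table = cfg.epoch_table()
    inj = cfg.injection()
    bad = dataclasses.replace(
        inj, delta_true={**inj.delta_true, "MetOpB": {"red": 0.01, "nir": 0.0}})
    with pytest.raises(ValueError, match="zero offset"):
        bad.validate_against(table)


def test_covariates_ranges_and_determinism(small_grid):
    a = simulate_covariates(small_grid, 1990, 2, seed=9)
    b = simulate_covariates(small_grid, 1990, 2, seed=9)
    assert a.identical(b)
    assert float(a["cc"].min()) >= 0 and float(a["cc"].max()) <= 1
    assert float(a["ai"].min()) > 0
    # northern-hemisphere Ta peaks in July (periods 13/14)
    ta = a["ta"].values
    poy = a["poy"].values
    july = ta[np.isin(poy, [13, 14])].mean()
    january = ta[np.isin(poy, [1, 2])].mean()
    assert july > january


def test_soundings_noiseless_equal_generating_law(tiny_setup):
    grid, truth, *_ = tiny_setup
    sif = SifTruthModel(noise_sd=0.0)
    tab = simulate_soundings(truth, sif, dt.date(2000, 6, 1), dt.date(2000, 6, 10),
                             seed=10)
    np.testing.assert_allclose(tab["sif_757"], tab["sif_true"], atol=1e-12)
    mu = np.cos(np.deg2rad(tab["sza"].to_numpy()))
    expect = sif.evaluate(tab["red"], tab["nir"], mu)
    np.testing.assert_allclose(tab["sif_757"], expect, atol=1e-6)


def test_sounding_aggregation_obeys_inverse_sqrt_n():
    """sd of an n-sounding cell mean shrinks as sounding_sd / sqrt(n)."""
    rng = np.random.default_rng(12)
    sd = 0.1
    for n in (5, 20):
        means = rng.normal(0.0, sd, (4000, n)).mean(axis=1)
        assert abs(means.std() - sd / np.sqrt(n)) < 0.15 * sd / np.sqrt(n)


def test_sounding_flag_failure_fraction(tiny_setup):
    grid, truth, *_ = tiny_setup
    sif = SifTruthModel()
    tab = simulate_soundings(truth, sif, dt.date(2000, 1, 1), dt.date(2000, 3, 31),
                             seed=13, flag_fail_fraction=0.3)
    flagged = (
        (tab["quality_flag"] != "best")
        | (tab["mode_flag"] != "nadir")
        | (tab["cloud_flag"] != "clear")
    ).mean()
    assert abs(flagged - 0.3) < 0.02


def test_site_gpp_linkage(tiny_setup):
    grid, truth, *_ = tiny_setup
    sif = SifTruthModel()
    sites = [(1, 1), (4, 2)]
    gpp = simulate_site_gpp(truth, sif, sites, dt.date(2000, 1, 1),
                            dt.date(2000, 12, 31), seed=14, noise_sd=0.0)
    for site, sub in gpp.groupby("site"):
        r = np.corrcoef(sub["gpp"], sub["sif_true"])[0, 1]
        assert r > 0.999999  # noiseless linear linkage
    # doubling alpha doubles the slope, R^2 unchanged
    alpha2 = {k: 2 * v for k, v in
              __import__("lcspp.synthetic", fromlist=["DEFAULT_GPP_ALPHA"]).DEFAULT_GPP_ALPHA.items()}
    gpp2 = simulate_site_gpp(truth, sif, sites, dt.date(2000, 1, 1),
                             dt.date(2000, 12, 31), seed=14, noise_sd=0.0,
                             alpha_by_class=alpha2)
    s1 = np.polyfit(gpp[gpp.site == "S000"]["sif_true"], gpp[gpp.site == "S000"]["gpp"], 1)[0]
    s2 = np.polyfit(gpp2[gpp2.site == "S000"]["sif_true"], gpp2[gpp2.site == "S000"]["gpp"], 1)[0]
    assert s2 == pytest.approx(2 * s1, rel=1e-9)


def test_site_gpp_bad_period_fraction(tiny_setup):
    grid, truth, *_ = tiny_setup
    sif = SifTruthModel()
    gpp = simulate_site_gpp(truth, sif, [(2, 2)], dt.date(2000, 1, 1),
                            dt.date(2003, 12, 31), seed=15,
                            bad_period_fraction=0.2)
    from lcspp.validate import aggregate_site_daily
    bi = aggregate_site_daily(gpp, ["gpp"])
    frac_below = (bi["qc"] <= 0.7).mean()
    assert abs(frac_below - 0.2) < 0.1
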