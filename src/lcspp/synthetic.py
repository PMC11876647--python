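"""Synthetic multi-sensor scene generator.

This module emulates every input the calibration / emulation pipeline needs,
with the full ground truth retained so that parameter recovery can be tested:

* a smooth two-band (red/NIR) surface truth with per-pixel seasonal
  harmonics, land-cover labels, and bright aseasonal pseudo-invariant
  calibration (PICS) pixels;
* a *drifting* sensor stream observing that truth through a lineage of
  sensor epochs with injected solar-zenith-angle (SZA) drift, per-epoch
  inter-sensor reflectance offsets, a meteorology-driven response, cloud
  gaps, and observation noise;
* a drift-free *reference* stream (a MODIS-like benchmark) observing the
  same truth over a late overlap window;
* gridded meteorological covariates;
* point SIF "soundings" generated by a known function of
  (red, NIR, cos SZA) plus per-sounding noise, mimicking a sparse
  sun-synchronous sampler with a 13:36 local overpass;
* site-level daily GPP series linearly linked to the true SIF.

Everything is driven by an explicit integer seed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

from .grids import GridSpec, BiweeklyIndex, biweekly_index_of, periods_list
from .io import make_dataset
from .products import cos_sza, daily_mean_cos_sza

__all__ = [
    "LAND_COVER_CLASSES",
    "SurfaceTruthModel",
    "SensorEpoch",
    "SensorEpochTable",
    "ArtifactInjection",
    "SifTruthModel",
    "DailyScene",
    "simulate_daily_reflectance",
    "simulate_covariates",
    "simulate_soundings",
    "simulate_site_gpp",
    "SceneConfig",
    "simulate_scene",
]

LAND_COVER_CLASSES = ["NF", "EBF", "DBF", "MF", "SH", "SAV", "GRA", "CRO", "PICS"]

_OVERPASS_LST = 13.6  # 13:36 nominal local solar time


# ---------------------------------------------------------------------------
# surface truth
# ---------------------------------------------------------------------------

@dataclass
class SurfaceTruthModel:
    """Per-pixel harmonic truth for red and NIR reflectance.

    reflectance(band, t) = mean + A1*cos(2*pi*(doy-p1)/365)
                               + A2*cos(4*pi*(doy-p2)/365) + trend*(year-year0)
    clipped to [0.01, 0.95].  PICS pixels are bright with zero seasonal
    amplitude and zero trend.
    """

    grid: GridSpec
    mean: dict[str, np.ndarray]
    amp1: dict[str, np.ndarray]
    phase1: dict[str, np.ndarray]  # day-of-year of the annual peak
    amp2: dict[str, np.ndarray]
    phase2: dict[str, np.ndarray]
    trend: dict[str, np.ndarray]   # reflectance per year
    landcover: np.ndarray          # strings from LAND_COVER_CLASSES
    base_year: int = 1982

    @property
    def pics_mask(self) -> np.ndarray:
        return self.landcover == "PICS"

    def reflectance(self, dates: np.ndarray) -> dict[str, np.ndarray]:
        """Truth reflectance (nt, nlat, nlon) per band at the given dates."""
        doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
        yfrac = np.array(
            [d.year - self.base_year + (d.timetuple().tm_yday - 1) / 365.25 for d in dates]
        )
        doy = doy[:, None, None]
        yfrac = yfrac[:, None, None]
        out = {}
        for band in ("red", "nir"):
            r = (
                self.mean[band][None]
                + self.amp1[band][None] * np.cos(2 * np.pi * (doy - self.phase1[band][None]) / 365.0)
                + self.amp2[band][None] * np.cos(4 * np.pi * (doy - self.phase2[band][None]) / 365.0)
                + self.trend[band][None] * yfrac
            )
            out[band] = np.clip(r, 0.01, 0.95).astype(np.float32)
        return out

    @classmethod
    def random(
        cls,
        grid: GridSpec,
        seed: int,
        pics_pixels: list[tuple[int, int]] | None = None,
        base_year: int = 1982,
    ) -> "SurfaceTruthModel":
        rng = np.random.default_rng(seed)
        shape = grid.shape
        veg_classes = [c for c in LAND_COVER_CLASSES if c != "PICS"]
        landcover = rng.choice(veg_classes, size=shape).astype("<U4")

        mean = {
            "red": rng.uniform(0.05, 0.12, shape),
            "nir": rng.uniform(0.22, 0.36, shape),
        }
        # red dips while NIR peaks in the growing season: opposite phases
        peak = rng.uniform(170, 230, shape)  # NH mid-summer NIR peak
        amp1 = {
            "red": -rng.uniform(0.01, 0.03, shape),
            "nir": rng.uniform(0.04, 0.10, shape),
        }
        phase1 = {"red": peak, "nir": peak}
        amp2 = {
            "red": rng.uniform(-0.005, 0.005, shape),
            "nir": rng.uniform(-0.01, 0.01, shape),
        }
        phase2 = {"red": rng.uniform(0, 365, shape), "nir": rng.uniform(0, 365, shape)}
        trend = {
            "red": rng.normal(0.0, 1e-4, shape),
            "nir": rng.normal(3e-4, 2e-4, shape),
        }
        if pics_pixels:
            rows = np.array([p[0] for p in pics_pixels])
            cols = np.array([p[1] for p in pics_pixels])
            landcover[rows, cols] = "PICS"
        pics = landcover == "PICS"
        mean["red"][pics] = rng.uniform(0.38, 0.46, pics.sum())
        mean["nir"][pics] = rng.uniform(0.42, 0.50, pics.sum())
        for band in ("red", "nir"):
            amp1[band][pics] = 0.0
            amp2[band][pics] = 0.0
            trend[band][pics] = 0.0
        return cls(grid, mean, amp1, phase1, amp2, phase2, trend, landcover, base_year)


# ---------------------------------------------------------------------------
# sensor lineage and injected artifacts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensorEpoch:
    sensor_id: str
    start: dt.date
    end: dt.date  # inclusive
    drifts: bool
    reference: bool = False


@dataclass
class SensorEpochTable:
    epochs: list[SensorEpoch]

    def __post_init__(self) -> None:
        eps = sorted(self.epochs, key=lambda e: e.start)
        for a, b in zip(eps, eps[1:]):
            if b.start != a.end + dt.timedelta(days=1):
                raise ValueError(
                    f"epochs must be contiguous and non-overlapping: "
                    f"{a.sensor_id} ends {a.end}, {b.sensor_id} starts {b.start}"
                )
        refs = [e for e in eps if e.reference]
        if len(refs) != 1:
            raise ValueError("exactly one reference epoch is required")
        if refs[0] is not eps[-1]:
            raise ValueError("the reference epoch must be last")
        self.epochs = eps

    @property
    def start(self) -> dt.date:
        return self.epochs[0].start

    @property
    def end(self) -> dt.date:
        return self.epochs[-1].end

    def index_of(self, dates: np.ndarray) -> np.ndarray:
        """Epoch index per date."""
        bounds = [e.start for e in self.epochs] + [self.end + dt.timedelta(days=1)]
        out = np.empty(len(dates), dtype=int)
        for i, d in enumerate(dates):
            for k, e in enumerate(self.epochs):
                if e.start <= d <= e.end:
                    out[i] = k
                    break
            else:
                raise ValueError(f"date {d} outside the epoch table")
        return out

    def switch_dates(self) -> list[dt.date]:
        """First day of each epoch after the first (the sensor switches)."""
        return [e.start for e in self.epochs[1:]]


@dataclass
class ArtifactInjection:
    """Artifacts injected into the drifting stream, with truth retained."""

    # per-epoch SZA drift amplitude (degrees reached at epoch end); the
    # drift is a linear ramp from 0, resetting at every epoch change
    sza_drift_max: dict[str, float]
    # true SZA sensitivity of observed reflectance, per band (per degree)
    a1_true: dict[str, float]
    # per-epoch, per-band inter-sensor offset (reflectance units)
    delta_true: dict[str, dict[str, float]]
    noise_sd: float = 0.005
    gap_probability: float = 0.35
    sza_jitter_sd: float = 0.5  # day-to-day acquisition-geometry scatter, deg
    # response of the drifting stream to meteorological anomalies
    met_response: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "red": {"ta": 3e-4, "p": 2e-5, "rad": 1.5e-5, "aod": 0.04, "cc": -0.02},
        "nir": {"ta": -2e-4, "p": -2e-5, "rad": 1e-5, "aod": -0.03, "cc": -0.02},
    })
    exclusion_windows: list[tuple[dt.date, dt.date]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.gap_probability < 1:
            raise ValueError("gap probability must be in [0, 1)")

    def validate_against(self, epochs: SensorEpochTable) -> None:
        for e in epochs.epochs:
            if e.reference:
                if self.sza_drift_max.get(e.sensor_id, 0.0) != 0.0:
                    raise ValueError("reference epoch must have zero drift")
                for band in ("red", "nir"):
                    if self.delta_true.get(e.sensor_id, {}).get(band, 0.0) != 0.0:
                        raise ValueError("reference epoch must have zero offset")


@dataclass
class SifTruthModel:
    """Known generating law for SIF soundings.

    kind='nirv' (default): SIF = scale * cos(SZA) * NIRv + intercept, the
    APAR-dominated structure; kind='linear': affine in (red, nir, cosSZA).
    """

    kind: str = "nirv"
    scale: float = 2.5
    intercept: float = 0.0
    linear_coef: tuple[float, float, float] = (-1.0, 3.0, 0.6)
    noise_sd: float = 0.1  # per-sounding, mW m-2 nm-1 sr-1

    def evaluate(self, red, nir, cos_sza_vals) -> np.ndarray:
        red = np.asarray(red, dtype=float)
        nir = np.asarray(nir, dtype=float)
        mu = np.clip(np.asarray(cos_sza_vals, dtype=float), 0.0, None)
        if self.kind == "nirv":
            with np.errstate(invalid="ignore", divide="ignore"):
                ndvi = np.where(nir + red > 0, (nir - red) / (nir + red), 0.0)
            out = self.scale * mu * ndvi * nir + self.intercept
        elif self.kind == "linear":
            c1, c2, c3 = self.linear_coef
            out = self.intercept + c1 * red + c2 * nir + c3 * mu
        else:
            raise ValueError(f"unknown SIF truth kind: {self.kind!r}")
        return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# daily reflectance streams
# ---------------------------------------------------------------------------

@dataclass
class SensorStream:
    """One sensor's daily observations."""

    dates: np.ndarray           # array of datetime.date
    red: np.ndarray             # (nt, nlat, nlon) float32, NaN where invalid
    nir: np.ndarray
    sza: np.ndarray             # degrees at acquisition
    valid: np.ndarray           # bool
    sensor_index: np.ndarray    # (nt,) epoch index, -1 for single-sensor streams


@dataclass
class DailyScene:
    """Bundle of both streams plus all truth parameters."""

    grid: GridSpec
    truth: SurfaceTruthModel
    injection: ArtifactInjection
    epochs: SensorEpochTable
    met: xr.Dataset
    drifting: SensorStream
    reference: SensorStream
    reference_start: dt.date


def _date_range(start: dt.date, end: dt.date) -> np.ndarray:
    n = (end - start).days + 1
    return np.array([start + dt.timedelta(days=i) for i in range(n)], dtype=object)


def _sza_baseline(grid: GridSpec, dates: np.ndarray) -> np.ndarray:
    """Drift-free SZA (degrees) at the nominal overpass, (nt, nlat)."""
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
    mu = cos_sza(grid.lat_centers[None, :], doy[:, None], _OVERPASS_LST)
    return np.rad2deg(np.arccos(np.clip(mu, -1.0, 1.0)))


def _met_anomaly_per_day(met: xr.Dataset, dates: np.ndarray, var: str) -> np.ndarray:
    """Anomaly of a biweekly covariate vs its period-of-year climatology,
    broadcast to days: (nt, nlat, nlon)."""
    da = met[var]
    clim = da.groupby(met["poy"]).mean("time")
    anom = (da.groupby(met["poy"]) - clim).values
    pkey = {(int(y), int(p)): i for i, (y, p) in
            enumerate(zip(met["year"].values, met["poy"].values))}
    idx = np.array([pkey[(d.year, biweekly_index_of(d).ordinal)] for d in dates])
    return anom[idx]


def simulate_daily_reflectance(
    truth: SurfaceTruthModel,
    inject: ArtifactInjection,
    epochs: SensorEpochTable,
    met: xr.Dataset,
    seed: int,
    reference_start: dt.date,
) -> DailyScene:
    """Generate the drifting and reference daily streams over the epoch span.

    drifting = truth + a1_true*(SZA drift + jitter) + delta_true(epoch)
               + meteorological response + noise
    reference = truth + noise (available from ``reference_start`` onward).
    """
    inject.validate_against(epochs)
    grid = truth.grid
    rng = np.random.default_rng(seed)
    dates = _date_range(epochs.start, epochs.end)
    nt = len(dates)
    nlat, nlon = grid.shape

    truth_ref = truth.reflectance(dates)
    sza_base = _sza_baseline(grid, dates)  # (nt, nlat)

    # --- drifting stream -------------------------------------------------
    ep_idx = epochs.index_of(dates)
    drift = np.zeros(nt)
    for k, e in enumerate(epochs.epochs):
        sel = ep_idx == k
        if not e.drifts:
            continue
        span = max((e.end - e.start).days, 1)
        frac = np.array([(d - e.start).days / span for d in dates[sel]])
        drift[sel] = inject.sza_drift_max.get(e.sensor_id, 0.0) * frac

    jitter = rng.normal(0.0, inject.sza_jitter_sd, (nt, nlat, nlon))
    sza_drifting = sza_base[:, :, None] + drift[:, None, None] + jitter
    sza_anom_true = drift[:, None, None] + jitter  # deviation from drift-free SZA

    delta_per_day = {
        band: np.array([
            inject.delta_true.get(epochs.epochs[k].sensor_id, {}).get(band, 0.0)
            for k in ep_idx
        ])
        for band in ("red", "nir")
    }

    met_resp = {}
    for band in ("red", "nir"):
        resp = np.zeros((nt, nlat, nlon), dtype=np.float32)
        coef = inject.met_response[band]
        for var, c in coef.items():
            if c == 0.0:
                continue
            resp += np.float32(c) * _met_anomaly_per_day(met, dates, var).astype(np.float32)
        met_resp[band] = resp

    valid_d = rng.random((nt, nlat, nlon)) >= inject.gap_probability
    obs_d = {}
    for band in ("red", "nir"):
        obs = (
            truth_ref[band].astype(np.float64)
            + inject.a1_true[band] * sza_anom_true
            + delta_per_day[band][:, None, None]
            + met_resp[band]
            + rng.normal(0.0, inject.noise_sd, (nt, nlat, nlon))
        )
        obs_d[band] = np.where(valid_d, obs, np.nan).astype(np.float32)
    sza_d = np.where(valid_d, sza_drifting, np.nan).astype(np.float32)
    drifting = SensorStream(dates, obs_d["red"], obs_d["nir"], sza_d, valid_d, ep_idx)

    # --- reference stream -------------------------------------------------
    ref_sel = np.array([d >= reference_start for d in dates])
    ref_dates = dates[ref_sel]
    ntr = len(ref_dates)
    valid_r = rng.random((ntr, nlat, nlon)) >= inject.gap_probability
    jitter_r = rng.normal(0.0, inject.sza_jitter_sd, (ntr, nlat, nlon))
    sza_r = sza_base[ref_sel][:, :, None] + jitter_r
    obs_r = {}
    for band in ("red", "nir"):
        obs = (
            truth_ref[band][ref_sel].astype(np.float64)
            + rng.normal(0.0, inject.noise_sd, (ntr, nlat, nlon))
        )
        obs_r[band] = np.where(valid_r, obs, np.nan).astype(np.float32)
    sza_r = np.where(valid_r, sza_r, np.nan).astype(np.float32)
    reference = SensorStream(
        ref_dates, obs_r["red"], obs_r["nir"], sza_r, valid_r,
        np.full(ntr, -1, dtype=int),
    )

    return DailyScene(grid, truth, inject, epochs, met, drifting, reference,
                      reference_start)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def simulate_covariates(
    grid: GridSpec,
    start_year: int,
    n_years: int,
    seed: int,
) -> xr.Dataset:
    """Biweekly meteorological covariates plus static elevation / aridity.

    Ta and Rad follow smooth seasonal cycles (northern-hemisphere July
    peak for rows at positive latitude); P, AOD, SD and CC are stochastic;
    ELE and AI are static spatial fields.
    """
    rng = np.random.default_rng(seed)
    periods = periods_list(start_year, n_years)
    nt = len(periods)
    nlat, nlon = grid.shape
    doy = np.array([p.mid.timetuple().tm_yday for p in periods], dtype=float)
    lat = grid.lat_centers
    hemi = np.where(lat >= 0, 1.0, -1.0)  # seasonal phase flips in the south

    seas = np.cos(2 * np.pi * (doy[:, None] - 200.0) / 365.0) * hemi[None, :]
    ta = (
        18.0 - 0.4 * np.abs(lat)[None, :] + 10.0 * seas
    )[:, :, None] + rng.normal(0, 1.5, (nt, nlat, nlon))
    rad = (
        180.0 + 90.0 * seas
    )[:, :, None] + rng.normal(0, 25.0, (nt, nlat, nlon))
    rad = np.clip(rad, 10.0, None)
    p = rng.gamma(2.0, 10.0, (nt, nlat, nlon))
    aod = np.clip(0.2 + rng.normal(0, 0.06, (nt, nlat, nlon)), 0.01, None)
    cold = ta < 0
    sd = np.where(cold, rng.gamma(1.5, 0.05, (nt, nlat, nlon)), 0.0)
    cc = np.clip(0.5 + rng.normal(0, 0.12, (nt, nlat, nlon)), 0.0, 1.0)

    gy, gx = np.meshgrid(np.linspace(0, 1, nlat), np.linspace(0, 1, nlon), indexing="ij")
    ele = 400.0 + 1500.0 * np.abs(np.sin(2 * gy + 1) * np.cos(3 * gx)) \
        + rng.normal(0, 30.0, (nlat, nlon))
    ai = np.clip(0.3 + 2.0 * gx + rng.normal(0, 0.1, (nlat, nlon)), 0.05, None)

    units = {"ta": "degC", "p": "mm", "rad": "W m-2", "aod": "1",
             "sd": "m", "cc": "1", "ele": "m", "ai": "1"}
    return make_dataset(
        grid, periods,
        {"ta": ta, "p": p, "rad": rad, "aod": aod, "sd": sd, "cc": cc,
         "ele": ele, "ai": ai},
        attrs={"title": "synthetic meteorological covariates", "seed": str(seed)},
        units=units,
    )


# ---------------------------------------------------------------------------
# SIF soundings
# ---------------------------------------------------------------------------

def simulate_soundings(
    truth: SurfaceTruthModel,
    sif: SifTruthModel,
    start: dt.date,
    end: dt.date,
    seed: int,
    swath_width: int = 8,
    cell_probability: float = 0.6,
    mean_soundings: float = 8.0,
    flag_fail_fraction: float = 0.25,
) -> pd.DataFrame:
    """Point soundings of SIF at a nominal 13:36 local overpass.

    Each day one random contiguous block of ``swath_width`` columns is
    overflown; cells inside it receive soundings with probability
    ``cell_probability`` and counts 1 + Poisson(mean_soundings - 1), so cell
    counts vary as for a real sparse sampler.  A configurable fraction of
    soundings fails the quality/cloud/mode screening.
    """
    rng = np.random.default_rng(seed)
    grid = truth.grid
    nlat, nlon = grid.shape
    dates = _date_range(start, end)
    rows_out: list[pd.DataFrame] = []
    for d in dates:
        c0 = rng.integers(0, max(nlon - swath_width, 1))
        cols = np.arange(c0, min(c0 + swath_width, nlon))
        rr, cc = np.meshgrid(np.arange(nlat), cols, indexing="ij")
        rr, cc = rr.ravel(), cc.ravel()
        hit = rng.random(rr.size) < cell_probability
        rr, cc = rr[hit], cc[hit]
        if rr.size == 0:
            continue
        counts = 1 + rng.poisson(max(mean_soundings - 1.0, 0.0), rr.size)
        rr = np.repeat(rr, counts)
        cc = np.repeat(cc, counts)
        doy = d.timetuple().tm_yday
        mu = cos_sza(grid.lat_centers[rr], doy, _OVERPASS_LST)
        ref = truth.reflectance(np.array([d], dtype=object))
        red = ref["red"][0][rr, cc]
        nirv = ref["nir"][0][rr, cc]
        sif_true = sif.evaluate(red, nirv, mu)
        sif_obs = sif_true + rng.normal(0.0, sif.noise_sd, rr.size)
        fails = rng.random(rr.size) < flag_fail_fraction
        which = rng.integers(0, 3, rr.size)
        rows_out.append(pd.DataFrame({
            "lat": grid.lat_centers[rr],
            "lon": grid.lon_centers[cc],
            "row": rr, "col": cc,
            "date": [d] * rr.size,
            "sif_757": sif_obs,
            "sif_true": sif_true,
            "sza": np.rad2deg(np.arccos(np.clip(mu, -1, 1))),
            "red": red, "nir": nirv,
            "quality_flag": np.where(fails & (which == 0), "bad", "best"),
            "mode_flag": np.where(fails & (which == 1), "glint", "nadir"),
            "cloud_flag": np.where(fails & (which == 2), "cloudy", "clear"),
        }))
    return pd.concat(rows_out, ignore_index=True)


# ---------------------------------------------------------------------------
# site GPP
# ---------------------------------------------------------------------------

DEFAULT_GPP_ALPHA = {
    "NF": 9.0, "EBF": 11.0, "DBF": 10.0, "MF": 9.5, "SH": 6.0,
    "SAV": 7.0, "GRA": 8.0, "CRO": 12.0, "PICS": 0.5,
}


def simulate_site_gpp(
    truth: SurfaceTruthModel,
    sif: SifTruthModel,
    sites: list[tuple[int, int]],
    start: dt.date,
    end: dt.date,
    seed: int,
    alpha_by_class: dict[str, float] | None = None,
    noise_sd: float = 0.8,
    bad_period_fraction: float = 0.2,
) -> pd.DataFrame:
    """Daily site GPP = alpha(land cover) * SIF_true_daily + noise, with a
    per-day QC fraction drawn so that roughly ``bad_period_fraction`` of
    biweekly periods fall below the 0.7 mean-QC screening threshold."""
    rng = np.random.default_rng(seed)
    alpha_by_class = alpha_by_class or DEFAULT_GPP_ALPHA
    grid = truth.grid
    dates = _date_range(start, end)
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
    ref = truth.reflectance(dates)
    out = []
    for si, (r, c) in enumerate(sites):
        lc = str(truth.landcover[r, c])
        alpha = alpha_by_class[lc]
        mu_daily = daily_mean_cos_sza(
            np.full(len(dates), grid.lat_centers[r]), doy)
        sif_true = sif.evaluate(ref["red"][:, r, c], ref["nir"][:, r, c], 1.0) \
            * np.asarray(mu_daily)
        gpp = alpha * sif_true + rng.normal(0.0, noise_sd, len(dates))
        # per-period base quality, inherited by days with small scatter
        pkeys = np.array([biweekly_index_of(d) for d in dates], dtype=object)
        qc = np.empty(len(dates))
        for pk in sorted(set(pkeys)):
            sel = pkeys == pk
            good = rng.random() >= bad_period_fraction
            base = rng.uniform(0.78, 1.0) if good else rng.uniform(0.2, 0.62)
            qc[sel] = np.clip(base + rng.uniform(-0.05, 0.05, sel.sum()), 0, 1)
        out.append(pd.DataFrame({
            "site": f"S{si:03d}", "row": r, "col": c, "landcover": lc,
            "date": dates, "gpp": gpp, "sif_true": sif_true, "qc": qc,
        }))
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# the default study scene
# ---------------------------------------------------------------------------

@dataclass
class SceneConfig:
    """The default synthetic study conditions.

    A 40x40-pixel, 16-year scene observed by a lineage of three sensors:
    two drifting epochs with inter-sensor offsets and SZA drift ramps up to
    +10 degrees, then a stable (reference) epoch; a drift-free reference
    stream covers the last 6 years.  10 calibration + 10 held-out PICS.
    """

    n_lat: int = 40
    n_lon: int = 40
    cell_size: float = 0.05
    lat_max: float = 42.0
    lon_min: float = 0.0
    start_year: int = 1982
    n_years: int = 16
    epoch_bounds: tuple[int, ...] = (5, 13)  # years after start at which sensors switch
    drift_max: tuple[float, ...] = (10.0, 8.0, 0.0)     # degrees per epoch
    delta_red: tuple[float, ...] = (0.04, 0.02, 0.0)    # per-epoch offsets
    delta_nir: tuple[float, ...] = (-0.04, -0.02, 0.0)
    a1_red: float = 0.0012   # reflectance per degree of SZA anomaly
    a1_nir: float = 0.0015
    noise_sd: float = 0.005
    gap_probability: float = 0.35
    n_pics_cal: int = 10
    n_pics_val: int = 10
    reference_overlap_years: int = 6

    def grid(self) -> GridSpec:
        return GridSpec.from_bounds(self.lat_max, self.lon_min,
                                    self.n_lat, self.n_lon, self.cell_size)

    def epoch_table(self) -> SensorEpochTable:
        y0 = self.start_year
        bounds = (0,) + self.epoch_bounds + (self.n_years,)
        names = [f"N{7 + 2 * i:02d}" for i in range(len(bounds) - 2)] + ["MetOpB"]
        eps = []
        for k in range(len(bounds) - 1):
            last = k == len(bounds) - 2
            eps.append(SensorEpoch(
                sensor_id=names[k],
                start=dt.date(y0 + bounds[k], 1, 1),
                end=dt.date(y0 + bounds[k + 1] - 1, 12, 31),
                drifts=not last,
                reference=last,
            ))
        return SensorEpochTable(eps)

    def injection(self) -> ArtifactInjection:
        tab = self.epoch_table()
        ids = [e.sensor_id for e in tab.epochs]
        return ArtifactInjection(
            sza_drift_max={s: d for s, d in zip(ids, self.drift_max)},
            a1_true={"red": self.a1_red, "nir": self.a1_nir},
            delta_true={
                s: {"red": dr, "nir": dn}
                for s, dr, dn in zip(ids, self.delta_red, self.delta_nir)
            },
            noise_sd=self.noise_sd,
            gap_probability=self.gap_probability,
        )

    @property
    def reference_start(self) -> dt.date:
        return dt.date(self.start_year + self.n_years - self.reference_overlap_years, 1, 1)


@dataclass
class Scene:
    config: SceneConfig
    daily: DailyScene
    pics_cal: list[tuple[int, int]]
    pics_val: list[tuple[int, int]]

    @property
    def grid(self) -> GridSpec:
        return self.daily.grid

    @property
    def truth(self) -> SurfaceTruthModel:
        return self.daily.truth


def simulate_scene(config: SceneConfig | None = None, seed: int = 0) -> Scene:
    """Generate the full default scene: truth, covariates, both streams."""
    config = config or SceneConfig()
    grid = config.grid()
    rng = np.random.default_rng(seed)
    n_pics = config.n_pics_cal + config.n_pics_val
    flat = rng.choice(grid.n_cells, size=n_pics, replace=False)
    pics = [(int(i // grid.shape[1]), int(i % grid.shape[1])) for i in flat]
    truth = SurfaceTruthModel.random(grid, seed=int(rng.integers(2**31)),
                                     pics_pixels=pics, base_year=config.start_year)
    met = simulate_covariates(grid, config.start_year, config.n_years,
                              seed=int(rng.integers(2**31)))
    daily = simulate_daily_reflectance(
        truth, config.injection(), config.epoch_table(), met,
        seed=int(rng.integers(2**31)), reference_start=config.reference_start,
    )
    return Scene(config, daily, pics[:config.n_pics_cal], pics[config.n_pics_cal:])
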