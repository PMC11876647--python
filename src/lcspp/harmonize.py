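"""Orbital-drift and inter-sensor bias removal for the drifting stream.

Stage 1 of the calibration chain.  A proxy of inter-sensor bias, delta, is
derived from bright pseudo-invariant calibration sites (PICS): the PICS-mean
reflectance series minus the mean seasonal cycle of the stable reference
epoch.  Then, per pixel, per period-of-year and per band, reflectance
anomalies are regressed by OLS on

    [SZA anomaly, delta, Ta anomaly, P anomaly, Rad anomaly, 1]

and only the SZA and delta contributions are removed (the meteorology-
explained anomalies are real surface signal and are retained).  The
correction applies to the drifting (NOAA-era) epochs only; the stable
reference-like epoch is passed through untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .grids import PERIODS_PER_YEAR

logger = logging.getLogger(__name__)

__all__ = [
    "PicsBiasSeries",
    "SzaBiasModel",
    "compute_pics_bias",
    "fit_sza_bias_model",
    "remove_sza_bias",
]

BANDS = ("red", "nir")
_REGRESSORS = ("sza_anom", "delta", "ta_anom", "p_anom", "rad_anom", "intercept")


@dataclass
class PicsBiasSeries:
    """Per-time-step inter-sensor bias proxy and the reference seasonal cycle."""

    delta: dict[str, np.ndarray]      # band -> (nt,)
    msc_ref: dict[str, np.ndarray]    # band -> (24,), reference-epoch cycle
    pics_mean: dict[str, np.ndarray]  # band -> (nt,), PICS-averaged series
    reference_epoch: int


@dataclass
class SzaBiasModel:
    """OLS coefficients per band x period-of-year x pixel.

    coef arrays have shape (24, nlat, nlon, 6) ordered as
    (a1 sza, a2 delta, a3 Ta, a4 P, a5 Rad, b).
    """

    coef: dict[str, np.ndarray]
    fitted: dict[str, np.ndarray]       # (24, nlat, nlon) bool
    n_obs: dict[str, np.ndarray]
    r2: dict[str, np.ndarray]
    sza_clim: np.ndarray                # (24, nlat, nlon)
    rho_clim: dict[str, np.ndarray]     # (24, nlat, nlon)
    min_n: int
    dropped_delta: dict[str, int] = field(default_factory=dict)


def _is_reference_step(cube: xr.Dataset, reference_epoch: int) -> np.ndarray:
    return cube["sensor"].values == reference_epoch


def compute_pics_bias(
    cube: xr.Dataset,
    pics_pixels: list[tuple[int, int]],
    reference_epoch: int,
) -> PicsBiasSeries:
    """Inter-sensor bias proxy delta(t) = PICS_mean(t) - MSC_ref(period-of-year).

    MSC_ref is the mean seasonal cycle of the PICS-averaged reflectance over
    the reference-epoch time steps.  Raises if any period-of-year is never
    observed in the reference epoch.
    """
    if not pics_pixels:
        raise ValueError("pics_pixels must be non-empty")
    rows = np.array([p[0] for p in pics_pixels])
    cols = np.array([p[1] for p in pics_pixels])
    poy = cube["poy"].values
    ref_steps = _is_reference_step(cube, reference_epoch)
    if not ref_steps.any():
        raise ValueError("reference epoch not present in the record")

    delta, msc_ref, pics_mean = {}, {}, {}
    for band in BANDS:
        series = np.nanmean(cube[band].values[:, rows, cols], axis=1)
        msc = np.full(PERIODS_PER_YEAR, np.nan)
        for p in range(1, PERIODS_PER_YEAR + 1):
            sel = ref_steps & (poy == p) & np.isfinite(series)
            if sel.any():
                msc[p - 1] = series[sel].mean()
        missing = [p + 1 for p in range(PERIODS_PER_YEAR) if not np.isfinite(msc[p])]
        if missing:
            raise ValueError(
                f"reference epoch never observes period(s)-of-year {missing} "
                f"for band {band}; MSC undefined there"
            )
        delta[band] = series - msc[poy - 1]
        msc_ref[band] = msc
        pics_mean[band] = series
    return PicsBiasSeries(delta, msc_ref, pics_mean, reference_epoch)


def _poy_climatology(values: np.ndarray, poy: np.ndarray, steps: np.ndarray) -> np.ndarray:
    """(24, ...) per-period-of-year mean over the selected time steps."""
    out = np.full((PERIODS_PER_YEAR,) + values.shape[1:], np.nan)
    for p in range(1, PERIODS_PER_YEAR + 1):
        sel = steps & (poy == p)
        if sel.any():
            with np.errstate(invalid="ignore"):
                out[p - 1] = np.nanmean(values[sel], axis=0)
    return out


def fit_sza_bias_model(
    cube: xr.Dataset,
    delta: PicsBiasSeries,
    met: xr.Dataset,
    min_n: int = 8,
    anomalize: bool = True,
) -> SzaBiasModel:
    """Fit, per pixel / period-of-year / band, the OLS of reflectance
    anomalies on [SZA anomaly, delta, Ta, P, Rad, intercept].

    Fitting uses the drifting (non-reference) epochs only.  Pixels/periods
    with fewer than ``min_n`` valid composites are left unfitted and
    flagged.  Rank-deficient designs (delta effectively constant) are refit
    without the delta column and counted in ``dropped_delta``.

    With ``anomalize=False`` the inputs are used as-is (no climatology
    subtraction) — the construction used by exact-recovery tests.
    """
    poy = cube["poy"].values
    drifting = ~_is_reference_step(cube, delta.reference_epoch)
    nlat = cube.sizes["lat"]
    nlon = cube.sizes["lon"]
    npix = nlat * nlon

    sza = cube["sza"].values.astype(float)
    sza_clim = _poy_climatology(sza, poy, drifting) if anomalize else \
        np.zeros((PERIODS_PER_YEAR, nlat, nlon))

    met_vals = {}
    for var in ("ta", "p", "rad"):
        v = met[var].values.astype(float)
        clim = _poy_climatology(v, met["poy"].values, np.ones(v.shape[0], bool)) \
            if anomalize else np.zeros((PERIODS_PER_YEAR,) + v.shape[1:])
        met_vals[var] = v - clim[met["poy"].values - 1]

    coef, fitted, n_obs_d, r2_d, rho_clim, dropped = {}, {}, {}, {}, {}, {}
    for band in BANDS:
        rho = cube[band].values.astype(float)
        clim = _poy_climatology(rho, poy, drifting) if anomalize else \
            np.zeros((PERIODS_PER_YEAR, nlat, nlon))
        rho_clim[band] = clim
        dvec = delta.delta[band]

        c = np.full((PERIODS_PER_YEAR, nlat, nlon, 6), np.nan)
        fit = np.zeros((PERIODS_PER_YEAR, nlat, nlon), dtype=bool)
        nobs = np.zeros((PERIODS_PER_YEAR, nlat, nlon), dtype=np.int32)
        r2 = np.full((PERIODS_PER_YEAR, nlat, nlon), np.nan)
        n_dropped = 0

        for p in range(1, PERIODS_PER_YEAR + 1):
            tsel = drifting & (poy == p)
            if not tsel.any():
                continue
            y = (rho[tsel] - clim[p - 1][None]).reshape(-1, npix).T     # (npix, ny)
            x_sza = (sza[tsel] - sza_clim[p - 1][None]).reshape(-1, npix).T
            x_d = np.broadcast_to(dvec[tsel][None, :], x_sza.shape)
            x_met = [met_vals[v][tsel].reshape(-1, npix).T for v in ("ta", "p", "rad")]
            ones = np.ones_like(x_sza)
            X = np.stack([x_sza, x_d, *x_met, ones], axis=-1)           # (npix, ny, 6)

            ok = np.isfinite(y) & np.isfinite(X).all(axis=-1)
            w = ok.astype(float)
            n = w.sum(axis=1)
            nobs[p - 1] = n.reshape(nlat, nlon)
            can = n >= min_n
            if not can.any():
                continue
            Xw = np.where(ok[..., None], X, 0.0)
            yw = np.where(ok, y, 0.0)
            # scale columns to unit rms so the conditioning check reflects
            # collinearity, not the wildly different regressor units
            scale = np.sqrt(np.einsum("pij,pij->pj", Xw, Xw)
                            / np.maximum(n, 1)[:, None])
            scale[scale <= 0] = 1.0
            Xs = Xw / scale[:, None, :]
            xtx = np.einsum("pij,pik->pjk", Xs, Xs)
            xty = np.einsum("pij,pi->pj", Xs, yw)
            beta = np.full((npix, 6), np.nan)
            # well-conditioned fits in one batched solve; degenerate ones
            # individually, dropping the delta column
            with np.errstate(all="ignore"):
                cond = np.linalg.cond(xtx)
            good = can & np.isfinite(cond) & (cond < 1e10)
            if good.any():
                beta[good] = np.linalg.solve(
                    xtx[good], xty[good][..., None])[..., 0] / scale[good]
            for i in np.nonzero(can & ~good)[0]:
                keep = [0, 2, 3, 4, 5]
                sub = xtx[i][np.ix_(keep, keep)]
                try:
                    b_sub = np.linalg.lstsq(sub, xty[i][keep], rcond=None)[0]
                except np.linalg.LinAlgError:
                    continue
                beta[i, keep] = b_sub / scale[i, keep]
                beta[i, 1] = 0.0
                n_dropped += 1
            pred = np.einsum("pij,pj->pi", Xw, np.where(np.isfinite(beta), beta, 0.0))
            resid = np.where(ok, y - pred, 0.0)
            ybar = np.divide(yw.sum(axis=1), np.maximum(n, 1))
            sst = (np.where(ok, y - ybar[:, None], 0.0) ** 2).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                r2_p = 1.0 - (resid ** 2).sum(axis=1) / sst
            done = can & np.isfinite(beta).all(axis=1)
            c[p - 1][done.reshape(nlat, nlon)] = beta[done]
            fit[p - 1] = done.reshape(nlat, nlon)
            r2[p - 1][done.reshape(nlat, nlon)] = r2_p[done]

        coef[band] = c
        fitted[band] = fit
        n_obs_d[band] = nobs
        r2_d[band] = r2
        dropped[band] = n_dropped
        if n_dropped:
            logger.info("band %s: dropped collinear delta column in %d fits",
                        band, n_dropped)

    return SzaBiasModel(coef, fitted, n_obs_d, r2_d, sza_clim, rho_clim,
                        min_n, dropped)


def remove_sza_bias(
    cube: xr.Dataset,
    model: SzaBiasModel,
    delta: PicsBiasSeries,
) -> xr.Dataset:
    """Corrected reflectance rho' = rho - a1*SZA_anom - a2*delta.

    Applied to drifting-epoch time steps only; reference-epoch steps and
    unfitted pixels pass through unchanged (flagged in ``<band>_corrected``).
    """
    poy = cube["poy"].values
    drifting = ~_is_reference_step(cube, delta.reference_epoch)
    out = cube.copy(deep=True)
    sza_anom = cube["sza"].values.astype(float) - model.sza_clim[poy - 1]
    for band in BANDS:
        rho = cube[band].values.astype(float)
        a1 = model.coef[band][poy - 1, :, :, 0]
        a2 = model.coef[band][poy - 1, :, :, 1]
        fit = model.fitted[band][poy - 1]
        corr = a1 * sza_anom + a2 * delta.delta[band][:, None, None]
        apply = fit & drifting[:, None, None] & np.isfinite(corr)
        out[band] = (("time", "lat", "lon"),
                     np.where(apply, rho - corr, rho).astype(cube[band].dtype))
        out[f"{band}_corrected"] = (("time", "lat", "lon"), apply)
    return out
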