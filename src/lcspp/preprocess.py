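"""Daily-observation preprocessing: BRDF normalization, QC screening,
exclusion windows, and biweekly maximum-value compositing (MVC).

The BRDF model is the kernel-driven RossThick / LiSparse-Reciprocal pair
used operationally for nadir BRDF-adjusted reflectance:

    rho(geom) = f_iso + f_vol * K_RossThick(geom) + f_geo * K_LiSparseR(geom)

with the LiSparseR shape constants h/b = 2 and b/r = 1.  Compositing selects,
for every pixel and half-month period, the valid day maximizing
NDVI = (NIR - red)/(NIR + red) and carries that day's red, NIR, SZA and
sensor id into the composite (ties broken by earliest date).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import xarray as xr

from .grids import BiweeklyIndex, biweekly_index_of
from .io import make_dataset
from .synthetic import SensorStream

logger = logging.getLogger(__name__)

__all__ = [
    "ViewGeometry",
    "STANDARD_GEOMETRY",
    "kernel_ross_thick",
    "kernel_li_sparse_r",
    "brdf_reflectance",
    "QC_BITS",
    "qc_filter",
    "apply_exclusion_windows",
    "composite_mvc",
]


# ---------------------------------------------------------------------------
# BRDF kernels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ViewGeometry:
    sza: float  # degrees
    vza: float
    raa: float

    def __post_init__(self) -> None:
        if not (0 <= self.sza < 90 and 0 <= self.vza < 90):
            raise ValueError("sza and vza must be in [0, 90)")
        if not 0 <= self.raa < 360:
            raise ValueError("raa must be in [0, 360)")


# standard normalization geometry: SZA 45, nadir view, zero relative azimuth
STANDARD_GEOMETRY = ViewGeometry(sza=45.0, vza=0.0, raa=0.0)

_HB = 2.0  # h/b of the LiSparse crown
_BR = 1.0  # b/r


def _phase_angle(ts, tv, phi):
    cos_xi = np.cos(ts) * np.cos(tv) + np.sin(ts) * np.sin(tv) * np.cos(phi)
    return np.arccos(np.clip(cos_xi, -1.0, 1.0))


def kernel_ross_thick(sza, vza, raa) -> np.ndarray:
    """RossThick volumetric kernel (Roujean normalization, zero at nadir sun
    and view)."""
    ts, tv, phi = (np.deg2rad(np.asarray(a, dtype=float)) for a in (sza, vza, raa))
    xi = _phase_angle(ts, tv, phi)
    return ((np.pi / 2 - xi) * np.cos(xi) + np.sin(xi)) / (np.cos(ts) + np.cos(tv)) - np.pi / 4


def kernel_li_sparse_r(sza, vza, raa) -> np.ndarray:
    """LiSparse-Reciprocal geometric kernel with h/b = 2, b/r = 1."""
    ts, tv, phi = (np.deg2rad(np.asarray(a, dtype=float)) for a in (sza, vza, raa))
    # adjust zenith angles for crown relative height/shape (b/r = 1 => no-op,
    # kept explicit for clarity with the standard formulation)
    tsp = np.arctan(_BR * np.tan(ts))
    tvp = np.arctan(_BR * np.tan(tv))
    xi = _phase_angle(tsp, tvp, phi)
    d = np.sqrt(
        np.tan(tsp) ** 2 + np.tan(tvp) ** 2
        - 2 * np.tan(tsp) * np.tan(tvp) * np.cos(phi)
    )
    sec_sum = 1.0 / np.cos(tsp) + 1.0 / np.cos(tvp)
    cos_t = _HB * np.sqrt(d ** 2 + (np.tan(tsp) * np.tan(tvp) * np.sin(phi)) ** 2) / sec_sum
    cos_t = np.clip(cos_t, -1.0, 1.0)
    t = np.arccos(cos_t)
    overlap = (1.0 / np.pi) * (t - np.sin(t) * cos_t) * sec_sum
    return overlap - sec_sum + 0.5 * (1.0 + np.cos(xi)) / (np.cos(tsp) * np.cos(tvp))


def brdf_reflectance(
    weights: Mapping[str, np.ndarray],
    geom: ViewGeometry = STANDARD_GEOMETRY,
) -> np.ndarray:
    """Kernel-driven reflectance f_iso + f_vol*K_vol + f_geo*K_geo.

    ``weights`` maps 'f_iso', 'f_vol', 'f_geo' to arrays (any shape).
    """
    k_vol = kernel_ross_thick(geom.sza, geom.vza, geom.raa)
    k_geo = kernel_li_sparse_r(geom.sza, geom.vza, geom.raa)
    return (
        np.asarray(weights["f_iso"], dtype=float)
        + np.asarray(weights["f_vol"], dtype=float) * k_vol
        + np.asarray(weights["f_geo"], dtype=float) * k_geo
    )


# ---------------------------------------------------------------------------
# QC screening
# ---------------------------------------------------------------------------

QC_BITS = {
    "cloud": 1, "snow": 2, "night": 4, "water": 8,
    "polar": 16, "bad_brdf": 32, "invalid": 64,
}


def qc_filter(
    red: np.ndarray,
    nir: np.ndarray,
    qc: np.ndarray,
    policy: Sequence[str] = ("cloud", "snow", "night", "water", "polar",
                             "bad_brdf", "invalid"),
) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """Mask cells whose QC bitmask fails any of the requested bits.

    Returns masked (red, nir) with NaN at failing cells and per-reason
    removal counts.
    """
    unknown = [b for b in policy if b not in QC_BITS]
    if unknown:
        raise ValueError(f"unknown QC bit names: {unknown}; known: {sorted(QC_BITS)}")
    qc = np.asarray(qc)
    bad = np.zeros(qc.shape, dtype=bool)
    counts = {}
    for name in policy:
        hit = (qc & QC_BITS[name]) != 0
        counts[name] = int(hit.sum())
        bad |= hit
    logger.info("qc_filter removals: %s", counts)
    red = np.where(bad, np.nan, red)
    nir = np.where(bad, np.nan, nir)
    return red, nir, counts


def apply_exclusion_windows(
    valid: np.ndarray,
    dates: Sequence[dt.date],
    windows: Sequence[tuple[dt.date, dt.date]],
) -> np.ndarray:
    """Clear the valid mask for all days inside any window (union semantics)."""
    valid = np.asarray(valid).copy()
    if not windows:
        return valid
    excluded = np.array(
        [any(w0 <= d <= w1 for (w0, w1) in windows) for d in dates]
    )
    valid[excluded] = False
    return valid


# ---------------------------------------------------------------------------
# maximum-value compositing
# ---------------------------------------------------------------------------

def composite_mvc(
    stream: SensorStream,
    grid,
    valid: np.ndarray | None = None,
) -> xr.Dataset:
    """Composite a daily stream to the biweekly grid by NDVI argmax.

    For each pixel and period, the valid day maximizing NDVI is selected and
    its red, NIR and SZA are carried into the composite (earliest day on
    ties; days with NIR + red == 0 are treated as invalid).  Periods with no
    valid day are NaN.  The per-period sensor index is the epoch observing
    the majority of the period's days.
    """
    valid = stream.valid if valid is None else valid
    dates = stream.dates
    keys = [biweekly_index_of(d) for d in dates]
    uperiods = sorted(set(keys))
    key_arr = np.array([(k.year, k.ordinal) for k in keys])

    nlat, nlon = grid.shape
    nt = len(uperiods)
    out = {
        "red": np.full((nt, nlat, nlon), np.nan, dtype=np.float32),
        "nir": np.full((nt, nlat, nlon), np.nan, dtype=np.float32),
        "sza": np.full((nt, nlat, nlon), np.nan, dtype=np.float32),
        "ndvi": np.full((nt, nlat, nlon), np.nan, dtype=np.float32),
        "n_valid_days": np.zeros((nt, nlat, nlon), dtype=np.float32),
    }
    sensor = np.full(nt, -1, dtype=np.int32)

    for i, p in enumerate(uperiods):
        sel = (key_arr[:, 0] == p.year) & (key_arr[:, 1] == p.ordinal)
        idx = np.nonzero(sel)[0]
        red = stream.red[idx].astype(np.float64)
        nir = stream.nir[idx].astype(np.float64)
        ok = valid[idx] & np.isfinite(red) & np.isfinite(nir)
        denom = nir + red
        ok &= denom != 0
        with np.errstate(invalid="ignore", divide="ignore"):
            ndvi = np.where(ok, (nir - red) / np.where(denom == 0, 1.0, denom), -np.inf)
        best = np.argmax(ndvi, axis=0)  # first occurrence wins ties
        any_ok = ok.any(axis=0)
        rows, cols = np.nonzero(any_ok)
        b = best[rows, cols]
        out["red"][i, rows, cols] = red[b, rows, cols]
        out["nir"][i, rows, cols] = nir[b, rows, cols]
        out["sza"][i, rows, cols] = stream.sza[idx][b, rows, cols]
        out["ndvi"][i, rows, cols] = ndvi[b, rows, cols]
        out["n_valid_days"][i] = ok.sum(axis=0)
        vals, counts = np.unique(stream.sensor_index[idx], return_counts=True)
        sensor[i] = vals[np.argmax(counts)]

    ds = make_dataset(grid, uperiods, out,
                      units={"red": "1", "nir": "1", "sza": "degree"})
    ds["sensor"] = ("time", sensor)
    return ds
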