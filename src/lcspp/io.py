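"""NetCDF I/O for gridded cubes.

All grids travel as :class:`xarray.Dataset` objects with dims
``(time, lat, lon)``, CF-style coordinates, float32 on disk / float64 in
computation, and NaN + ``_FillValue`` for missing cells.  The biweekly time
axis is carried both as the period start date (the ``time`` coordinate) and
as auxiliary integer coordinates ``year`` and ``poy`` (period-of-year 1..24)
plus the string coordinate ``half``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import xarray as xr

from .grids import BiweeklyIndex, GridSpec

logger = logging.getLogger(__name__)

__all__ = ["make_dataset", "read_cube", "write_cube", "write_product", "grid_of", "periods_of"]


def make_dataset(
    grid: GridSpec,
    periods: Sequence[BiweeklyIndex],
    data_vars: Mapping[str, np.ndarray],
    attrs: Mapping[str, str] | None = None,
    units: Mapping[str, str] | None = None,
) -> xr.Dataset:
    """Assemble a (time, lat, lon) dataset on the package grid convention."""
    time = np.array([np.datetime64(p.start, "ns") for p in periods])
    coords = {
        "time": ("time", time),
        "lat": ("lat", grid.lat_centers, {"units": "degrees_north"}),
        "lon": ("lon", grid.lon_centers, {"units": "degrees_east"}),
        "year": ("time", np.array([p.year for p in periods], dtype=np.int32)),
        "poy": ("time", np.array([p.ordinal for p in periods], dtype=np.int32)),
        "half": ("time", np.array([p.half for p in periods])),
    }
    shape = (len(periods),) + grid.shape
    dvars = {}
    for name, arr in data_vars.items():
        arr = np.asarray(arr)
        if arr.shape != shape and arr.shape != grid.shape:
            raise ValueError(
                f"variable {name!r} has shape {arr.shape}, expected {shape} or {grid.shape}"
            )
        dims = ("time", "lat", "lon") if arr.shape == shape else ("lat", "lon")
        var_attrs = {}
        if units and name in units:
            var_attrs["units"] = units[name]
        dvars[name] = (dims, arr, var_attrs)
    ds = xr.Dataset(dvars, coords=coords, attrs=dict(attrs or {}))
    ds.attrs.setdefault("Conventions", "CF-1.8")
    ds.attrs.setdefault("cell_size", grid.cell_size)
    return ds


def grid_of(ds: xr.Dataset) -> GridSpec:
    """Infer the GridSpec of a dataset (after coordinate normalization)."""
    lat = ds["lat"].values
    lon = ds["lon"].values
    if lat.size > 1:
        cell = float(abs(lat[1] - lat[0]))
    elif lon.size > 1:
        cell = float(lon[1] - lon[0])
    else:
        cell = float(ds.attrs.get("cell_size", 0.05))
    return GridSpec(lat, lon, cell)


def periods_of(ds: xr.Dataset) -> list[BiweeklyIndex]:
    """Recover the BiweeklyIndex sequence of a dataset's time axis."""
    return [
        BiweeklyIndex(int(y), (int(p) + 1) // 2, "a" if int(p) % 2 == 1 else "b")
        for y, p in zip(ds["year"].values, ds["poy"].values)
    ]


def _normalize_coords(ds: xr.Dataset) -> xr.Dataset:
    for axis in ("lat", "lon"):
        if axis not in ds.coords:
            raise ValueError(f"malformed coordinates: missing axis {axis!r}")
        vals = ds[axis].values
        if vals.ndim != 1:
            raise ValueError(f"malformed coordinates: axis {axis!r} is not 1-D")
        if vals.size > 1:
            d = np.diff(vals)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError(f"malformed coordinates: axis {axis!r} is not monotonic")
    if ds["lat"].size > 1 and ds["lat"].values[0] < ds["lat"].values[-1]:
        ds = ds.isel(lat=slice(None, None, -1))
    if ds["lon"].size > 1 and ds["lon"].values[0] > ds["lon"].values[-1]:
        ds = ds.isel(lon=slice(None, None, -1))
    return ds


def read_cube(path: str | Path, variables: Sequence[str] | None = None) -> xr.Dataset:
    """Read a cube, normalizing latitude to descending / longitude ascending.

    Raises ``KeyError`` listing the available variables if a requested one is
    absent, and ``ValueError`` naming the offending axis for malformed
    coordinates.
    """
    ds = xr.open_dataset(path).load()
    ds = _normalize_coords(ds)
    if variables is not None:
        missing = [v for v in variables if v not in ds.data_vars]
        if missing:
            raise KeyError(
                f"variables {missing} not in file; available: {sorted(ds.data_vars)}"
            )
        ds = ds[list(variables)]
    return ds


def _encoding(ds: xr.Dataset) -> dict:
    enc = {}
    for name, var in ds.data_vars.items():
        if np.issubdtype(var.dtype, np.floating):
            enc[name] = {"dtype": "float32", "_FillValue": np.float32(np.nan)}
    return enc


def write_cube(ds: xr.Dataset, path: str | Path) -> Path:
    """Write one cube to NetCDF (float32 on disk, NaN fill)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ds.to_netcdf(path, encoding=_encoding(ds))
    return path


def write_product(
    ds: xr.Dataset,
    directory: str | Path,
    prefix: str = "LCSPP",
    overwrite: bool = False,
) -> list[Path]:
    """Write one NetCDF file per biweekly period: <prefix>_<YYYYMM><a|b>.nc."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    periods = periods_of(ds)
    paths = []
    for i, period in enumerate(periods):
        path = directory / f"{prefix}_{period.label}.nc"
        if path.exists() and not overwrite:
            raise FileExistsError(
                f"{path} exists; pass overwrite=True to replace product files"
            )
        step = ds.isel(time=[i])
        step.to_netcdf(path, encoding=_encoding(step))
        paths.append(path)
    n_months = len({(p.year, p.month) for p in periods})
    if len(paths) != 2 * n_months:
        logger.warning(
            "partial months at record edges: wrote %d files for %d months",
            len(paths), n_months,
        )
    return paths
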