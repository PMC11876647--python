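"""Spatial grid and biweekly-calendar conventions shared by every stage.

The product grid is a regular geographic grid with cell-center registration,
latitude stored descending (+90 -> -90) and longitude ascending (-180 -> 180),
so that area weights are simply cos(latitude of the cell center).

Time is discretized into 24 half-month ("biweekly") periods per year: period
"a" of a month covers days 1-15, period "b" covers day 16 through the month
end.  The ordinal period-of-year runs 1..24.
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "GridSpec",
    "BiweeklyIndex",
    "biweekly_index_of",
    "period_date_range",
    "iter_periods",
    "PERIODS_PER_YEAR",
]

PERIODS_PER_YEAR = 24


@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon grid, cell-center registered.

    Parameters
    ----------
    lat_centers : array of latitudes in degrees, strictly descending.
    lon_centers : array of longitudes in degrees, strictly ascending.
    cell_size : grid spacing in degrees (uniform in both axes).
    """

    lat_centers: np.ndarray
    lon_centers: np.ndarray
    cell_size: float = 0.05

    def __post_init__(self) -> None:
        lat = np.asarray(self.lat_centers, dtype=float)
        lon = np.asarray(self.lon_centers, dtype=float)
        object.__setattr__(self, "lat_centers", lat)
        object.__setattr__(self, "lon_centers", lon)
        if lat.ndim != 1 or lon.ndim != 1:
            raise ValueError("lat_centers and lon_centers must be 1-D")
        if lat.size > 1:
            steps = np.diff(lat)
            if not np.all(steps < 0):
                raise ValueError("lat_centers must be strictly descending")
            if not np.allclose(-steps, self.cell_size, rtol=1e-6):
                raise ValueError("lat spacing does not match cell_size")
        if lon.size > 1:
            steps = np.diff(lon)
            if not np.all(steps > 0):
                raise ValueError("lon_centers must be strictly ascending")
            if not np.allclose(steps, self.cell_size, rtol=1e-6):
                raise ValueError("lon spacing does not match cell_size")

    @classmethod
    def from_bounds(
        cls,
        lat_max: float,
        lon_min: float,
        n_lat: int,
        n_lon: int,
        cell_size: float = 0.05,
    ) -> "GridSpec":
        """Grid whose north/west outer edges are at (lat_max, lon_min)."""
        lat0 = lat_max - cell_size / 2.0
        lon0 = lon_min + cell_size / 2.0
        lats = lat0 - cell_size * np.arange(n_lat)
        lons = lon0 + cell_size * np.arange(n_lon)
        return cls(lats, lons, cell_size)

    @property
    def shape(self) -> tuple[int, int]:
        return self.lat_centers.size, self.lon_centers.size

    @property
    def n_cells(self) -> int:
        return self.lat_centers.size * self.lon_centers.size

    def area_weights(self) -> np.ndarray:
        """Per-row area weights proportional to cos(latitude)."""
        return np.cos(np.deg2rad(self.lat_centers))


@dataclass(frozen=True, order=True)
class BiweeklyIndex:
    """One half-month compositing period."""

    year: int
    month: int
    half: str  # "a" (days 1-15) or "b" (day 16 .. month end)

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.half not in ("a", "b"):
            raise ValueError(f"half must be 'a' or 'b', got {self.half!r}")

    @property
    def ordinal(self) -> int:
        """Period-of-year, 1..24."""
        return 2 * (self.month - 1) + (1 if self.half == "a" else 2)

    @property
    def start(self) -> dt.date:
        return dt.date(self.year, self.month, 1 if self.half == "a" else 16)

    @property
    def end(self) -> dt.date:
        if self.half == "a":
            return dt.date(self.year, self.month, 15)
        last = calendar.monthrange(self.year, self.month)[1]
        return dt.date(self.year, self.month, last)

    @property
    def mid(self) -> dt.date:
        """Representative date of the period (midpoint, rounded down)."""
        return self.start + (self.end - self.start) // 2

    @property
    def label(self) -> str:
        """File-name style label, e.g. '198201a'."""
        return f"{self.year:04d}{self.month:02d}{self.half}"

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.label


def biweekly_index_of(date: dt.date) -> BiweeklyIndex:
    """Map a calendar date to its biweekly period (days 1-15 -> 'a')."""
    return BiweeklyIndex(date.year, date.month, "a" if date.day <= 15 else "b")


def period_date_range(period: BiweeklyIndex) -> list[dt.date]:
    """All calendar dates belonging to a period."""
    n = (period.end - period.start).days + 1
    return [period.start + dt.timedelta(days=i) for i in range(n)]


def iter_periods(start_year: int, n_years: int) -> Iterator[BiweeklyIndex]:
    """Yield the 24*n_years periods starting at January of start_year."""
    for year in range(start_year, start_year + n_years):
        for month in range(1, 13):
            for half in ("a", "b"):
                yield BiweeklyIndex(year, month, half)


def periods_list(start_year: int, n_years: int) -> list[BiweeklyIndex]:
    return list(iter_periods(start_year, n_years))


def period_ordinals(periods: Sequence[BiweeklyIndex]) -> np.ndarray:
    return np.array([p.ordinal for p in periods], dtype=int)


def period_years(periods: Sequence[BiweeklyIndex]) -> np.ndarray:
    return np.array([p.year for p in periods], dtype=int)
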