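"""Solar geometry and the three photosynthesis-proxy product layers.

The emulated-SIF product comes in three flavors:

* ``clear_inst``  — instantaneous clear-sky value at the nominal satellite
  overpass time (13:36 local solar time by default);
* ``clear_daily`` — daily-mean clear-sky value, obtained from ``clear_inst``
  by the ratio of the 24-h mean of max(cos SZA, 0) to cos SZA at overpass;
* ``all_daily``   — all-sky daily value, rescaling ``clear_inst`` by the
  ratio of the observed daily downward PAR to a modeled clear-sky
  instantaneous PAR.

Solar declination uses the Spencer truncated-Fourier series; the clear-sky
PAR model is a single-transmittance Beer-law atmosphere
``S0 * E0(doy) * cos(SZA) * tau**(1/cos(SZA)) * f_par``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SolarGeometryConfig",
    "ClearSkyParConfig",
    "solar_declination",
    "cos_sza",
    "daily_mean_cos_sza",
    "clear_daily_from_inst",
    "clear_sky_par_inst",
    "all_daily_from_inst",
]


@dataclass(frozen=True)
class SolarGeometryConfig:
    overpass_local_time: float = 13.6  # 13:36 local solar time, hours
    integration_step_minutes: float = 2.0

    def __post_init__(self) -> None:
        if (24 * 60) % self.integration_step_minutes != 0:
            raise ValueError("integration step must divide 24 h")


@dataclass(frozen=True)
class ClearSkyParConfig:
    solar_constant: float = 1361.0  # W m-2
    transmittance: float = 0.75     # broadband clear-sky, unitless
    par_fraction: float = 0.45      # PAR share of broadband shortwave

    def __post_init__(self) -> None:
        if not 0 < self.transmittance <= 1:
            raise ValueError("transmittance must be in (0, 1]")
        if not 0 < self.par_fraction < 1:
            raise ValueError("par_fraction must be in (0, 1)")


def solar_declination(doy) -> np.ndarray:
    """Solar declination (radians), Spencer truncated-Fourier series."""
    g = 2.0 * np.pi * (np.asarray(doy, dtype=float) - 1.0) / 365.0
    return (
        0.006918
        - 0.399912 * np.cos(g) + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g) + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g) + 0.00148 * np.sin(3 * g)
    )


def eccentricity_factor(doy) -> np.ndarray:
    """Sun-earth distance correction E0, Spencer series."""
    g = 2.0 * np.pi * (np.asarray(doy, dtype=float) - 1.0) / 365.0
    return (
        1.000110
        + 0.034221 * np.cos(g) + 0.001280 * np.sin(g)
        + 0.000719 * np.cos(2 * g) + 0.000077 * np.sin(2 * g)
    )


def cos_sza(lat, doy, local_solar_time) -> np.ndarray:
    """Cosine of the solar zenith angle; may be negative (sun below horizon).

    Parameters are broadcast against each other: latitude in degrees,
    day-of-year (1-based), local solar time in hours.
    """
    lat_r = np.deg2rad(np.asarray(lat, dtype=float))
    decl = solar_declination(doy)
    hour_angle = np.deg2rad((np.asarray(local_solar_time, dtype=float) - 12.0) * 15.0)
    return np.sin(lat_r) * np.sin(decl) + np.cos(lat_r) * np.cos(decl) * np.cos(hour_angle)


def daily_mean_cos_sza(lat, doy, config: SolarGeometryConfig | None = None) -> np.ndarray:
    """24-h mean of max(cos SZA, 0); exactly 0 in polar night."""
    config = config or SolarGeometryConfig()
    step_h = config.integration_step_minutes / 60.0
    # midpoint rule over the full day
    times = np.arange(step_h / 2.0, 24.0, step_h)
    lat_b = np.asarray(lat, dtype=float)[..., None]
    doy_b = np.asarray(doy, dtype=float)[..., None]
    c = cos_sza(lat_b, doy_b, times)
    out = np.clip(c, 0.0, None).mean(axis=-1)
    if np.ndim(lat) == 0 and np.ndim(doy) == 0:
        return float(out)
    return out


def clear_daily_from_inst(clear_inst, cos_sza_daily, cos_sza_inst) -> np.ndarray:
    """Daily clear-sky layer: clear_inst * cos_sza_daily / cos_sza_inst.

    Where the sun is below the horizon at overpass (cos_sza_inst <= 0) the
    product is defined as 0 (polar-winter rule).
    """
    clear_inst = np.asarray(clear_inst, dtype=float)
    cd = np.asarray(cos_sza_daily, dtype=float)
    ci = np.asarray(cos_sza_inst, dtype=float)
    ok = ci > 0
    out = np.where(ok, (clear_inst * cd) / np.where(ok, ci, 1.0), 0.0)
    return out


def clear_sky_par_inst(lat, doy, config: SolarGeometryConfig | None = None,
                       par_config: ClearSkyParConfig | None = None) -> np.ndarray:
    """Clear-sky top-of-canopy PAR (W m-2) at the overpass time.

    Beer-law single-transmittance atmosphere with air mass 1/cos(SZA);
    0 where the sun is below the horizon.
    """
    config = config or SolarGeometryConfig()
    par_config = par_config or ClearSkyParConfig()
    mu = np.asarray(cos_sza(lat, doy, config.overpass_local_time), dtype=float)
    e0 = eccentricity_factor(doy)
    tau = par_config.transmittance
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        air_mass = np.divide(1.0, mu, out=np.ones_like(mu), where=mu > 0)
        atm = np.where(mu > 0, tau ** air_mass, 0.0)
    out = par_config.solar_constant * e0 * np.clip(mu, 0.0, None) * atm * par_config.par_fraction
    return out


def all_daily_from_inst(clear_inst, par_clear_inst, par_daily) -> np.ndarray:
    """All-sky daily layer: clear_inst / par_clear_inst * par_daily.

    Where par_clear_inst == 0 with clear_inst > 0 the input is inconsistent;
    those cells are returned as NaN so the caller can flag them.
    """
    clear_inst = np.asarray(clear_inst, dtype=float)
    pc = np.asarray(par_clear_inst, dtype=float)
    pd_ = np.asarray(par_daily, dtype=float)
    shape = np.broadcast_shapes(clear_inst.shape, pc.shape, pd_.shape)
    ci, pc, pd_ = np.broadcast_to(clear_inst, shape), np.broadcast_to(pc, shape), np.broadcast_to(pd_, shape)
    out = np.zeros(shape)
    ok = pc > 0
    out[ok] = ci[ok] / pc[ok] * pd_[ok]
    bad = (~ok) & (ci > 0)
    out[bad] = np.nan
    return out
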