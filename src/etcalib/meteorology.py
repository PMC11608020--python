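"""Thermodynamic, radiative and unit-conversion primitives for daily ET0.

All vapour pressures are handled internally in kPa and wind speeds in
m s-1; the hPa / mmHg / miles-per-day dialects required by individual
mass-transfer formulations are produced only at model boundaries via
:func:`convert_pressure` and :func:`convert_wind_to_miles_per_day`.

Functions accept scalars or NumPy arrays and broadcast elementwise.
"""

from __future__ import annotations

import datetime
import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: Solar constant, MJ m-2 min-1.
SOLAR_CONSTANT = 0.0820
#: Stefan-Boltzmann constant on a daily basis, MJ K-4 m-2 day-1.
STEFAN_BOLTZMANN_DAILY = 4.903e-9
#: Albedo of the reference grass surface.
REFERENCE_ALBEDO = 0.23
#: Conversion factors out of the internal kPa representation.
HPA_PER_KPA = 10.0
MMHG_PER_KPA = 760.0 / 101.325  # 7.500617 mmHg per kPa
#: Statute mile, metres.  Configurable at the call site of the wind
#: conversion; the statute mile is the documented default.
METRES_PER_MILE = 1609.344
SECONDS_PER_DAY = 86400.0

_PRESSURE_FACTORS = {"hPa": HPA_PER_KPA, "mmHg": MMHG_PER_KPA, "kPa": 1.0}


def _check_finite(name: str, value) -> None:
    if not np.all(np.isfinite(value)):
        raise ValueError(f"{name} must be finite, got {value!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StationMeta:
    """Location metadata driving the radiation and pressure terms."""

    latitude: float
    elevation: float
    anemometer_height: float = 2.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not self.elevation > -430.0:
            raise ValueError(f"elevation out of range: {self.elevation}")
        if not self.anemometer_height > 0.0:
            raise ValueError(
                f"anemometer_height must be positive: {self.anemometer_height}"
            )


@dataclass(frozen=True)
class DailyWeatherRecord:
    """One day of measured meteorology at a station.

    Temperatures in deg C, relative humidities in percent, solar
    radiation in MJ m-2 day-1, wind speed at 2 m in m s-1.
    """

    date: datetime.date
    tmax: float
    tmin: float
    tmean: float
    rhmax: float
    rhmin: float
    rhmean: float
    rs: float
    u2: float

    def __post_init__(self) -> None:
        for name in ("tmax", "tmin", "tmean", "rhmax", "rhmin", "rhmean", "rs", "u2"):
            _check_finite(name, getattr(self, name))
        if not self.tmin <= self.tmean <= self.tmax:
            raise ValueError(
                f"{self.date}: require tmin <= tmean <= tmax, got "
                f"{self.tmin}/{self.tmean}/{self.tmax}"
            )
        if not 0.0 <= self.rhmin <= self.rhmean <= self.rhmax <= 100.0:
            raise ValueError(
                f"{self.date}: require 0 <= rhmin <= rhmean <= rhmax <= 100, got "
                f"{self.rhmin}/{self.rhmean}/{self.rhmax}"
            )
        if self.rs < 0.0:
            raise ValueError(f"{self.date}: rs must be >= 0, got {self.rs}")
        if self.u2 < 0.0:
            raise ValueError(f"{self.date}: u2 must be >= 0, got {self.u2}")

    @property
    def day_of_year(self) -> int:
        return self.date.timetuple().tm_yday


@dataclass(frozen=True)
class VapourPressures:
    """Saturation/actual vapour pressures and their deficit, kPa."""

    es_max: float
    es_min: float
    es: float
    ea: float
    vpd: float

    @classmethod
    def from_record(cls, record: DailyWeatherRecord) -> "VapourPressures":
        es_mx = saturation_vapour_pressure(record.tmax)
        es_mn = saturation_vapour_pressure(record.tmin)
        es = mean_saturation_vapour_pressure(record.tmax, record.tmin)
        ea = actual_vapour_pressure(
            record.tmax, record.tmin, record.rhmax, record.rhmin
        )
        return cls(
            es_max=float(es_mx),
            es_min=float(es_mn),
            es=float(es),
            ea=float(ea),
            vpd=float(vapour_pressure_deficit(es, ea)),
        )


@dataclass(frozen=True)
class PMInputs:
    """Energy-balance inputs of the combination equation."""

    delta: float  # slope of saturation curve, kPa degC-1
    gamma: float  # psychrometric constant, kPa degC-1
    rn: float  # net radiation, MJ m-2 day-1
    g: float = 0.0  # soil heat flux, MJ m-2 day-1 (0 at daily steps)

    def __post_init__(self) -> None:
        if not self.delta > 0.0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        if not self.gamma > 0.0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        _check_finite("rn", self.rn)
        _check_finite("g", self.g)


# ---------------------------------------------------------------------------
# Vapour pressure chain
# ---------------------------------------------------------------------------


def saturation_vapour_pressure(t):
    """Saturation vapour pressure (kPa) at air temperature ``t`` (deg C)."""
    t = np.asarray(t, dtype=float)
    _check_finite("t", t)
    if np.any(t <= -237.3):
        raise ValueError("temperature at or below -237.3 degC")
    out = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    return out if out.ndim else float(out)


def mean_saturation_vapour_pressure(tmax, tmin):
    """Mean of the saturation vapour pressures at tmax and tmin, kPa."""
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    if np.any(tmin > tmax):
        raise ValueError("tmin exceeds tmax")
    out = (saturation_vapour_pressure(tmax) + saturation_vapour_pressure(tmin)) / 2.0
    return out if np.ndim(out) else float(out)


def actual_vapour_pressure(tmax, tmin, rhmax, rhmin):
    """Actual vapour pressure (kPa) from temperature and humidity extremes.

    Pairs RHmax with the saturation pressure at Tmin and RHmin with the
    saturation pressure at Tmax.
    """
    rhmax = np.asarray(rhmax, dtype=float)
    rhmin = np.asarray(rhmin, dtype=float)
    if np.any((rhmax < 0) | (rhmax > 100) | (rhmin < 0) | (rhmin > 100)):
        raise ValueError("relative humidity outside [0, 100]")
    out = (
        saturation_vapour_pressure(tmin) * rhmax / 100.0
        + saturation_vapour_pressure(tmax) * rhmin / 100.0
    ) / 2.0
    return out if np.ndim(out) else float(out)


def vapour_pressure_deficit(es, ea):
    """VPD = es - ea, kPa.  Negative values are propagated with a warning."""
    es = np.asarray(es, dtype=float)
    ea = np.asarray(ea, dtype=float)
    if np.any(es < 0) or np.any(ea < 0):
        raise ValueError("vapour pressures must be >= 0")
    out = es - ea
    if np.any(out < 0):
        logger.warning(
            "negative vapour pressure deficit encountered (ea > es); "
            "value propagated, not clipped"
        )
    return out if out.ndim else float(out)


def slope_saturation_curve(tmean):
    """Slope of the saturation vapour pressure curve at tmean, kPa degC-1."""
    tmean = np.asarray(tmean, dtype=float)
    out = 4098.0 * saturation_vapour_pressure(tmean) / (tmean + 237.3) ** 2
    return out if out.ndim else float(out)


def atmospheric_pressure(elevation):
    """Atmospheric pressure (kPa) at ``elevation`` metres above sea level."""
    z = np.asarray(elevation, dtype=float)
    out = 101.3 * ((293.0 - 0.0065 * z) / 293.0) ** 5.26
    return out if out.ndim else float(out)


def psychrometric_constant(elevation):
    """Psychrometric constant (kPa degC-1) from station elevation."""
    out = 0.000665 * np.asarray(atmospheric_pressure(elevation))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Radiation chain
# ---------------------------------------------------------------------------


def extraterrestrial_radiation(latitude, day_of_year):
    """Daily extraterrestrial radiation Ra, MJ m-2 day-1."""
    doy = np.asarray(day_of_year, dtype=float)
    if np.any((doy < 1) | (doy > 366)):
        raise ValueError("day_of_year outside [1, 366]")
    phi = math.radians(latitude)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    decl = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    cos_ws = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    ws = np.arccos(cos_ws)
    out = (
        24.0 * 60.0 / np.pi
        * SOLAR_CONSTANT
        * dr
        * (ws * np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.sin(ws))
    )
    out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)


def clear_sky_radiation(latitude, day_of_year, elevation):
    """Clear-sky solar radiation Rso, MJ m-2 day-1."""
    ra = np.asarray(extraterrestrial_radiation(latitude, day_of_year))
    out = (0.75 + 2e-5 * elevation) * ra
    return out if out.ndim else float(out)


def net_radiation(rs, tmax, tmin, ea, station: StationMeta, day_of_year,
                  albedo: float = REFERENCE_ALBEDO):
    """Net radiation Rn = Rns - Rnl at the reference surface, MJ m-2 day-1.

    The relative shortwave ratio rs/Rso is capped at 1.0 for robustness
    against measurement noise.  Raises if rs > 0 while Rso = 0 (polar
    night cannot receive shortwave radiation).
    """
    rs = np.asarray(rs, dtype=float)
    if np.any(rs < 0):
        raise ValueError("rs must be >= 0")
    rso = np.asarray(clear_sky_radiation(station.latitude, day_of_year,
                                         station.elevation))
    if np.any((rso <= 0) & (rs > 0)):
        raise ValueError("rs > 0 with zero clear-sky radiation (polar night)")
    rns = (1.0 - albedo) * rs
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rso > 0, np.minimum(rs / np.where(rso > 0, rso, 1.0), 1.0), 0.0)
    tmax_k4 = (np.asarray(tmax, dtype=float) + 273.16) ** 4
    tmin_k4 = (np.asarray(tmin, dtype=float) + 273.16) ** 4
    rnl = (
        STEFAN_BOLTZMANN_DAILY
        * (tmax_k4 + tmin_k4) / 2.0
        * (0.34 - 0.14 * np.sqrt(np.asarray(ea, dtype=float)))
        * (1.35 * ratio - 0.35)
    )
    out = rns - rnl
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Unit conversions and wind profile
# ---------------------------------------------------------------------------


def convert_pressure(value, target: str):
    """Convert a pressure from kPa to ``target`` ('hPa', 'mmHg' or 'kPa')."""
    if target not in _PRESSURE_FACTORS:
        raise ValueError(
            f"unknown pressure unit {target!r}; expected one of "
            f"{sorted(_PRESSURE_FACTORS)}"
        )
    value = np.asarray(value, dtype=float)
    _check_finite("value", value)
    out = value * _PRESSURE_FACTORS[target]
    return out if out.ndim else float(out)


def convert_wind_to_miles_per_day(u, metres_per_mile: float = METRES_PER_MILE):
    """Convert wind speed from m s-1 to miles day-1 (statute mile default)."""
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("wind speed must be >= 0")
    out = u * SECONDS_PER_DAY / metres_per_mile
    return out if out.ndim else float(out)


def wind_at_2m(uz, measurement_height: float):
    """Adjust wind measured at ``measurement_height`` (m) to 2 m.

    Uses the standard logarithmic profile; pass-through when the
    anemometer already sits at 2 m.
    """
    if measurement_height <= 0:
        raise ValueError("measurement height must be positive")
    uz = np.asarray(uz, dtype=float)
    if measurement_height == 2.0:
        out = uz
    else:
        out = uz * 4.87 / np.log(67.8 * measurement_height - 5.42)
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------


def sample_skewness(values) -> float:
    """Adjusted Fisher-Pearson skewness (spreadsheet-compatible).

    [n / ((n-1)(n-2))] * sum(((x - mean) / s)^3) with s the sample
    (ddof=1) standard deviation.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 values, got {n}")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("zero variance: skewness undefined")
    return float(n / ((n - 1) * (n - 2)) * np.sum(((x - x.mean()) / s) ** 3))
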