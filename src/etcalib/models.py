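"""Daily ET0 estimators: FAO-56 Penman-Monteith and six mass-transfer models.

Each mass-transfer model declares its unit dialect in a :class:`ModelSpec`
and the dispatcher :func:`estimate_et0` converts from the internal
kPa / m s-1 representation; callers never pre-convert.  This is the single
biggest implementation trap of the model family: vapour pressure deficit is
expected in hPa by most models but in mmHg by Rohwer and Penman, and Penman
additionally takes wind in miles per day.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import meteorology as met
from .meteorology import DailyWeatherRecord, PMInputs, StationMeta, VapourPressures

logger = logging.getLogger(__name__)

REFERENCE_MODEL = "fao56pm"


@dataclass(frozen=True)
class ModelSpec:
    """Identity and unit dialect of an ET0 estimator."""

    model_id: str
    vpd_unit: str  # 'hPa', 'mmHg' or 'n/a'
    wind_unit: str  # 'm_s', 'miles_day' or 'n/a'


MODEL_SPECS: dict[str, ModelSpec] = {
    "fao56pm": ModelSpec("fao56pm", vpd_unit="kPa", wind_unit="m_s"),
    "dalton": ModelSpec("dalton", vpd_unit="hPa", wind_unit="m_s"),
    "rohwer": ModelSpec("rohwer", vpd_unit="mmHg", wind_unit="m_s"),
    "penman": ModelSpec("penman", vpd_unit="mmHg", wind_unit="miles_day"),
    "romanenko": ModelSpec("romanenko", vpd_unit="n/a", wind_unit="n/a"),
    "wmo": ModelSpec("wmo", vpd_unit="hPa", wind_unit="m_s"),
    "mahringer": ModelSpec("mahringer", vpd_unit="hPa", wind_unit="m_s"),
}

#: The six calibratable mass-transfer models, in deterministic order.
MASS_TRANSFER_MODELS: tuple[str, ...] = tuple(
    sorted(m for m in MODEL_SPECS if m != REFERENCE_MODEL)
)


def get_model_spec(model_id: str) -> ModelSpec:
    try:
        return MODEL_SPECS[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model_id {model_id!r}; known models: {sorted(MODEL_SPECS)}"
        ) from None


# ---------------------------------------------------------------------------
# Series container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ET0Series:
    """Dated daily ET0 values (mm day-1) labelled by estimation method."""

    dates: tuple[datetime.date, ...]
    values: np.ndarray
    method: str
    variant: str = "original"  # 'original' | 'modified' | 'reference'

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "dates", tuple(self.dates))
        if len(self.dates) != values.size:
            raise ValueError("dates and values must have equal length")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValueError("dates must be strictly increasing")

    def __len__(self) -> int:
        return len(self.dates)

    def to_pandas(self) -> pd.Series:
        return pd.Series(
            self.values, index=pd.DatetimeIndex(self.dates), name=self.method
        )

    @classmethod
    def from_pandas(cls, series: pd.Series, method: str,
                    variant: str = "original") -> "ET0Series":
        dates = tuple(ts.date() for ts in pd.DatetimeIndex(series.index))
        return cls(dates=dates, values=series.to_numpy(dtype=float),
                   method=method, variant=variant)

    def with_values(self, values, variant: str | None = None) -> "ET0Series":
        return replace(self, values=np.asarray(values, dtype=float),
                       variant=self.variant if variant is None else variant)


def aligned_values(a: ET0Series, b: ET0Series) -> tuple[np.ndarray, np.ndarray]:
    """Return the value arrays of two series after checking date alignment."""
    if a.dates != b.dates:
        raise ValueError(
            f"series are not date-aligned ({a.method}/{a.variant} vs "
            f"{b.method}/{b.variant})"
        )
    return a.values, b.values


# ---------------------------------------------------------------------------
# Core equations
# ---------------------------------------------------------------------------


def et0_fao56_pm(pm: PMInputs, tmean, u2, es, ea):
    """FAO-56 Penman-Monteith daily reference evapotranspiration, mm day-1.

    ET0 = [0.408 * delta * (Rn - G)
           + gamma * (900 / (T + 273)) * u2 * (es - ea)]
          / [delta + gamma * (1 + 0.34 * u2)]
    """
    u2 = np.asarray(u2, dtype=float)
    if np.any(u2 < 0):
        raise ValueError("u2 must be >= 0")
    for name, v in (("tmean", tmean), ("es", es), ("ea", ea)):
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite {name}")
    num = (
        0.408 * pm.delta * (pm.rn - pm.g)
        + pm.gamma * (900.0 / (np.asarray(tmean, dtype=float) + 273.0))
        * u2 * (np.asarray(es, dtype=float) - np.asarray(ea, dtype=float))
    )
    den = pm.delta + pm.gamma * (1.0 + 0.34 * u2)
    out = num / den
    return out if np.ndim(out) else float(out)


def et0_dalton(u2, vpd_hpa):
    """Dalton: (0.3648 + 0.07223 * u2) * VPD, with VPD in hPa."""
    _check_wind(u2)
    out = (0.3648 + 0.07223 * np.asarray(u2, dtype=float)) * np.asarray(
        vpd_hpa, dtype=float)
    return out if np.ndim(out) else float(out)


def et0_rohwer(u2, vpd_mmhg):
    """Rohwer: 0.44 * (1 + 0.27 * u2) * VPD, with VPD in mmHg."""
    _check_wind(u2)
    out = 0.44 * (1.0 + 0.27 * np.asarray(u2, dtype=float)) * np.asarray(
        vpd_mmhg, dtype=float)
    return out if np.ndim(out) else float(out)


def et0_penman(u2_miles, vpd_mmhg):
    """Penman: 0.35 * (1 + 0.98/100 * u2) * VPD, wind in miles day-1, VPD in mmHg."""
    _check_wind(u2_miles)
    out = 0.35 * (1.0 + 0.98 / 100.0 * np.asarray(u2_miles, dtype=float)) * np.asarray(
        vpd_mmhg, dtype=float)
    return out if np.ndim(out) else float(out)


def et0_romanenko(tmean, rhmean):
    """Romanenko: 0.00006 * (T + 25)^2 * (100 - RH); T degC, RH percent."""
    rh = np.asarray(rhmean, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("rhmean outside [0, 100]")
    out = 0.00006 * (np.asarray(tmean, dtype=float) + 25.0) ** 2 * (100.0 - rh)
    return out if np.ndim(out) else float(out)


def et0_wmo(u2, vpd_hpa):
    """WMO: (0.1298 + 0.0934 * u2) * VPD, with VPD in hPa."""
    _check_wind(u2)
    out = (0.1298 + 0.0934 * np.asarray(u2, dtype=float)) * np.asarray(
        vpd_hpa, dtype=float)
    return out if np.ndim(out) else float(out)


def et0_mahringer(u2, vpd_hpa):
    """Mahringer: 0.15072 * sqrt(3.60 * u2) * VPD, with VPD in hPa."""
    _check_wind(u2)
    out = 0.15072 * np.sqrt(3.60 * np.asarray(u2, dtype=float)) * np.asarray(
        vpd_hpa, dtype=float)
    return out if np.ndim(out) else float(out)


def _check_wind(u) -> None:
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("wind speed must be >= 0")
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite wind speed")


def apply_linear_calibration(et0_raw, a: float, b: float):
    """Apply the modified-equation mapping a * et0 + b, elementwise.

    Linearity means monthly means transform identically, so the mapping
    commutes with averaging.  Negative outputs are propagated with a
    logged warning, never clipped.
    """
    for name, v in (("et0_raw", et0_raw), ("a", a), ("b", b)):
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite {name}")
    out = a * np.asarray(et0_raw, dtype=float) + b
    if np.any(out < 0):
        logger.warning("calibrated ET0 went negative; value propagated")
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# Dispatch from internal units
# ---------------------------------------------------------------------------


def estimate_et0(model_id: str, *, tmean=None, rhmean=None, u2=None,
                 vpd_kpa=None):
    """Evaluate a mass-transfer model from internal-unit inputs.

    ``vpd_kpa`` is in kPa and ``u2`` in m s-1; the model's declared
    dialect conversions are applied here.  Romanenko ignores wind and VPD
    and uses ``tmean`` / ``rhmean`` only.
    """
    spec = get_model_spec(model_id)
    if model_id == REFERENCE_MODEL:
        raise ValueError("use et0_fao56_pm for the reference model")
    if model_id == "romanenko":
        if tmean is None or rhmean is None:
            raise ValueError("romanenko requires tmean and rhmean")
        return et0_romanenko(tmean, rhmean)
    if u2 is None or vpd_kpa is None:
        raise ValueError(f"{model_id} requires u2 and vpd_kpa")
    vpd = met.convert_pressure(vpd_kpa, spec.vpd_unit)
    wind = (met.convert_wind_to_miles_per_day(u2)
            if spec.wind_unit == "miles_day" else u2)
    fn = {
        "dalton": et0_dalton,
        "rohwer": et0_rohwer,
        "penman": et0_penman,
        "wmo": et0_wmo,
        "mahringer": et0_mahringer,
    }[model_id]
    return fn(wind, vpd)


# ---------------------------------------------------------------------------
# Record-level drivers
# ---------------------------------------------------------------------------


def reference_series(records: Sequence[DailyWeatherRecord], station: StationMeta,
                     soil_heat_flux: float = 0.0) -> ET0Series:
    """FAO-56 PM daily ET0 series for a run of weather records."""
    dates, values = [], []
    for rec in records:
        vp = VapourPressures.from_record(rec)
        pm = PMInputs(
            delta=met.slope_saturation_curve(rec.tmean),
            gamma=met.psychrometric_constant(station.elevation),
            rn=met.net_radiation(rec.rs, rec.tmax, rec.tmin, vp.ea, station,
                                 rec.day_of_year),
            g=soil_heat_flux,
        )
        dates.append(rec.date)
        values.append(et0_fao56_pm(pm, rec.tmean, rec.u2, vp.es, vp.ea))
    return ET0Series(dates=tuple(dates), values=np.array(values),
                     method=REFERENCE_MODEL, variant="reference")


def model_series(records: Sequence[DailyWeatherRecord], model_id: str) -> ET0Series:
    """Original-equation daily ET0 series of one mass-transfer model."""
    get_model_spec(model_id)  # fail loudly before any computation
    dates, values = [], []
    for rec in records:
        vp = VapourPressures.from_record(rec)
        dates.append(rec.date)
        values.append(
            estimate_et0(model_id, tmean=rec.tmean, rhmean=rec.rhmean,
                         u2=rec.u2, vpd_kpa=vp.vpd)
        )
    return ET0Series(dates=tuple(dates), values=np.array(values),
                     method=model_id, variant="original")


def calibrated_series(series: ET0Series, a: float, b: float) -> ET0Series:
    """Modified-equation series obtained from an original series."""
    return ET0Series(
        dates=series.dates,
        values=np.asarray(apply_linear_calibration(series.values, a, b)),
        method=series.method,
        variant="modified",
    )
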