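"""Seeded synthetic daily weather with prescribed marginal statistics.

Generates one April-October season of :class:`DailyWeatherRecord` whose
pooled mean / standard deviation / skewness per variable approach
configurable targets.  Temperature and solar radiation follow deterministic
seasonal cycles plus skew-normal noise; the noise moments are obtained by
cumulant matching (third cumulants of independent components add), so the
pooled series - cycle plus noise - carries the requested variance and
skewness.  Wind speed is drawn from a shifted lognormal matched to
(mean, sd, skew) by moments; relative humidity is anti-correlated with
temperature.

Only marginal statistics are prescribed; the temperature-humidity
anti-correlation (default -0.5) is a modelling assumption needed for
realistic vapour pressure deficits, not a measured quantity.
"""

from __future__ import annotations

import datetime
import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import models as mdl
from .meteorology import (
    DailyWeatherRecord,
    StationMeta,
    clear_sky_radiation,
    sample_skewness,
)
from .models import ET0Series

logger = logging.getLogger(__name__)

#: Largest skewness a skew-normal distribution can represent (|delta| -> 1).
SKEW_NORMAL_MAX_SKEW = 0.9952
_SOLVER_TOL = 1e-8


@dataclass(frozen=True)
class VariableTargets:
    """Marginal statistics a generated variable should approach."""

    mean: float
    sd: float
    skew: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not self.min < self.max:
            raise ValueError(f"require min < max, got [{self.min}, {self.max}]")
        if not self.sd > 0:
            raise ValueError(f"sd must be > 0, got {self.sd}")
        if not self.min < self.mean < self.max:
            raise ValueError(
                f"infeasible targets: mean {self.mean} outside "
                f"({self.min}, {self.max})"
            )


# Default targets: semi-arid high-plateau April-October climatology
# (daily means over nine pooled seasons).
DEFAULT_TMEAN_TARGETS = VariableTargets(mean=16.42, sd=5.12, skew=-0.32,
                                        min=4.44, max=23.26)
DEFAULT_RHMEAN_TARGETS = VariableTargets(mean=53.98, sd=8.90, skew=0.49,
                                         min=39.83, max=75.39)
DEFAULT_RS_TARGETS = VariableTargets(mean=20.15, sd=3.53, skew=-0.32,
                                     min=11.88, max=24.88)
DEFAULT_U2_TARGETS = VariableTargets(mean=2.65, sd=0.77, skew=1.41,
                                     min=1.48, max=6.30)
DEFAULT_STATION = StationMeta(latitude=38.4667, elevation=1669.0)


@dataclass(frozen=True)
class WeatherGenConfig:
    """Configuration of :func:`generate_season`."""

    start: datetime.date = datetime.date(2012, 4, 1)
    end: datetime.date = datetime.date(2012, 10, 31)
    tmean: VariableTargets = DEFAULT_TMEAN_TARGETS
    rhmean: VariableTargets = DEFAULT_RHMEAN_TARGETS
    rs: VariableTargets = DEFAULT_RS_TARGETS
    u2: VariableTargets = DEFAULT_U2_TARGETS
    station: StationMeta = DEFAULT_STATION
    # diurnal spans used to derive max/min from daily means
    temp_span_mean: float = 12.0
    temp_span_sd: float = 2.0
    rh_span_mean: float = 30.0
    rh_span_sd: float = 5.0
    # seasonal cycle of tmean: amplitude (degC) and calendar peak day
    tmean_amplitude: float = 7.5
    tmean_peak_doy: int = 203
    #: correlation imposed between rhmean and tmean (assumption, not data)
    rh_temp_corr: float = -0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end date before start date")
        if self.end.year != self.start.year:
            raise ValueError("season must lie within one calendar year")
        if not -1.0 < self.rh_temp_corr < 1.0:
            raise ValueError("rh_temp_corr must be in (-1, 1)")
        for name in ("temp_span_mean", "temp_span_sd", "rh_span_mean",
                     "rh_span_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# Skew-normal machinery
# ---------------------------------------------------------------------------


def skew_normal_parameters(mean: float, sd: float, skew: float
                           ) -> tuple[float, float, float]:
    """Location/scale/shape (xi, omega, alpha) matching (mean, sd, skew).

    Solved numerically for the shape delta; raises for skewness outside
    the representable range (|skew| >= ~0.9952).
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if abs(skew) >= SKEW_NORMAL_MAX_SKEW:
        raise ValueError(
            f"|skew| = {abs(skew)} not representable by a skew-normal"
        )
    if skew == 0.0:
        return mean, sd, 0.0

    def gamma1(delta: float) -> float:
        num = (4.0 - math.pi) / 2.0 * (delta * math.sqrt(2.0 / math.pi)) ** 3
        den = (1.0 - 2.0 * delta ** 2 / math.pi) ** 1.5
        return num / den

    target = abs(skew)
    delta = optimize.brentq(lambda d: gamma1(d) - target, 0.0, 1.0 - 1e-12,
                            xtol=_SOLVER_TOL)
    delta = math.copysign(delta, skew)
    omega = sd / math.sqrt(1.0 - 2.0 * delta ** 2 / math.pi)
    xi = mean - omega * delta * math.sqrt(2.0 / math.pi)
    alpha = delta / math.sqrt(1.0 - delta ** 2)
    return xi, omega, alpha


def _sample_skew_normal(rng: np.random.Generator, n: int, mean: float,
                        sd: float, skew: float) -> np.ndarray:
    if sd == 0.0:
        return np.full(n, mean)
    skew = float(np.clip(skew, -0.95, 0.95))
    xi, omega, alpha = skew_normal_parameters(mean, sd, skew)
    return stats.skewnorm.rvs(alpha, loc=xi, scale=omega, size=n,
                              random_state=rng)


def _cycle_plus_skew_noise(rng: np.random.Generator, cycle: np.ndarray,
                           targets: VariableTargets,
                           max_cycle_var_fraction: float = 0.75) -> np.ndarray:
    """Deterministic cycle plus skew-normal noise hitting pooled targets.

    The cycle is recentred on the target mean and, if necessary, shrunk so
    it leaves variance for the noise.  Noise variance and third moment are
    the residual cumulants after subtracting the cycle's.
    """
    c = cycle - cycle.mean()
    var_c = float(c.var())
    target_var = targets.sd ** 2
    if var_c > max_cycle_var_fraction * target_var:
        lam = math.sqrt(max_cycle_var_fraction * target_var / var_c)
        c = lam * c
        var_c = float(c.var())
    mu3_c = float(np.mean(c ** 3))
    var_n = target_var - var_c
    mu3_n = targets.skew * targets.sd ** 3 - mu3_c
    skew_n = mu3_n / var_n ** 1.5 if var_n > 0 else 0.0
    noise = _sample_skew_normal(rng, c.size, 0.0, math.sqrt(var_n), skew_n)
    # target min/max are soft descriptors; physical clipping is the caller's
    # responsibility so that the pooled moments stay on target
    return targets.mean + c + noise


def _shifted_lognormal(rng: np.random.Generator, n: int,
                       targets: VariableTargets) -> np.ndarray:
    """Right-skewed sample from a shifted lognormal matched by moments."""
    if targets.skew <= 0:
        raise ValueError("shifted lognormal requires positive skew")
    # skew = (w + 2) sqrt(w - 1) with w = exp(sigma^2)
    w = optimize.brentq(
        lambda w_: (w_ + 2.0) * math.sqrt(w_ - 1.0) - targets.skew,
        1.0 + 1e-12, 50.0, xtol=_SOLVER_TOL,
    )
    sigma = math.sqrt(math.log(w))
    scale_sq = targets.sd ** 2 / (w * (w - 1.0))  # exp(2 mu)
    mu = 0.5 * math.log(scale_sq)
    shift = targets.mean - math.exp(mu + sigma ** 2 / 2.0)
    draw = shift + rng.lognormal(mean=mu, sigma=sigma, size=n)
    return np.maximum(draw, 0.0)


# ---------------------------------------------------------------------------
# Season generation
# ---------------------------------------------------------------------------


def generate_season(config: WeatherGenConfig) -> list[DailyWeatherRecord]:
    """Generate one season of daily weather records.  Seed-deterministic."""
    rng = np.random.default_rng(config.seed)
    dates = pd.date_range(config.start, config.end, freq="D")
    doy = np.array([ts.timetuple().tm_yday for ts in dates], dtype=float)
    n = doy.size

    # --- daily mean temperature: sinusoidal cycle + skew-normal noise
    t_cycle = config.tmean_amplitude * np.cos(
        2.0 * np.pi * (doy - config.tmean_peak_doy) / 365.25
    )
    tmean = _cycle_plus_skew_noise(rng, t_cycle, config.tmean)

    # --- relative humidity anti-correlated with temperature
    rho = config.rh_temp_corr
    z_t = (tmean - tmean.mean()) / tmean.std()
    resid_sd = config.rhmean.sd * math.sqrt(1.0 - rho ** 2)
    resid_skew = config.rhmean.skew  # residual carries the marginal skew
    resid = _sample_skew_normal(rng, n, 0.0, resid_sd, resid_skew)
    rhmean = config.rhmean.mean + rho * config.rhmean.sd * z_t + resid
    rhmean = np.clip(rhmean, 0.0, 100.0)

    # --- solar radiation: clear-sky-shaped cycle + noise, capped at Rso
    rso = np.asarray(clear_sky_radiation(config.station.latitude, doy,
                                         config.station.elevation))
    rs_cycle = rso * (config.rs.mean / rso.mean())
    rs = _cycle_plus_skew_noise(rng, rs_cycle, config.rs,
                                max_cycle_var_fraction=0.6)
    rs = np.minimum(np.maximum(rs, 0.0), rso)

    # --- wind speed: shifted lognormal
    u2 = _shifted_lognormal(rng, n, config.u2)

    # --- diurnal spans -> max/min fields
    t_span = np.maximum(rng.normal(config.temp_span_mean, config.temp_span_sd,
                                   size=n), 0.1)
    rh_span = np.maximum(rng.normal(config.rh_span_mean, config.rh_span_sd,
                                    size=n), 0.1)
    tmax = tmean + t_span / 2.0
    tmin = tmean - t_span / 2.0
    rhmax = np.minimum(rhmean + rh_span / 2.0, 100.0)
    rhmin = np.maximum(rhmean - rh_span / 2.0, 0.0)

    records = [
        DailyWeatherRecord(
            date=dates[i].date(),
            tmax=float(tmax[i]), tmin=float(tmin[i]), tmean=float(tmean[i]),
            rhmax=float(rhmax[i]), rhmin=float(rhmin[i]),
            rhmean=float(rhmean[i]),
            rs=float(rs[i]), u2=float(u2[i]),
        )
        for i in range(n)
    ]
    return records


def generate_pooled_seasons(config: WeatherGenConfig, n_seasons: int
                            ) -> list[DailyWeatherRecord]:
    """Concatenate ``n_seasons`` seasons in consecutive years (sub-seeded)."""
    out: list[DailyWeatherRecord] = []
    for k in range(n_seasons):
        cfg = replace(
            config,
            start=config.start.replace(year=config.start.year + k),
            end=config.end.replace(year=config.end.year + k),
            seed=config.seed + k,
        )
        out.extend(generate_season(cfg))
    return out


# ---------------------------------------------------------------------------
# Paired truth for parameter-recovery tests
# ---------------------------------------------------------------------------


def generate_model_truth(records: Sequence[DailyWeatherRecord], model_id: str,
                         a: float, b: float, noise_sd: float, seed: int
                         ) -> tuple[ET0Series, ET0Series]:
    """Paired (reference, estimated) series with a known affine relation.

    ``estimated`` is the original model output on the records and
    ``reference`` = a * estimated + b + Gaussian(0, noise_sd), so a
    subsequent calibration fit should recover (a, b).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    estimated = mdl.model_series(records, model_id)
    rng = np.random.default_rng(seed)
    ref_values = a * estimated.values + b + rng.normal(0.0, noise_sd,
                                                       size=len(estimated))
    reference = ET0Series(dates=estimated.dates, values=ref_values,
                          method="synthetic", variant="reference")
    return reference, estimated


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

_SUMMARY_FIELDS = ("tmean", "rhmean", "rs", "u2")


def summary_statistics(records: Sequence[DailyWeatherRecord]) -> pd.DataFrame:
    """Per-variable mean / sd / skew / min / max of a record list."""
    if not records:
        raise ValueError("no records to summarise")
    rows = {}
    for name in _SUMMARY_FIELDS:
        x = np.array([getattr(r, name) for r in records], dtype=float)
        sd = float(x.std(ddof=1)) if x.size > 1 else float("nan")
        if x.size >= 3 and sd > 0:
            skew = sample_skewness(x)
        else:
            logger.warning("%s: skewness undefined (constant or short series)",
                           name)
            skew = float("nan")
        rows[name] = {
            "mean": float(x.mean()), "sd": sd, "skew": skew,
            "min": float(x.min()), "max": float(x.max()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")[
        ["mean", "sd", "skew", "min", "max"]
    ]
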