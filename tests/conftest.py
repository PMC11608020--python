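"""Shared fixtures and independent oracles.

The oracle functions here are deliberately written as straight-line
arithmetic, separate from the package implementations, so the two routes
can be compared in tests.
"""

from __future__ import annotations

import datetime
import math

import numpy as np
import pytest

from etcalib.meteorology import DailyWeatherRecord, StationMeta
from etcalib.synthetic import WeatherGenConfig, generate_season


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def oracle_net_radiation(rs, tmax, tmin, ea, latitude, elevation, doy):
    """Staged brute-force Ra -> Rso -> Rns -> Rnl -> Rn computation."""
    phi = math.radians(latitude)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    dec = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    ws = math.acos(max(-1.0, min(1.0, -math.tan(phi) * math.tan(dec))))
    ra = (24.0 * 60.0 / math.pi) * 0.0820 * dr * (
        ws * math.sin(phi) * math.sin(dec)
        + math.cos(phi) * math.cos(dec) * math.sin(ws)
    )
    ra = max(ra, 0.0)
    rso = (0.75 + 2e-5 * elevation) * ra
    rns = (1.0 - 0.23) * rs
    ratio = min(rs / rso, 1.0) if rso > 0 else 0.0
    rnl = (
        4.903e-9
        * ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4) / 2.0
        * (0.34 - 0.14 * math.sqrt(ea))
        * (1.35 * ratio - 0.35)
    )
    return rns - rnl


def oracle_fao56_pm(delta, gamma, rn, g, tmean, u2, es, ea):
    """Single-expression combination-equation oracle."""
    return (
        0.408 * delta * (rn - g)
        + gamma * (900.0 / (tmean + 273.0)) * u2 * (es - ea)
    ) / (delta + gamma * (1.0 + 0.34 * u2))


def oracle_grid_search_fit(x, y, iterations: int = 60, points: int = 41):
    """Dense iterative grid search minimising sum((y - (a*x + b))^2).

    Searches over (a, c) in the centred model y = a*(x - mean(x)) + c,
    where the SSE surface is axis-aligned, then maps c back to the
    intercept.  Purely enumerative: independent of the closed-form OLS
    path it is used to check.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    a_lo, a_hi = -10.0, 10.0
    c_lo, c_hi = -40.0, 40.0
    best = (0.0, 0.0)
    for _ in range(iterations):
        a_grid = np.linspace(a_lo, a_hi, points)
        c_grid = np.linspace(c_lo, c_hi, points)
        sse = ((y[None, None, :] - (a_grid[:, None, None] * xc[None, None, :]
                                    + c_grid[None, :, None])) ** 2).sum(axis=2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        best = (float(a_grid[i]), float(c_grid[j]))
        a_step = a_grid[1] - a_grid[0]
        c_step = c_grid[1] - c_grid[0]
        a_lo, a_hi = best[0] - 2 * a_step, best[0] + 2 * a_step
        c_lo, c_hi = best[1] - 2 * c_step, best[1] + 2 * c_step
    a, c = best
    return a, c - a * x.mean()


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def station() -> StationMeta:
    return StationMeta(latitude=38.4667, elevation=1669.0)


@pytest.fixture(scope="session")
def default_config() -> WeatherGenConfig:
    return WeatherGenConfig()


@pytest.fixture(scope="session")
def season_records(default_config) -> list[DailyWeatherRecord]:
    return generate_season(default_config)


@pytest.fixture
def toy_records() -> list[DailyWeatherRecord]:
    """Three hand-sized valid days."""
    return [
        DailyWeatherRecord(
            date=datetime.date(2020, 6, d), tmax=28.0 + d, tmin=12.0 + d,
            tmean=20.0 + d, rhmax=80.0, rhmin=35.0, rhmean=55.0,
            rs=22.0, u2=2.5,
        )
        for d in (1, 2, 3)
    ]
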