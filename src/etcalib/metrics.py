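"""Skill statistics (MAE, MAPE, RMSE, NSE, R2) and categorical accuracy bands.

Band conventions (half-open where the prose ranges overlap):

* MAPE: excellent [0, 10), good [10, 20), reasonable [20, 50], inaccurate (50, inf)
* NSE:  good (0.75, 1], satisfying [0.36, 0.75], less_satisfactory (-inf, 0.36)

Acceptability thresholds are strict inequalities: MAE < 0.52 mm day-1,
RMSE < 0.50 mm day-1, NSE > 0.75.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .models import ET0Series, aligned_values

MAE_ACCEPTABLE_LIMIT = 0.52  # mm day-1
RMSE_ACCEPTABLE_LIMIT = 0.50  # mm day-1
NSE_ACCEPTABLE_LIMIT = 0.75


@dataclass(frozen=True)
class MetricSet:
    """Five-statistic evaluation of one estimated series plus labels."""

    mae: float
    mape: float
    rmse: float
    nse: float
    r2: float
    mape_class: str
    nse_class: str
    acceptable_mae: bool
    acceptable_rmse: bool
    acceptable_nse: bool


def classify_mape(mape: float) -> str:
    """Accuracy band of a MAPE value (percent)."""
    if not np.isfinite(mape) or mape < 0:
        raise ValueError(f"MAPE must be finite and >= 0, got {mape}")
    if mape < 10.0:
        return "excellent"
    if mape < 20.0:
        return "good"
    if mape <= 50.0:
        return "reasonable"
    return "inaccurate"


def classify_nse(nse: float) -> str:
    """Accuracy band of a Nash-Sutcliffe efficiency."""
    if nse > 1.0:
        raise ValueError(f"NSE cannot exceed 1, got {nse}")
    if nse > 0.75:
        return "good"
    if nse >= 0.36:
        return "satisfying"
    return "less_satisfactory"


def _as_arrays(actual, estimated) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(actual, ET0Series) and isinstance(estimated, ET0Series):
        return aligned_values(actual, estimated)
    x = np.asarray(actual, dtype=float)
    y = np.asarray(estimated, dtype=float)
    if x.shape != y.shape:
        raise ValueError("actual and estimated must have equal length")
    return x, y


def evaluate(actual: Union[ET0Series, np.ndarray],
             estimated: Union[ET0Series, np.ndarray]) -> MetricSet:
    """Compute MAE, MAPE, RMSE, NSE and R2 of ``estimated`` against ``actual``.

    ``actual`` is the reference (X) and ``estimated`` the model (Y):
    MAE = mean|X-Y|, MAPE = mean|100 (X-Y)/X|, RMSE = sqrt(mean (X-Y)^2),
    NSE = 1 - sum (X-Y)^2 / sum (X - mean X)^2, and R2 is the squared
    Pearson correlation.
    """
    x, y = _as_arrays(actual, estimated)
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 paired values, got {n}")
    if np.any(x == 0.0):
        raise ValueError("actual series contains exact zeros: MAPE undefined")
    diff = x - y
    mae = float(np.mean(np.abs(diff)))
    mape = float(np.mean(np.abs(diff / x)) * 100.0)
    rmse = float(np.sqrt(np.mean(diff ** 2)))
    x_dev = x - x.mean()
    sxx = float(np.dot(x_dev, x_dev))
    if sxx == 0.0:
        raise ValueError("actual series has zero variance: NSE/R2 undefined")
    nse = float(1.0 - np.dot(diff, diff) / sxx)
    y_dev = y - y.mean()
    syy = float(np.dot(y_dev, y_dev))
    if syy == 0.0:
        raise ValueError("estimated series has zero variance: R2 undefined")
    r2 = float(np.dot(x_dev, y_dev) ** 2 / (sxx * syy))
    r2 = min(max(r2, 0.0), 1.0)
    return MetricSet(
        mae=mae, mape=mape, rmse=rmse, nse=nse, r2=r2,
        mape_class=classify_mape(mape),
        nse_class=classify_nse(nse),
        acceptable_mae=mae < MAE_ACCEPTABLE_LIMIT,
        acceptable_rmse=rmse < RMSE_ACCEPTABLE_LIMIT,
        acceptable_nse=nse > NSE_ACCEPTABLE_LIMIT,
    )


def acceptability_flags(m: MetricSet) -> dict[str, bool]:
    """Strict-inequality acceptability of a metric set."""
    return {
        "mae": m.mae < MAE_ACCEPTABLE_LIMIT,
        "rmse": m.rmse < RMSE_ACCEPTABLE_LIMIT,
        "nse": m.nse > NSE_ACCEPTABLE_LIMIT,
    }


def metrics_table(metric_sets: Mapping[str, MetricSet]) -> pd.DataFrame:
    """Tabulate metric sets by model with classification columns."""
    rows = []
    for model_id in sorted(metric_sets):
        m = metric_sets[model_id]
        rows.append({
            "model": model_id, "mae": m.mae, "mape": m.mape, "rmse": m.rmse,
            "nse": m.nse, "r2": m.r2, "mape_class": m.mape_class,
            "nse_class": m.nse_class, "acceptable_mae": m.acceptable_mae,
            "acceptable_rmse": m.acceptable_rmse,
            "acceptable_nse": m.acceptable_nse,
        })
    return pd.DataFrame(rows).set_index("model")
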