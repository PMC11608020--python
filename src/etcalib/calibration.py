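"""Least-squares fitting of the linear calibration coefficients (a, b).

The calibration maps each mass-transfer model's output onto the FAO-56 PM
reference: reference = a * estimated + b.  Ordinary least squares is the
closed-form solution of the sum-of-squared-errors objective that an
iterative spreadsheet solver would minimise, so it is used directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import ET0Series, MASS_TRANSFER_MODELS, aligned_values, get_model_spec


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted slope/intercept of one model with training diagnostics."""

    model_id: str
    a: float
    b: float
    n: int
    sse: float  # residual sum of squares, mm2 day-2
    r2: float  # squared Pearson correlation of the fit

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"{self.model_id}: need n >= 3, got {self.n}")
        if self.sse < 0:
            raise ValueError(f"{self.model_id}: sse must be >= 0")
        if not -1e-12 <= self.r2 <= 1 + 1e-12:
            raise ValueError(f"{self.model_id}: r2 out of [0, 1]: {self.r2}")


def fit_linear_calibration(actual: ET0Series, estimated: ET0Series) -> CalibrationResult:
    """OLS of ``actual`` (reference) on ``estimated`` (model output).

    Returns the (a, b) minimising sum((actual - (a*estimated + b))^2).
    """
    y, x = aligned_values(actual, estimated)
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 paired days, got {n}")
    x_dev = x - x.mean()
    sxx = float(np.dot(x_dev, x_dev))
    if sxx == 0.0:
        raise ValueError("estimated series has zero variance: degenerate fit")
    y_dev = y - y.mean()
    a = float(np.dot(x_dev, y_dev) / sxx)
    b = float(y.mean() - a * x.mean())
    resid = y - (a * x + b)
    sse = float(np.dot(resid, resid))
    syy = float(np.dot(y_dev, y_dev))
    r2 = float(np.dot(x_dev, y_dev) ** 2 / (sxx * syy)) if syy > 0 else 1.0
    return CalibrationResult(
        model_id=estimated.method, a=a, b=b, n=n, sse=sse,
        r2=min(max(r2, 0.0), 1.0),
    )


def calibrate_all_models(
    reference: ET0Series,
    estimates: Mapping[str, ET0Series],
    models: Sequence[str] = MASS_TRANSFER_MODELS,
) -> list[CalibrationResult]:
    """One :class:`CalibrationResult` per model, ordered by model_id."""
    results = []
    for model_id in sorted(models):
        get_model_spec(model_id)
        if model_id not in estimates:
            raise ValueError(f"missing estimated series for model {model_id!r}")
        results.append(fit_linear_calibration(reference, estimates[model_id]))
    return results


def coefficients_table(results: Sequence[CalibrationResult]) -> pd.DataFrame:
    """Plain table of the fitted coefficients (model, a, b, n, sse, r2)."""
    return pd.DataFrame(
        [
            {"model": r.model_id, "a": r.a, "b": r.b, "n": r.n,
             "sse": r.sse, "r2": r.r2}
            for r in results
        ]
    ).set_index("model")
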