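"""Stride-length error metrics.

Two metric blocks are used:

* a relative-error block — per-stride error percentage
  ``|actual − predicted| / |actual| × 100`` summarised by mean, SD, min
  and max, reported both as ratios (mean error 0.0778 style) and as
  percentages (7.78% style);
* an absolute block — MAE, MSE, RMSE = √MSE and the coefficient of
  determination R² = 1 − SS_res / SS_tot, with SS_tot about the mean of
  the actuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "MetricsReport",
    "error_percentage",
    "error_summary",
    "regression_metrics",
]


@dataclass
class MetricsReport:
    """Summary metrics; fields that are undefined for a block are None.

    ``r_squared`` is None (absent, not NaN) when the actuals have zero
    variance.
    """

    n: int
    mae: float | None = None
    sd_of_errors: float | None = None
    min_error: float | None = None
    max_error: float | None = None
    mse: float | None = None
    rmse: float | None = None
    r_squared: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def summary(self) -> str:
        lines = [f"n = {self.n}"]
        for key in ("mae", "sd_of_errors", "min_error", "max_error",
                    "mse", "rmse", "r_squared"):
            val = getattr(self, key)
            if val is not None:
                lines.append(f"{key:>14s} = {val:.6g}")
        return "\n".join(lines)


def error_percentage(actual: float, predicted: float) -> float:
    """Relative stride-length error: |actual − predicted| / |actual| × 100."""
    if actual == 0:
        raise ValueError("relative error undefined for actual = 0")
    return abs(actual - predicted) / abs(actual) * 100.0


def _check_pair(actuals, predictions) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actuals, dtype=float)
    p = np.asarray(predictions, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise ValueError("actuals and predictions must be 1-D with equal length")
    if len(a) == 0:
        raise ValueError("empty input")
    return a, p


def error_summary(
    actuals, predictions, population_sd: bool = False
) -> MetricsReport:
    """Mean / SD / min / max of per-stride relative errors, as ratios.

    SD uses the sample (n−1) denominator unless ``population_sd``; for a
    single stride the sample SD is reported as 0.
    """
    a, p = _check_pair(actuals, predictions)
    if np.any(a == 0):
        raise ValueError("relative error undefined for actual = 0")
    errs = np.abs(a - p) / np.abs(a)  # ratios, Table-style
    if len(errs) > 1:
        sd = float(np.std(errs, ddof=0 if population_sd else 1))
    else:
        sd = 0.0
    return MetricsReport(
        n=len(errs),
        mae=float(np.mean(errs)),
        sd_of_errors=sd,
        min_error=float(np.min(errs)),
        max_error=float(np.max(errs)),
    )


def regression_metrics(actuals, predictions) -> MetricsReport:
    """MAE, MSE, RMSE and R² of predictions against actuals (absolute units)."""
    a, p = _check_pair(actuals, predictions)
    resid = a - p
    mae = float(np.mean(np.abs(resid)))
    mse = float(np.mean(resid**2))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    r2 = None if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return MetricsReport(
        n=len(a), mae=mae, mse=mse, rmse=math.sqrt(mse), r_squared=r2
    )
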