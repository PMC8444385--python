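"""Relative growth rates and estimate-vs-ground-truth validation statistics.

The relative growth rate between two area measurements A1 (earlier) and A2
(later) separated by time t is

    RGR = (1/t) * ln(A2 / A1),

the specific (exponential) growth rate of area. RGR values are commonly
quoted as percentages of the ln-ratio: a week-to-week RGR of 56.9% means
ln(A2/A1) = 0.569 over one week, equivalently 56.9/7 = 8.1% per day.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GrowthSeries",
    "ValidationStats",
    "relative_growth_rate",
    "series_rgr",
    "validation_stats",
]


@dataclass
class GrowthSeries:
    """Longitudinal (time, area) observations for one plant."""

    plant_id: str
    times: np.ndarray  # days, strictly increasing
    areas: np.ndarray  # one-sided area, cm^2, > 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if len(self.times) != len(self.areas):
            raise ValueError("times and areas must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.areas <= 0):
            raise ValueError("areas must be positive")


@dataclass
class ValidationStats:
    """Agreement statistics between estimates and ground truth."""

    rmse: float
    mape: float  # percent
    spearman_rho: float
    slope: float
    intercept: float
    r_squared: float
    n: int


def relative_growth_rate(a1: float, a2: float, t: float) -> float:
    """RGR = (1/t) ln(a2/a1); multiply by 100 for the percent convention."""
    if a1 <= 0 or a2 <= 0:
        raise ValueError("areas must be positive")
    if t <= 0:
        raise ValueError("time interval must be positive")
    return math.log(a2 / a1) / t


def series_rgr(series: GrowthSeries, unit: str = "per_interval") -> np.ndarray:
    """One RGR per consecutive observation pair.

    ``per_interval`` returns ln(A2/A1) for each pair (the interval is the
    natural unit, e.g. week-to-week); ``per_day`` divides by the interval
    length in days.
    """
    if unit not in ("per_interval", "per_day"):
        raise ValueError(f"unknown unit {unit!r}")
    if len(series.times) < 2:
        warnings.warn("growth series has fewer than 2 observations",
                      stacklevel=2)
        return np.array([])
    log_ratio = np.diff(np.log(series.areas))
    if unit == "per_day":
        return log_ratio / np.diff(series.times)
    return log_ratio


def validation_stats(
    estimates: np.ndarray, ground_truth: np.ndarray
) -> ValidationStats:
    """RMSE, MAPE, Spearman rho and OLS regression of estimate on truth.

    MAPE requires strictly positive ground truth; Spearman uses average
    ranks for ties.
    """
    est = np.asarray(estimates, dtype=float)
    obs = np.asarray(ground_truth, dtype=float)
    if est.shape != obs.shape or est.ndim != 1:
        raise ValueError("estimates and ground truth must be equal-length vectors")
    if len(est) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.any(obs == 0):
        raise ValueError("ground truth must be nonzero for MAPE")
    rmse = float(np.sqrt(np.mean((est - obs) ** 2)))
    mape = float(100.0 * np.mean(np.abs((est - obs) / obs)))
    rho = float(stats.spearmanr(est, obs).statistic)
    reg = stats.linregress(obs, est)
    return ValidationStats(
        rmse=rmse,
        mape=mape,
        spearman_rho=rho,
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        r_squared=float(reg.rvalue**2),
        n=len(est),
    )
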