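"""Exponential growth-rate estimation from cell-density time series.

The growth rate is expressed in doublings per hour and equals 1/G, the
inverse of the generation (doubling) time.  It is estimated as the
least-squares slope of log2(density) against time over an exponential-phase
window; when no window is supplied, the contiguous window of at least three
points with the maximal slope is selected automatically (ties favour longer,
then earlier windows) and reported for audit.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin


@dataclasses.dataclass
class GrowthCurve:
    times: np.ndarray  # hours, strictly increasing
    density: np.ndarray  # cells/mL, > 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.density.shape:
            raise ValueError("times and density must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.density <= 0):
            raise ValueError("densities must be > 0")


@dataclasses.dataclass
class GrowthRate:
    rate: float  # doublings per hour (= 1/G)
    generation_time: float  # hours; inf when rate <= 0
    window: tuple[float, float]  # fitted time interval
    log2_n0: float  # fitted intercept, log2 cells/mL at t=0
    r_squared: float


def _fit_window(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    res = stats.linregress(t, y)
    return res.slope, res.intercept, res.rvalue**2


class GrowthRateEstimator(BaseEstimator, RegressorMixin):
    """Least-squares exponential growth-rate fit on the log2 scale.

    Parameters
    ----------
    window : (t_start, t_end) or None
        Time interval to fit; ``None`` selects the maximal-slope contiguous
        window of at least ``min_points`` samples.
    min_points : int, default 3
        Minimum points in a fitted window.

    Attributes
    ----------
    rate_ : doublings per hour.
    generation_time_ : 1/rate (h), infinite for non-growing cultures.
    window_ : the fitted (t_start, t_end).
    log2_n0_ : fitted intercept.
    """

    def __init__(self, window: tuple[float, float] | None = None, min_points: int = 3):
        self.window = window
        self.min_points = min_points

    def fit(self, X, y=None):
        if isinstance(X, GrowthCurve):
            curve = X
        else:
            curve = GrowthCurve(np.ravel(np.asarray(X)), np.asarray(y))
        t, logd = curve.times, np.log2(curve.density)
        if self.window is not None:
            lo, hi = self.window
            mask = (t >= lo) & (t <= hi)
            if mask.sum() < self.min_points:
                raise ValueError(
                    f"window {self.window} contains fewer than {self.min_points} points"
                )
            slope, intercept, r2 = _fit_window(t[mask], logd[mask])
            chosen = (float(t[mask][0]), float(t[mask][-1]))
        else:
            if t.size < self.min_points:
                raise ValueError(f"need at least {self.min_points} points")
            best = None
            for i in range(t.size):
                for j in range(i + self.min_points - 1, t.size):
                    slope, intercept, r2 = _fit_window(t[i : j + 1], logd[i : j + 1])
                    # maximal slope; ties favour longer, then earlier windows
                    key = (slope, j - i, -i)
                    if best is None or key > best[0]:
                        best = (key, slope, intercept, r2, (float(t[i]), float(t[j])))
            _, slope, intercept, r2, chosen = best
        self.rate_ = float(slope)
        self.generation_time_ = float(1.0 / slope) if slope > 0 else float("inf")
        self.window_ = chosen
        self.log2_n0_ = float(intercept)
        self.r_squared_ = float(r2)
        return self

    def predict(self, X):
        t = np.ravel(np.asarray(X, dtype=float))
        return 2.0 ** (self.log2_n0_ + self.rate_ * t)

    def result(self) -> GrowthRate:
        return GrowthRate(
            rate=self.rate_,
            generation_time=self.generation_time_,
            window=self.window_,
            log2_n0=self.log2_n0_,
            r_squared=self.r_squared_,
        )


def growth_rate(
    curve: GrowthCurve, window: tuple[float, float] | None = None
) -> GrowthRate:
    """Estimate doublings/h (and G = 1/rate) from a growth curve."""
    return GrowthRateEstimator(window=window).fit(curve).result()
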