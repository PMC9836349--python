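"""Kinetic lacZ reporter quantification.

β-galactosidase activity is read out kinetically: OD420 is measured every
minute for an hour, the slope is taken over a contiguous window in the linear
range with a strong R², and relative activity is the slope divided by the
assayed culture volume times its OD600:

    activity = slope / (volume_ml × OD600)

Terminator strength is the percent reduction of reporter activity versus a
no-terminator control; readthrough between conditions is reported as a fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

DEFAULT_MIN_POINTS = 10
DEFAULT_R2_FLOOR = 0.995


class AssayError(ValueError):
    pass


@dataclass
class KineticSeries:
    """Timed OD420 readings plus the assayed culture's OD600."""

    time: np.ndarray          # minutes, strictly increasing
    od420: np.ndarray
    od600: float
    volume_ml: float = 0.1
    sample_id: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=np.float64)
        self.od420 = np.asarray(self.od420, dtype=np.float64)
        if self.time.shape != self.od420.shape or self.time.ndim != 1:
            raise AssayError("time and od420 must be 1-D arrays of equal length")
        if len(self.time) < 3:
            raise AssayError("a kinetic series needs at least 3 readings")
        if np.any(np.diff(self.time) <= 0):
            raise AssayError("times must be strictly increasing")
        if self.od600 <= 0:
            raise AssayError("od600 must be positive")
        if self.volume_ml <= 0:
            raise AssayError("volume_ml must be positive")

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class SlopeFit:
    slope: float
    window: tuple[int, int]   # (start_idx, end_idx) half-open
    r_squared: float
    low_confidence: bool = False


@dataclass(frozen=True)
class ActivityResult:
    sample_id: str
    slope: float
    window: tuple[int, int]
    r_squared: float
    activity: float
    low_confidence: bool = False


class _PrefixFitter:
    """O(1) least-squares slope/R² per contiguous window via prefix sums.

    A zero-variance window (flat line) counts as a perfect linear fit:
    slope 0, R² 1.
    """

    def __init__(self, t: np.ndarray, y: np.ndarray):
        z = np.zeros(1)
        self.ct = np.concatenate([z, np.cumsum(t)])
        self.cy = np.concatenate([z, np.cumsum(y)])
        self.ctt = np.concatenate([z, np.cumsum(t * t)])
        self.cty = np.concatenate([z, np.cumsum(t * y)])
        self.cyy = np.concatenate([z, np.cumsum(y * y)])

    def fit(self, i: int, j: int) -> tuple[float, float]:
        n = j - i
        st = self.ct[j] - self.ct[i]
        sy = self.cy[j] - self.cy[i]
        sxx = (self.ctt[j] - self.ctt[i]) - st * st / n
        sxy = (self.cty[j] - self.cty[i]) - st * sy / n
        syy = (self.cyy[j] - self.cyy[i]) - sy * sy / n
        slope = sxy / sxx
        if syy <= 0.0:
            return slope, 1.0
        r2 = 1.0 - (syy - sxy * sxy / sxx) / syy
        return slope, min(max(r2, 0.0), 1.0)


def fit_kinetic_slope(series: KineticSeries,
                      min_points: int = DEFAULT_MIN_POINTS,
                      r2_floor: float = DEFAULT_R2_FLOOR) -> SlopeFit:
    """Slope of the longest contiguous linear window of the kinetic read.

    Among all contiguous windows of at least ``min_points`` readings whose
    least-squares R² reaches ``r2_floor``, the longest is selected (ties:
    highest R², then earliest start). If no window qualifies, the best-R²
    window of exactly ``min_points`` readings is returned flagged low
    confidence.
    """
    n = len(series)
    if min_points < 3:
        raise AssayError("min_points must be >= 3")
    if n < min_points:
        raise AssayError(f"series has {n} readings, need at least {min_points}")
    fitter = _PrefixFitter(series.time, series.od420)

    best: Optional[tuple[int, float, int, float]] = None  # (len, r2, -start, slope)
    fallback: Optional[tuple[float, int, float]] = None   # (r2, -start, slope)
    for i in range(n):
        for j in range(i + min_points, n + 1):
            slope, r2 = fitter.fit(i, j)
            if j - i == min_points:
                cand = (r2, -i, slope)
                if fallback is None or cand[:2] > fallback[:2]:
                    fallback = (r2, -i, slope)
            if r2 >= r2_floor:
                cand_key = (j - i, r2, -i)
                if best is None or cand_key > best[:3]:
                    best = (j - i, r2, -i, slope)
    if best is not None:
        length, r2, neg_start, slope = best
        start = -neg_start
        return SlopeFit(slope=slope, window=(start, start + length),
                        r_squared=r2, low_confidence=False)
    r2, neg_start, slope = fallback
    start = -neg_start
    return SlopeFit(slope=slope, window=(start, start + min_points),
                    r_squared=r2, low_confidence=True)


def beta_gal_activity(slope: float, od600: float, volume_ml: float = 0.1) -> float:
    """Relative β-galactosidase activity: slope / (volume_ml × OD600)."""
    if od600 <= 0:
        raise AssayError("od600 must be positive")
    if volume_ml <= 0:
        raise AssayError("volume_ml must be positive")
    return slope / (volume_ml * od600)


def activity_from_series(series: KineticSeries,
                         min_points: int = DEFAULT_MIN_POINTS,
                         r2_floor: float = DEFAULT_R2_FLOOR) -> ActivityResult:
    """Full per-sample readout: slope window, R², and activity."""
    fit = fit_kinetic_slope(series, min_points=min_points, r2_floor=r2_floor)
    activity = beta_gal_activity(fit.slope, series.od600, series.volume_ml)
    return ActivityResult(sample_id=series.sample_id, slope=fit.slope,
                          window=fit.window, r_squared=fit.r_squared,
                          activity=activity, low_confidence=fit.low_confidence)


#: terminator strength classes: percent repression -> color label
STRENGTH_CLASSES = ((90.0, "red"), (50.0, "yellow"))


def terminator_strength(activity_term: float,
                        activity_no_term: float) -> tuple[float, str]:
    """Percent repression versus a no-terminator control, with color class.

    percent = 100 × (1 − activity_term / activity_no_term), clipped at 0;
    red above 90%, yellow above 50%, green otherwise.
    """
    if activity_no_term <= 0:
        raise AssayError("no-terminator control activity must be positive")
    if activity_term < 0:
        raise AssayError("terminator activity must be nonnegative")
    percent = max(0.0, 100.0 * (1.0 - activity_term / activity_no_term))
    for edge, label in STRENGTH_CLASSES:
        if percent > edge:
            return percent, label
    return percent, "green"


def fold_readthrough(activity_condition: float, activity_control: float) -> float:
    """Readthrough fold change between a condition and its control."""
    if activity_control <= 0:
        raise AssayError("control activity must be positive")
    return activity_condition / activity_control
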