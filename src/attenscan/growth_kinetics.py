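"""Doubling-time estimation from OD600 growth curves.

Doubling time is obtained from an exponential line of best fit over the
60–360 min window (inclusive): ordinary least squares on ln(OD600) versus
time, doubling time = ln 2 / slope. A non-positive slope is reported as
non-growing (infinite doubling time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_WINDOW_MIN = (60.0, 360.0)

#: sentinel for cultures with no measurable growth in the fit window
NON_GROWING = math.inf


class GrowthError(ValueError):
    pass


@dataclass
class GrowthCurve:
    time: np.ndarray     # minutes, ascending
    od600: np.ndarray
    strain_id: str = ""
    replicate_id: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=np.float64)
        self.od600 = np.asarray(self.od600, dtype=np.float64)
        if self.time.shape != self.od600.shape or self.time.ndim != 1:
            raise GrowthError("time and od600 must be 1-D arrays of equal length")
        if np.any(np.diff(self.time) < 0):
            raise GrowthError("times must be ascending")


def doubling_time(curve: GrowthCurve,
                  window_min: tuple[float, float] = DEFAULT_WINDOW_MIN) -> float:
    """Doubling time in minutes from a log-linear fit inside ``window_min``.

    Points with window_min[0] ≤ t ≤ window_min[1] (closed interval) enter an
    OLS fit of ln(OD600) against time; returns ln 2 / slope, or the
    :data:`NON_GROWING` sentinel when the slope is not positive.
    """
    lo, hi = window_min
    mask = (curve.time >= lo) & (curve.time <= hi)
    if int(mask.sum()) < 3:
        raise GrowthError(
            f"need >= 3 points in the fit window [{lo}, {hi}] min, "
            f"got {int(mask.sum())}"
        )
    od = curve.od600[mask]
    if np.any(od <= 0):
        raise GrowthError("all OD600 readings in the fit window must be positive")
    fit = stats.linregress(curve.time[mask], np.log(od))
    if fit.slope <= 0:
        return NON_GROWING
    return math.log(2.0) / fit.slope


def percent_change(dt_mutant: float, dt_reference: float) -> float:
    """Percent change in doubling time of a mutant versus a reference strain."""
    for name, dt in (("mutant", dt_mutant), ("reference", dt_reference)):
        if not math.isfinite(dt) or dt <= 0:
            raise GrowthError(
                f"{name} doubling time is non-growing or invalid ({dt}); "
                "report it directly instead of as a percent change"
            )
    return 100.0 * (dt_mutant - dt_reference) / dt_reference
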