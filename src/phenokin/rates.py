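"""Specific-rate extraction from batch time-courses.

During exponential growth dX/dt = mu.X, so mu is the least-squares slope of
ln(X/X0) against time; substrate depletion is first order in S, dS/dt = -q.S,
so q is the slope of -ln(S/S0) against time.  Each batch (one initial
substrate concentration S0, one replicate) yields one (S0, rate) point; the
collection of points over the S0 sweep is what the Haldane fit consumes.

The exponential window can be chosen explicitly, left as the full usable
series (the default, mirroring how batch studies are usually reduced), or
selected automatically as the contiguous stretch with the best log-linear
fit — useful when high substrate induces a lag phase that would otherwise
bias the slope down.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .errors import InsufficientDataError

__all__ = [
    "BatchCurve",
    "RateEstimate",
    "WindowSelection",
    "specific_growth_rate",
    "specific_degradation_rate",
    "select_exponential_window",
]

Branch = Literal["growth", "degradation"]

#: Substrate points below this fraction of S0 are treated as below the
#: detection/quantification floor and excluded from log fits.
DETECTION_FRACTION = 0.01

#: Minimum log-linear r-squared for an automatically selected window to be
#: considered a trustworthy exponential phase.
WINDOW_R2_THRESHOLD = 0.90


@dataclass
class BatchCurve:
    """One replicate's time-course at a given initial substrate concentration.

    At least one of ``biomass`` (dry mass, mg/L) or ``substrate`` (mg/L) must
    be present with >= 3 points; times are hours, strictly increasing.
    """

    s0: float
    times: np.ndarray
    biomass: np.ndarray | None = None
    substrate: np.ndarray | None = None
    replicate: str = "r1"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.biomass is None and self.substrate is None:
            raise ValueError("at least one of biomass/substrate must be present")
        for name in ("biomass", "substrate"):
            series = getattr(self, name)
            if series is None:
                continue
            series = np.asarray(series, dtype=float)
            setattr(self, name, series)
            if series.shape != self.times.shape:
                raise ValueError(f"{name} length must match times")
            if series.size < 3:
                raise ValueError(f"{name} needs at least 3 points")
            if np.any(series < 0):
                raise ValueError(f"{name} concentrations must be non-negative")
        if self.substrate is not None and self.s0 > 0:
            if abs(self.substrate[0] - self.s0) > 0.10 * self.s0:
                warnings.warn(
                    f"first substrate reading {self.substrate[0]:.4g} deviates more "
                    f"than 10% from nominal s0={self.s0:.4g}",
                    stacklevel=2,
                )


@dataclass(frozen=True)
class RateEstimate:
    """One (S0, specific rate) point with its log-linear fit diagnostics."""

    s0: float
    rate: float  # h^-1; mu or q
    r2_loglinear: float
    window: tuple[float, float]
    n_points: int
    branch: Branch
    replicate: str = "r1"
    low_quality: bool = False


@dataclass(frozen=True)
class WindowSelection:
    """Outcome of automatic exponential-window selection."""

    t_start: float
    t_end: float
    r2: float
    n_points: int
    low_quality: bool


def _loglinear_slope(t: np.ndarray, log_y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope of log_y vs t and its r^2.

    A flat series has zero slope and an undefined correlation; the latter is
    reported as 0 by convention.
    """
    if np.ptp(log_y) == 0.0:
        return 0.0, 0.0
    res = stats.linregress(t, log_y)
    r2 = res.rvalue**2
    if not np.isfinite(r2):
        r2 = 0.0
    return float(res.slope), float(r2)


def _window_mask(times: np.ndarray, window: tuple[float, float] | None) -> np.ndarray:
    if window is None:
        return np.ones_like(times, dtype=bool)
    lo, hi = window
    return (times >= lo) & (times <= hi)


def specific_growth_rate(
    curve: BatchCurve, window: tuple[float, float] | None = None
) -> RateEstimate:
    """mu (h^-1) from the slope of ln(X/X0) vs time over ``window``.

    All biomass values inside the window must be strictly positive (the log
    is undefined otherwise); fewer than 3 usable points is an error.
    """
    if curve.biomass is None:
        raise InsufficientDataError("curve has no biomass series")
    mask = _window_mask(curve.times, window)
    t = curve.times[mask]
    x = curve.biomass[mask]
    if t.size < 3:
        raise InsufficientDataError(
            f"only {t.size} biomass points in window; need at least 3"
        )
    if np.any(x <= 0):
        raise ValueError("non-positive biomass in window; cannot take logarithm")
    slope, r2 = _loglinear_slope(t, np.log(x))
    return RateEstimate(
        s0=curve.s0,
        rate=slope,
        r2_loglinear=r2,
        window=(float(t[0]), float(t[-1])),
        n_points=int(t.size),
        branch="growth",
        replicate=curve.replicate,
    )


def specific_degradation_rate(
    curve: BatchCurve,
    window: tuple[float, float] | None = None,
    detection_floor: float | None = None,
) -> RateEstimate:
    """q (h^-1) from the slope of -ln(S/S0) vs time over ``window``.

    Points at or below the detection floor (``DETECTION_FRACTION`` of S0 by
    default, or an absolute ``detection_floor`` in mg/L, e.g. the calibration
    LOQ) are excluded: once substrate is exhausted the log-linear model no
    longer applies and ln(S) diverges.
    """
    if curve.substrate is None:
        raise InsufficientDataError("curve has no substrate series")
    floor = detection_floor if detection_floor is not None else DETECTION_FRACTION * curve.s0
    mask = _window_mask(curve.times, window) & (curve.substrate > max(floor, 0.0))
    t = curve.times[mask]
    s = curve.substrate[mask]
    if t.size == 0:
        raise InsufficientDataError("entire substrate series is at/below detection")
    if t.size < 3:
        raise InsufficientDataError(
            f"only {t.size} substrate points above detection in window; need at least 3"
        )
    slope, r2 = _loglinear_slope(t, np.log(s))
    return RateEstimate(
        s0=curve.s0,
        rate=-slope,
        r2_loglinear=r2,
        window=(float(t[0]), float(t[-1])),
        n_points=int(t.size),
        branch="degradation",
        replicate=curve.replicate,
    )


def select_exponential_window(
    curve: BatchCurve,
    branch: Branch = "growth",
    min_points: int = 3,
    r2_threshold: float = WINDOW_R2_THRESHOLD,
) -> WindowSelection:
    """Pick the contiguous window whose log-linear fit has the highest r^2.

    Ties (within 1e-12) favour more points, then an earlier start — so an
    exact exponential keeps the whole series, while a lag phase at the front
    (flat biomass at high, toxic S0) is dropped because including it degrades
    linearity.  If no window reaches ``r2_threshold`` the best one is still
    returned, flagged ``low_quality``.
    """
    if branch == "growth":
        if curve.biomass is None:
            raise InsufficientDataError("curve has no biomass series")
        keep = curve.biomass > 0
        values = curve.biomass
    elif branch == "degradation":
        if curve.substrate is None:
            raise InsufficientDataError("curve has no substrate series")
        keep = curve.substrate > DETECTION_FRACTION * curve.s0
        values = curve.substrate
    else:
        raise ValueError(f"unknown branch {branch!r}")

    t = curve.times[keep]
    log_y = np.log(values[keep])
    if t.size < min_points + 1:
        raise InsufficientDataError(
            f"need at least {min_points + 1} usable points for window selection, have {t.size}"
        )

    best: tuple[float, int, float] | None = None  # (r2, n, t_start)
    best_window: WindowSelection | None = None
    for i in range(t.size - min_points + 1):
        for j in range(i + min_points, t.size + 1):
            _, r2 = _loglinear_slope(t[i:j], log_y[i:j])
            n = j - i
            if best is None or _window_better((r2, n, t[i]), best):
                best = (r2, n, float(t[i]))
                best_window = WindowSelection(
                    t_start=float(t[i]),
                    t_end=float(t[j - 1]),
                    r2=r2,
                    n_points=n,
                    low_quality=r2 < r2_threshold,
                )
    assert best_window is not None
    return best_window


def _window_better(cand: tuple[float, int, float], best: tuple[float, int, float]) -> bool:
    r2_c, n_c, t_c = cand
    r2_b, n_b, t_b = best
    if r2_c > r2_b + 1e-12:
        return True
    if r2_c < r2_b - 1e-12:
        return False
    if n_c != n_b:
        return n_c > n_b
    return t_c < t_b
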