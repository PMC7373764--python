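"""Nonlinear least-squares fitting of the Haldane law to (S0, rate) points.

The objective sum_i (rate_i - haldane(S0_i; rate*, Ks, Ki))^2 is multimodal
for sparse substrate grids, so the fit runs a seeded multistart: a heuristic
initial guess (rate* from the observed maximum, Ks from the half-maximum
crossing, Ki from the largest tested S0) plus log-uniform perturbations of
it.  Optimisation is in log-parameter space, which enforces positivity and
conditions the problem across the several-decades parameter ranges typical
of phenol kinetics.  The best start wins by lowest SSR, ties by smaller Ks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from . import kinetics
from .errors import DegenerateDataError, InsufficientDataError
from .kinetics import DerivedKinetics, HaldaneParameters
from .rates import RateEstimate

__all__ = ["HaldaneFitResult", "fit_haldane", "r_squared"]

#: Positivity bounds applied to every parameter (mg/L or h^-1).
PARAM_BOUNDS = (1e-6, 1e6)

#: Multistart perturbation factors span [0.1, 10] log-uniformly.
PERTURBATION_DECADES = 1.0

Weighting = Literal[None, "inverse_square"]


@dataclass(frozen=True)
class HaldaneFitResult:
    """Fitted parameters, derived quantities and goodness of fit."""

    params: HaldaneParameters
    derived: DerivedKinetics
    r2: float  # 1 - SS_res/SS_tot
    r2_pearson: float  # squared Pearson correlation, reported alongside
    residuals: np.ndarray  # observed - predicted, per point
    n_points: int
    converged: bool
    n_starts_used: int
    ssr: float


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot about the observed mean."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must have equal length >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed rates have zero variance; r^2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def _pearson_r2(obs: np.ndarray, pred: np.ndarray) -> float:
    if np.ptp(pred) == 0.0 or np.ptp(obs) == 0.0:
        return 0.0
    return float(np.corrcoef(obs, pred)[0, 1] ** 2)


def _as_arrays(points: Iterable) -> tuple[np.ndarray, np.ndarray]:
    s0, rate = [], []
    for p in points:
        if isinstance(p, RateEstimate):
            s0.append(p.s0)
            rate.append(p.rate)
        else:
            a, b = p
            s0.append(float(a))
            rate.append(float(b))
    return np.asarray(s0, dtype=float), np.asarray(rate, dtype=float)


def _initial_guess(s0: np.ndarray, rate: np.ndarray) -> np.ndarray:
    """Heuristic start: rate* ~ 2 x max rate, Ks from the half-max crossing
    on the rising limb, Ki ~ the largest tested substrate level."""
    order = np.argsort(s0)
    s_sorted, r_sorted = s0[order], rate[order]
    r_max = float(np.max(r_sorted))
    i_max = int(np.argmax(r_sorted))
    rising_s = s_sorted[: i_max + 1]
    rising_r = r_sorted[: i_max + 1]
    half = r_max / 2.0
    if rising_r.size >= 2 and rising_r[0] <= half <= rising_r[-1]:
        ks0 = float(np.interp(half, rising_r, rising_s))
    else:
        ks0 = float(np.median(s_sorted))
    ks0 = max(ks0, PARAM_BOUNDS[0])
    return np.array([2.0 * r_max, ks0, float(np.max(s_sorted))])


def fit_haldane(
    points: Iterable,
    branch: str = "growth",
    init: Sequence[float] | None = None,
    seed: int | None = 0,
    n_starts: int = 10,
    weighting: Weighting = None,
) -> HaldaneFitResult:
    """Fit (rate*, Ks, Ki) to ``points`` — RateEstimates or (s0, rate) pairs.

    Requires >= 4 points with distinct S0 (three free parameters plus one
    degree of freedom) and non-negative rates, not all zero.  ``init``
    overrides the heuristic centre of the multistart; ``weighting``
    'inverse_square' divides residuals by the observed rate (points with
    rate 0 keep unit weight).  Non-convergence of every start yields a
    result flagged ``converged=False``, not an exception.
    """
    s0, rate = _as_arrays(points)
    if np.unique(s0).size < 4:
        raise InsufficientDataError(
            f"need >= 4 distinct substrate levels, have {np.unique(s0).size}"
        )
    if np.any(rate < 0):
        raise ValueError("rates must be non-negative")
    if np.all(rate == 0):
        raise DegenerateDataError("all rates are zero; nothing to fit")
    if weighting not in (None, "inverse_square"):
        raise ValueError(f"unknown weighting {weighting!r}")

    weights = np.ones_like(rate)
    if weighting == "inverse_square":
        nz = rate > 0
        weights[nz] = 1.0 / rate[nz]

    centre = np.asarray(init, dtype=float) if init is not None else _initial_guess(s0, rate)
    centre = np.clip(centre, *PARAM_BOUNDS)
    log_lo, log_hi = np.log(PARAM_BOUNDS[0]), np.log(PARAM_BOUNDS[1])

    rng = np.random.default_rng(seed)
    starts = [np.log(centre)]
    for _ in range(n_starts):
        jitter = rng.uniform(-PERTURBATION_DECADES, PERTURBATION_DECADES, size=3)
        starts.append(np.clip(np.log(centre) + jitter * np.log(10.0), log_lo, log_hi))

    def residuals_log(log_theta: np.ndarray) -> np.ndarray:
        rate_star, ks, ki = np.exp(log_theta)
        model = rate_star * s0 / (ks + s0 + s0 * s0 / ki)
        return (model - rate) * weights

    best = None  # (ssr, ks, result)
    any_converged = False
    for x0 in starts:
        sol = least_squares(
            residuals_log,
            np.clip(x0, log_lo, log_hi),
            bounds=(log_lo, log_hi),
            method="trf",
            ftol=1e-14,
            xtol=1e-14,
            gtol=1e-10,
            max_nfev=2000,
        )
        ssr = float(2.0 * sol.cost)
        ks_cand = float(np.exp(sol.x[1]))
        any_converged = any_converged or sol.status > 0
        if best is None or _fit_better(ssr, ks_cand, best[0], best[1]):
            best = (ssr, ks_cand, sol)

    assert best is not None
    sol = best[2]
    rate_star, ks, ki = (float(v) for v in np.exp(sol.x))
    params = HaldaneParameters(rate_star=rate_star, ks=ks, ki=ki, branch=branch)
    predicted = kinetics.haldane_rate(s0, params)
    resid = rate - predicted
    ss_tot = float(np.sum((rate - rate.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return HaldaneFitResult(
        params=params,
        derived=kinetics.derive(params),
        r2=r2,
        r2_pearson=_pearson_r2(rate, predicted),
        residuals=resid,
        n_points=int(rate.size),
        converged=any_converged,
        n_starts_used=len(starts),
        ssr=float(np.sum(resid**2)),
    )


def _fit_better(ssr_c: float, ks_c: float, ssr_b: float, ks_b: float) -> bool:
    scale = max(ssr_b, 1e-300)
    if ssr_c < ssr_b - 1e-12 * scale:
        return True
    if ssr_c > ssr_b + 1e-12 * scale:
        return False
    return ks_c < ks_b
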