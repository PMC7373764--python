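"""Synthetic batch-culture generator.

Emulates the shake-flask design the kinetics analysis assumes: a sweep of
initial phenol concentrations (default grid 41-1117 mg/L), triplicate
cultures sampled every 12 h over 120 h, exponential biomass growth and
first-order substrate depletion with Haldane-shaped specific rates,

    dX/dt = mu(S) . X,      dS/dt = -q(S) . S,

where mu and q carry separately fitted parameter triples (the two processes
are not linked by a yield coefficient, matching how the batch model is
posed; an optional yield-linked mode ties dX/dt to Y.q(S).S for realism
experiments).  High substrate is toxic: above a threshold (default
1000 mg/L) the culture sits in a lag phase (state frozen at x0, s0) for a
fixed duration (default 12 h) before kinetics start.

Integration is a fixed-step classical Runge-Kutta (RK4) scheme with 200
internal steps per sampling interval — the dynamics are smooth and
non-stiff at these parameter scales, so sampled values are step-converged
to better than 1e-6 relative.  Observation noise is multiplicative log-normal with a
given coefficient of variation, unbiased in the mean, applied independently
per reading; runs are bit-reproducible for a fixed scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .errors import IntegrationError
from .kinetics import HaldaneParameters, haldane_rate
from .rates import BatchCurve, RateEstimate

__all__ = [
    "SimulationScenario",
    "simulate_batch",
    "simulate_scenario",
    "generate_rate_points",
]

#: Default growth-branch parameters: the phenol-degrading G. nicotianae
#: batch study this generator emulates (mu* h^-1, Ks and Ki in mg/L).
DEFAULT_GROWTH = HaldaneParameters(rate_star=0.574, ks=20.29, ki=268.1, branch="growth")

#: Default degradation-branch parameters from the same study (q*, Ks', Ki').
DEFAULT_DEGRADATION = HaldaneParameters(
    rate_star=1.244, ks=9.152, ki=517.5, branch="degradation"
)

#: Initial-phenol sweep echoing the study's range endpoints (41 and 1117 mg/L).
DEFAULT_S0_GRID = (41.0, 100.0, 200.0, 400.0, 600.0, 800.0, 980.0, 1117.0)


@dataclass(frozen=True)
class SimulationScenario:
    """Everything needed to generate one synthetic batch experiment."""

    growth_params: HaldaneParameters = DEFAULT_GROWTH
    #: None disables substrate depletion entirely (q = 0 everywhere)
    degradation_params: HaldaneParameters | None = DEFAULT_DEGRADATION
    s0_grid: tuple[float, ...] = DEFAULT_S0_GRID
    x0: float = 20.0  # inoculum dry biomass, mg/L
    sampling_interval: float = 12.0  # h
    horizon: float = 120.0  # h
    noise_cv: float = 0.05  # multiplicative CV of each observation
    replicates: int = 3
    seed: int = 0
    #: lag rule: a callable s0 -> hours, a constant (hours), or None for the
    #: default threshold rule (12 h lag above 1000 mg/L, else none).
    lag: Callable[[float], float] | float | None = None
    lag_threshold: float = 1000.0  # mg/L
    lag_duration: float = 12.0  # h
    substeps: int = 200  # internal RK4 steps per sampling interval
    yield_coefficient: float | None = None  # mg biomass per mg substrate, optional

    def __post_init__(self) -> None:
        if self.x0 < 0 or any(s < 0 for s in self.s0_grid):
            raise ValueError("concentrations must be non-negative")
        if self.sampling_interval <= 0 or self.horizon <= 0:
            raise ValueError("sampling_interval and horizon must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.substeps < 1:
            raise ValueError("substeps must be >= 1")

    def lag_for(self, s0: float) -> float:
        if callable(self.lag):
            return float(self.lag(s0))
        if self.lag is not None:
            return float(self.lag)
        return self.lag_duration if s0 > self.lag_threshold else 0.0


def _derivative(scn: SimulationScenario, x: float, s: float) -> tuple[float, float]:
    s_eff = max(s, 0.0)
    q = 0.0 if scn.degradation_params is None else haldane_rate(s_eff, scn.degradation_params)
    if scn.yield_coefficient is not None:
        dx = scn.yield_coefficient * q * s_eff
    else:
        dx = haldane_rate(s_eff, scn.growth_params) * x
    return dx, -q * s_eff


def _integrate(scn: SimulationScenario, s0: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free trajectories sampled at the scenario interval."""
    times = np.arange(0.0, scn.horizon + 1e-9, scn.sampling_interval)
    h = scn.sampling_interval / scn.substeps
    lag = scn.lag_for(s0)
    # snap the lag to the internal step grid so samples stay aligned
    lag = round(lag / h) * h

    x_out = np.empty_like(times)
    s_out = np.empty_like(times)
    x, s = float(scn.x0), float(s0)
    t = 0.0
    next_i = 0
    # frozen lag interval: state pinned at (x0, s0)
    while next_i < times.size and times[next_i] <= lag + 1e-9:
        x_out[next_i], s_out[next_i] = x, s
        next_i += 1
    t = lag
    while next_i < times.size:
        t_target = times[next_i]
        n_sub = round((t_target - t) / h)
        for _ in range(n_sub):
            k1 = _derivative(scn, x, s)
            k2 = _derivative(scn, x + 0.5 * h * k1[0], s + 0.5 * h * k1[1])
            k3 = _derivative(scn, x + 0.5 * h * k2[0], s + 0.5 * h * k2[1])
            k4 = _derivative(scn, x + h * k3[0], s + h * k3[1])
            x += h * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]) / 6.0
            s += h * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]) / 6.0
            s = max(s, 0.0)
            t += h
            if not (np.isfinite(x) and np.isfinite(s)):
                raise IntegrationError(f"non-finite state at t = {t:.4g} h (s0 = {s0:g})")
        x_out[next_i], s_out[next_i] = x, s
        next_i += 1
    return times, x_out, s_out


def _noise_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unbiased multiplicative log-normal factors with the given CV."""
    if cv == 0.0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)


def simulate_batch(scn: SimulationScenario, s0: float) -> list[BatchCurve]:
    """Simulate one initial concentration; returns one BatchCurve per replicate.

    ``s0`` must be a member of the scenario grid.  Replicates share the
    noise-free trajectory and differ only in their observation noise; the
    per-replicate random streams are derived deterministically from the
    scenario seed, the grid position and the replicate index.
    """
    matches = [i for i, g in enumerate(scn.s0_grid) if abs(g - s0) <= 1e-9 * max(1.0, g)]
    if not matches:
        raise ValueError(f"s0 = {s0:g} mg/L is not in the scenario grid {scn.s0_grid}")
    grid_index = matches[0]

    times, x_true, s_true = _integrate(scn, s0)
    curves = []
    for rep in range(scn.replicates):
        rng = np.random.default_rng([scn.seed, grid_index, rep])
        x_obs = x_true * _noise_factors(rng, scn.noise_cv, times.size)
        s_obs = s_true * _noise_factors(rng, scn.noise_cv, times.size)
        curves.append(
            BatchCurve(
                s0=s0,
                times=times.copy(),
                biomass=x_obs,
                substrate=s_obs,
                replicate=f"r{rep + 1}",
            )
        )
    return curves


def simulate_scenario(scn: SimulationScenario) -> list[BatchCurve]:
    """All grid levels, all replicates, in grid-then-replicate order."""
    out: list[BatchCurve] = []
    for s0 in scn.s0_grid:
        out.extend(simulate_batch(scn, s0))
    return out


def generate_rate_points(
    scn: SimulationScenario, noise_sd: float, branch: str = "growth"
) -> list[RateEstimate]:
    """Rate-level generator: haldane_rate at each grid S0 plus noise.

    Bypasses the time-course entirely — each point is the instantaneous
    Haldane rate at S0 with multiplicative Gaussian noise of standard
    deviation ``noise_sd`` (relative), truncated at zero.  One point per
    replicate per level.  Used to exercise the fitting stage against a known
    truth without the window-averaging bias of slope extraction.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    params = scn.growth_params if branch == "growth" else scn.degradation_params
    if params is None:
        raise ValueError(f"scenario has no {branch} parameters")
    rng = np.random.default_rng([scn.seed, 0x9E3779B9 % (2**31)])
    points = []
    for s0 in scn.s0_grid:
        true_rate = haldane_rate(s0, params)
        for rep in range(scn.replicates):
            noisy = true_rate * (1.0 + rng.normal(0.0, noise_sd)) if noise_sd else true_rate
            points.append(
                RateEstimate(
                    s0=s0,
                    rate=max(noisy, 0.0),
                    r2_loglinear=1.0,
                    window=(0.0, scn.horizon),
                    n_points=int(scn.horizon / scn.sampling_interval) + 1,
                    branch=branch,  # type: ignore[arg-type]
                    replicate=f"r{rep + 1}",
                )
            )
    return points
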