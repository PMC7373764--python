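"""The Haldane substrate-inhibition rate law and its closed-form derivatives.

Growth of microbes on an inhibitory substrate such as phenol is described by

    rate(S) = rate* . S / (Ks + S + S^2/Ki)

where ``rate*`` is the fitting parameter (mu* for growth, q* for degradation),
``Ks`` the half-saturation constant and ``Ki`` the inhibition constant, both
in mg/L.  The law rises to a single maximum at the critical substrate
concentration Sm = sqrt(Ks.Ki) and declines beyond it; the true maximum rate

    rate_max = rate* / (1 + 2 sqrt(Ks/Ki))

is always strictly below the fitting parameter, which is why reporting
``rate*`` as "the maximum rate" overestimates it.  As Ki -> infinity the law
reduces to the Monod form rate*.S/(Ks+S); ``ki=None`` selects that limit
explicitly.

The same algebra serves the growth branch (mu*, Ks, Ki) and the degradation
branch (q*, Ks', Ki'); the branch label is carried for reporting only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "HaldaneParameters",
    "DerivedKinetics",
    "haldane_rate",
    "critical_substrate",
    "true_max_rate",
    "derive",
    "overestimation_percent",
]

Branch = Literal["growth", "degradation"]


@dataclass(frozen=True)
class HaldaneParameters:
    """Parameter triple of the Haldane law for one branch.

    ``ki=None`` is the explicit Monod (no-inhibition) limit.
    """

    rate_star: float  # h^-1; mu* or q*
    ks: float  # mg/L
    ki: float | None  # mg/L, or None for the Monod limit
    branch: Branch = "growth"

    def __post_init__(self) -> None:
        if not self.rate_star > 0:
            raise ValueError(f"rate_star must be positive, got {self.rate_star}")
        if not self.ks > 0:
            raise ValueError(f"ks must be positive, got {self.ks}")
        if self.ki is not None and not self.ki > 0:
            raise ValueError(f"ki must be positive or None, got {self.ki}")
        if self.branch not in ("growth", "degradation"):
            raise ValueError(f"branch must be 'growth' or 'degradation', got {self.branch!r}")

    @property
    def is_monod(self) -> bool:
        return self.ki is None

    def to_record(self) -> dict:
        """Flat key-value form used in report tables."""
        return {
            "branch": self.branch,
            "rate_star": self.rate_star,
            "ks": self.ks,
            "ki": math.inf if self.ki is None else self.ki,
        }


@dataclass(frozen=True)
class DerivedKinetics:
    """Closed-form quantities derived from a Haldane parameter triple."""

    s_m: float  # mg/L; sqrt(Ks.Ki), infinite in the Monod limit
    true_max_rate: float  # h^-1; the actual peak of the rate law


def haldane_rate(s, p: HaldaneParameters):
    """Specific rate (h^-1) at substrate concentration ``s`` (mg/L).

    Vectorised over ``s``; negative substrate is a domain error.
    """
    scalar_in = np.isscalar(s)
    arr = np.asarray(s, dtype=float)
    if np.any(arr < 0):
        raise ValueError("substrate concentration must be non-negative")
    if p.ki is None:
        rate = p.rate_star * arr / (p.ks + arr)
    else:
        rate = p.rate_star * arr / (p.ks + arr + arr * arr / p.ki)
    return float(rate) if scalar_in else rate


def critical_substrate(p: HaldaneParameters) -> float:
    """Sm = sqrt(Ks.Ki), the concentration at which the rate peaks.

    Infinite in the Monod limit (the rate saturates, never peaks).
    """
    if p.ki is None:
        return math.inf
    return math.sqrt(p.ks * p.ki)


def true_max_rate(p: HaldaneParameters) -> float:
    """The actual maximum of the rate law, rate*/(1 + 2 sqrt(Ks/Ki)).

    Equals ``haldane_rate(critical_substrate(p), p)``; strictly below
    ``rate_star`` whenever Ki is finite, and equal to it in the Monod limit.
    """
    if p.ki is None:
        return p.rate_star
    return p.rate_star / (1.0 + 2.0 * math.sqrt(p.ks / p.ki))


def derive(p: HaldaneParameters) -> DerivedKinetics:
    """Both derived quantities at once, as reported alongside fits."""
    return DerivedKinetics(s_m=critical_substrate(p), true_max_rate=true_max_rate(p))


def overestimation_percent(p: HaldaneParameters) -> float:
    """By how much (%) the fitting parameter rate* exceeds the true maximum.

    100.(rate* - rate_max)/rate_max; zero in the Monod limit.
    """
    tmr = true_max_rate(p)
    return 100.0 * (p.rate_star - tmr) / tmr
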