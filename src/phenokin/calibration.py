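"""Linear spectrophotometric calibrations.

Phenol is quantified colorimetrically (4-aminoantipyrine assay, read at
500 nm): absorbance is linear in concentration over the calibrated range,
``A = slope * C + intercept``.  Biomass is read as OD600 and converted to
dry biomass through a second linear coefficient that must be supplied by
the user (it is instrument- and strain-specific and has no default).

The forward direction maps concentration to absorbance; the inverse maps a
raw reading back to concentration, which is what the kinetics operate on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidReadingError

__all__ = [
    "LinearCalibration",
    "PHENOL_A500",
    "absorbance_to_concentration",
    "concentration_to_absorbance",
    "od_to_dry_biomass",
]

#: Readings this far below the intercept (as a fraction of the intercept)
#: are treated as blank scatter and clamp to zero concentration.
CLAMP_FRACTION = 0.02


@dataclass(frozen=True)
class LinearCalibration:
    """A straight-line standard curve, absorbance = slope * concentration + intercept.

    Parameters
    ----------
    slope : float
        Absorbance per (mg/L); must be positive.
    intercept : float
        Blank absorbance (dimensionless).
    valid_range : tuple of float
        Concentration range (mg/L) over which the line was calibrated.
        Values outside trigger an extrapolation warning, not an error.
    """

    slope: float
    intercept: float = 0.0
    valid_range: tuple[float, float] = (0.0, 1200.0)

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"calibration slope must be positive, got {self.slope}")
        lo, hi = self.valid_range
        if not lo < hi:
            raise ValueError(f"valid_range must be increasing, got {self.valid_range}")

    def forward(self, concentration):
        return self.slope * np.asarray(concentration, dtype=float) + self.intercept

    def inverse(self, absorbance):
        return (np.asarray(absorbance, dtype=float) - self.intercept) / self.slope


#: Phenol standard curve (A500, 4-aminoantipyrine assay), calibrated over
#: 100-1200 mg/L; the stored range starts at 0 so that blanks invert cleanly.
PHENOL_A500 = LinearCalibration(slope=0.002447, intercept=0.1423, valid_range=(0.0, 1200.0))


def _maybe_scalar(x: np.ndarray, scalar_in: bool):
    return float(x) if scalar_in else x


def concentration_to_absorbance(x, cal: LinearCalibration):
    """Forward-evaluate the standard curve at concentration ``x`` (mg/L).

    Negative concentrations are a domain error; concentrations outside
    ``cal.valid_range`` emit an extrapolation warning.
    """
    scalar_in = np.isscalar(x)
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("concentration must be non-negative")
    _warn_if_outside_range(arr, cal)
    return _maybe_scalar(cal.forward(arr), scalar_in)


def absorbance_to_concentration(a, cal: LinearCalibration, dilution_factor: float = 1.0):
    """Invert the standard curve: raw absorbance -> concentration (mg/L).

    Readings within ``CLAMP_FRACTION`` of the intercept below it are blank
    scatter and clamp to 0; readings further below raise
    :class:`~phenokin.errors.InvalidReadingError`.  ``dilution_factor``
    multiplies the result when the assayed sample was diluted before reading
    (default 1: the curve is assumed to absorb any fixed dilution already).
    """
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be positive")
    scalar_in = np.isscalar(a)
    arr = np.asarray(a, dtype=float)
    tol = CLAMP_FRACTION * abs(cal.intercept)
    if np.any(arr < cal.intercept - tol):
        bad = float(np.min(arr))
        raise InvalidReadingError(
            f"absorbance {bad:.5g} is more than {CLAMP_FRACTION:.0%} below the "
            f"calibration intercept {cal.intercept:.5g}; not a valid reading"
        )
    conc = np.maximum(cal.inverse(arr), 0.0) * dilution_factor
    _warn_if_outside_range(conc, cal)
    return _maybe_scalar(conc, scalar_in)


def od_to_dry_biomass(od, coeff: LinearCalibration | None):
    """Convert OD600 readings to dry biomass (mg/L) through a user calibration.

    ``coeff`` is the growth-absorbance-vs-dry-biomass line (forward maps
    biomass to OD); there is no default because the coefficient depends on
    the instrument and organism.
    """
    if coeff is None:
        raise ConfigurationError(
            "biomass input is OD600 but no dry-biomass calibration was supplied; "
            "set the 'calibration: biomass: {slope, intercept}' config block"
        )
    scalar_in = np.isscalar(od)
    arr = np.asarray(od, dtype=float)
    return _maybe_scalar(np.maximum(coeff.inverse(arr), 0.0), scalar_in)


def _warn_if_outside_range(conc: np.ndarray, cal: LinearCalibration) -> None:
    lo, hi = cal.valid_range
    if np.any((conc < lo) | (conc > hi)):
        warnings.warn(
            f"concentration outside calibrated range [{lo:g}, {hi:g}] mg/L; "
            "extrapolating the standard curve",
            stacklevel=3,
        )
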