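"""CSV and config I/O.

Time-course files are plain CSV with a header row and optional ``#``-prefixed
metadata lines.  Columns: ``time_h``, ``s0_mg_per_l``, ``replicate``, and one
of each measurement pair — ``biomass_mg_per_l`` or raw ``od600`` for biomass,
``phenol_mg_per_l`` or raw ``a500`` for substrate.  Raw columns are converted
on read through the calibrations in force.
"""

from __future__ import annotations

import io as _io
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .calibration import (
    PHENOL_A500,
    LinearCalibration,
    absorbance_to_concentration,
    concentration_to_absorbance,
    od_to_dry_biomass,
)
from .errors import ConfigurationError
from .rates import BatchCurve

__all__ = ["read_curves_csv", "write_curves_csv", "curves_to_frame"]

FLOAT_FMT = "%.10g"


def curves_to_frame(
    curves: Iterable[BatchCurve],
    raw: Mapping[str, LinearCalibration] | None = None,
) -> pd.DataFrame:
    """Stack curves into the canonical long table.

    With ``raw`` calibrations (keys ``biomass`` and/or ``phenol``) the
    concentrations are forward-converted into instrument readings (``od600``,
    ``a500``) instead — the schema real raw data arrives in.
    """
    raw = raw or {}
    rows = []
    for c in curves:
        rec: dict = {
            "time_h": c.times,
            "s0_mg_per_l": np.full_like(c.times, c.s0),
            "replicate": [c.replicate] * c.times.size,
        }
        if c.biomass is not None:
            if "biomass" in raw:
                rec["od600"] = raw["biomass"].forward(c.biomass)
            else:
                rec["biomass_mg_per_l"] = c.biomass
        if c.substrate is not None:
            if "phenol" in raw:
                rec["a500"] = concentration_to_absorbance(c.substrate, raw["phenol"])
            else:
                rec["phenol_mg_per_l"] = c.substrate
        rows.append(pd.DataFrame(rec))
    return pd.concat(rows, ignore_index=True)


def write_curves_csv(
    curves: Iterable[BatchCurve],
    path,
    metadata: Mapping[str, object] | None = None,
    raw: Mapping[str, LinearCalibration] | None = None,
) -> None:
    frame = curves_to_frame(curves, raw=raw)
    buf = _io.StringIO()
    for key, value in (metadata or {}).items():
        buf.write(f"# {key}: {value}\n")
    frame.to_csv(buf, index=False, float_format=FLOAT_FMT)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_curves_csv(
    path,
    biomass_cal: LinearCalibration | None = None,
    phenol_cal: LinearCalibration = PHENOL_A500,
    dilution_factor: float = 1.0,
) -> list[BatchCurve]:
    """Parse a time-course CSV into BatchCurves, converting raw readings.

    Raw ``od600`` requires ``biomass_cal`` (no default exists for the
    OD-to-dry-mass coefficient); raw ``a500`` converts through the phenol
    standard curve.
    """
    frame = pd.read_csv(path, comment="#")
    required = {"time_h", "s0_mg_per_l", "replicate"}
    missing = required - set(frame.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing required columns {sorted(missing)}")

    has_biomass = "biomass_mg_per_l" in frame.columns or "od600" in frame.columns
    has_substrate = "phenol_mg_per_l" in frame.columns or "a500" in frame.columns
    if not has_biomass and not has_substrate:
        raise ConfigurationError(
            f"{path}: need at least one measurement column "
            "(biomass_mg_per_l | od600 | phenol_mg_per_l | a500)"
        )
    if "od600" in frame.columns and biomass_cal is None:
        raise ConfigurationError(
            f"{path}: od600 column present but no biomass calibration configured"
        )

    curves = []
    for (s0, rep), grp in frame.groupby(["s0_mg_per_l", "replicate"], sort=True):
        grp = grp.sort_values("time_h")
        biomass = substrate = None
        if "biomass_mg_per_l" in grp.columns:
            biomass = grp["biomass_mg_per_l"].to_numpy(dtype=float)
        elif "od600" in grp.columns:
            biomass = od_to_dry_biomass(grp["od600"].to_numpy(dtype=float), biomass_cal)
        if "phenol_mg_per_l" in grp.columns:
            substrate = grp["phenol_mg_per_l"].to_numpy(dtype=float)
        elif "a500" in grp.columns:
            substrate = absorbance_to_concentration(
                grp["a500"].to_numpy(dtype=float), phenol_cal, dilution_factor
            )
        curves.append(
            BatchCurve(
                s0=float(s0),
                times=grp["time_h"].to_numpy(dtype=float),
                biomass=biomass,
                substrate=substrate,
                replicate=str(rep),
            )
        )
    return curves
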