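"""Pipeline configuration: a single YAML mapping with printable defaults.

Every run is fully determined by the config plus its seed; the SHA-256 hash
of the canonical config dump is stamped into every output file so that
numbers are traceable to the exact settings that produced them.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Literal

import yaml

from .calibration import PHENOL_A500, LinearCalibration
from .errors import ConfigurationError
from .kinetics import HaldaneParameters
from .simulate import SimulationScenario

__all__ = ["PipelineConfig", "load_config", "default_config_yaml", "config_hash"]


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    output_dir: str = "phenokin_out"
    #: path to a time-course CSV; None means simulate the scenario below
    input_csv: str | None = None
    scenario: SimulationScenario = field(default_factory=SimulationScenario)
    #: 'curves' extracts rates from time-courses (the batch-study route);
    #: 'direct' generates rate-level points, bypassing slope extraction
    rate_source: Literal["curves", "direct"] = "curves"
    #: 'full' fits every usable point up to substrate exhaustion (the
    #: batch-study convention); 'auto' picks the best log-linear window
    window_mode: Literal["full", "auto"] = "full"
    branches: tuple[str, ...] = ("growth", "degradation")
    phenol_cal: LinearCalibration = field(default_factory=lambda: PHENOL_A500)
    biomass_cal: LinearCalibration | None = None
    dilution_factor: float = 1.0
    fit_multistart: int = 10
    fit_weighting: str | None = None
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.rate_source not in ("curves", "direct"):
            raise ConfigurationError(f"rate_source must be curves|direct, got {self.rate_source!r}")
        if self.window_mode not in ("full", "auto"):
            raise ConfigurationError(f"window_mode must be full|auto, got {self.window_mode!r}")
        for b in self.branches:
            if b not in ("growth", "degradation"):
                raise ConfigurationError(f"unknown branch {b!r}")


def _cal_to_dict(cal: LinearCalibration | None) -> dict | None:
    if cal is None:
        return None
    return {"slope": cal.slope, "intercept": cal.intercept, "range": list(cal.valid_range)}


def _cal_from_dict(d: dict | None) -> LinearCalibration | None:
    if d is None:
        return None
    return LinearCalibration(
        slope=float(d["slope"]),
        intercept=float(d.get("intercept", 0.0)),
        valid_range=tuple(d.get("range", (0.0, 1200.0))),
    )


def _params_to_dict(p: HaldaneParameters) -> dict:
    return {"rate_star": p.rate_star, "ks": p.ks, "ki": p.ki, "branch": p.branch}


def _params_from_dict(d: dict, branch: str) -> HaldaneParameters:
    return HaldaneParameters(
        rate_star=float(d["rate_star"]),
        ks=float(d["ks"]),
        ki=None if d.get("ki") is None else float(d["ki"]),
        branch=d.get("branch", branch),
    )


def config_to_dict(cfg: PipelineConfig) -> dict:
    scn = cfg.scenario
    return {
        "seed": cfg.seed,
        "output_dir": cfg.output_dir,
        "input_csv": cfg.input_csv,
        "rate_source": cfg.rate_source,
        "window_mode": cfg.window_mode,
        "branches": list(cfg.branches),
        "calibration": {
            "phenol": _cal_to_dict(cfg.phenol_cal),
            "biomass": _cal_to_dict(cfg.biomass_cal),
            "dilution_factor": cfg.dilution_factor,
        },
        "fit": {"multistart": cfg.fit_multistart, "weighting": cfg.fit_weighting},
        "verbosity": cfg.verbosity,
        "scenario": {
            "growth_params": _params_to_dict(scn.growth_params),
            "degradation_params": (
                None if scn.degradation_params is None else _params_to_dict(scn.degradation_params)
            ),
            "s0_grid": list(scn.s0_grid),
            "x0": scn.x0,
            "sampling_interval": scn.sampling_interval,
            "horizon": scn.horizon,
            "noise_cv": scn.noise_cv,
            "replicates": scn.replicates,
            "lag_threshold": scn.lag_threshold,
            "lag_duration": scn.lag_duration,
            "substeps": scn.substeps,
            "yield_coefficient": scn.yield_coefficient,
        },
    }


def config_from_dict(d: dict) -> PipelineConfig:
    cal = d.get("calibration", {}) or {}
    fit = d.get("fit", {}) or {}
    scn_d = d.get("scenario", {}) or {}
    scn_kwargs: dict = {}
    if "growth_params" in scn_d:
        scn_kwargs["growth_params"] = _params_from_dict(scn_d["growth_params"], "growth")
    if "degradation_params" in scn_d:
        dp = scn_d["degradation_params"]
        scn_kwargs["degradation_params"] = (
            None if dp is None else _params_from_dict(dp, "degradation")
        )
    for key in (
        "x0",
        "sampling_interval",
        "horizon",
        "noise_cv",
        "lag_threshold",
        "lag_duration",
        "yield_coefficient",
    ):
        if key in scn_d and scn_d[key] is not None:
            scn_kwargs[key] = float(scn_d[key])
    for key in ("replicates", "substeps"):
        if key in scn_d:
            scn_kwargs[key] = int(scn_d[key])
    if "s0_grid" in scn_d:
        scn_kwargs["s0_grid"] = tuple(float(s) for s in scn_d["s0_grid"])
    scn_kwargs["seed"] = int(d.get("seed", 0))
    scenario = SimulationScenario(**scn_kwargs)

    phenol = _cal_from_dict(cal.get("phenol")) or PHENOL_A500
    return PipelineConfig(
        seed=int(d.get("seed", 0)),
        output_dir=str(d.get("output_dir", "phenokin_out")),
        input_csv=d.get("input_csv"),
        scenario=scenario,
        rate_source=d.get("rate_source", "curves"),
        window_mode=d.get("window_mode", "full"),
        branches=tuple(d.get("branches", ("growth", "degradation"))),
        phenol_cal=phenol,
        biomass_cal=_cal_from_dict(cal.get("biomass")),
        dilution_factor=float(cal.get("dilution_factor", 1.0)),
        fit_multistart=int(fit.get("multistart", 10)),
        fit_weighting=fit.get("weighting"),
        verbosity=int(d.get("verbosity", 1)),
    )


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a YAML mapping")
    return config_from_dict(data)


def default_config_yaml() -> str:
    """Canonical dump of every default setting (the dump-config output)."""
    return yaml.safe_dump(config_to_dict(PipelineConfig()), sort_keys=True)


def config_hash(cfg: PipelineConfig) -> str:
    """Hash of the analysis settings; where outputs land is not part of it."""
    d = config_to_dict(cfg)
    d.pop("output_dir", None)
    d.pop("verbosity", None)
    canonical = yaml.safe_dump(d, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
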