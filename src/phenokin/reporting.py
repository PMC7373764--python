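"""Pipeline driver and report emission.

Stages: acquire curves (read or simulate) -> calibrate -> extract rates ->
fit each branch -> derive -> report.  Every stage writes its output file
before the next begins, so each number in the final report is traceable to
an on-disk intermediate; stage failures carry the stage name, and partial
outputs are retained.  Fixed config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
from collections import defaultdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, config_hash
from .errors import InsufficientDataError, PhenokinError, PipelineStageError
from .fitting import HaldaneFitResult, fit_haldane
from .io import read_curves_csv, write_curves_csv
from .kinetics import overestimation_percent
from .rates import (
    BatchCurve,
    DETECTION_FRACTION,
    RateEstimate,
    select_exponential_window,
    specific_degradation_rate,
    specific_growth_rate,
)
from .simulate import generate_rate_points, simulate_scenario

__all__ = ["percent_degradation", "run_pipeline"]

#: report rounding, decimal places per branch (applied only when printing)
REPORT_DECIMALS = {"growth": 2, "degradation": 3}


def percent_degradation(c0: float, ct: float, tolerance: float = 0.02) -> float:
    """Endpoint removal, 100.(C0 - Ct)/C0, clipped to [0, 100].

    ``ct`` may exceed ``c0`` by at most ``tolerance`` (measurement scatter on
    an undegraded sample); more than that, or a non-positive ``c0``, is a
    domain error.
    """
    if c0 <= 0:
        raise ValueError(f"initial concentration must be positive, got {c0}")
    if ct < 0 or ct > c0 * (1.0 + tolerance):
        raise ValueError(f"final concentration {ct} outside [0, {c0 * (1 + tolerance):.6g}]")
    return float(np.clip(100.0 * (c0 - ct) / c0, 0.0, 100.0))


def _metadata(cfg: PipelineConfig) -> dict:
    return {"tool": f"phenokin {__version__}", "seed": cfg.seed, "config": config_hash(cfg)}


def _write_table(frame: pd.DataFrame, path: Path, meta: Mapping[str, object]) -> None:
    buf = _io.StringIO()
    for k, v in meta.items():
        buf.write(f"# {k}: {v}\n")
    frame.to_csv(buf, index=False, float_format="%.10g")
    path.write_text(buf.getvalue())


def _full_window(curve: BatchCurve, branch: str) -> tuple[float, float] | None:
    """Batch-study default window: end of lag to substrate exhaustion.

    The lag is detectable only when the leading readings are exactly frozen
    (noise-free synthetic data); with noise the full series is used and the
    'auto' window mode is the tool for lag exclusion.
    """
    t = curve.times
    start = t[0]
    series = curve.biomass if branch == "growth" else curve.substrate
    if series is not None:
        i = 0
        while i + 1 < series.size and series[i + 1] == series[0]:
            i += 1
        start = t[i]
    end = t[-1]
    if curve.substrate is not None:
        above = curve.substrate > DETECTION_FRACTION * curve.s0
        if above.any():
            end = t[above][-1]
        else:
            end = start
    return (float(start), float(end))


def _extract_rates(curves: list[BatchCurve], cfg: PipelineConfig):
    points: list[RateEstimate] = []
    skipped: list[dict] = []
    for curve in curves:
        for branch in cfg.branches:
            series = curve.biomass if branch == "growth" else curve.substrate
            if series is None:
                continue
            try:
                if cfg.window_mode == "auto":
                    sel = select_exponential_window(curve, branch)  # type: ignore[arg-type]
                    window = (sel.t_start, sel.t_end)
                    low_q = sel.low_quality
                else:
                    window = _full_window(curve, branch)
                    low_q = False
                if branch == "growth":
                    est = specific_growth_rate(curve, window)
                else:
                    est = specific_degradation_rate(curve, window)
                if low_q:
                    est = dataclasses.replace(est, low_quality=True)
                points.append(est)
            except (PhenokinError, ValueError) as exc:
                skipped.append(
                    {
                        "s0": curve.s0,
                        "replicate": curve.replicate,
                        "branch": branch,
                        "reason": str(exc),
                    }
                )
    return points, skipped


def _aggregate(points: list[RateEstimate]) -> pd.DataFrame:
    """Per-replicate rates averaged within (branch, s0); mean +/- SD."""
    groups: dict[tuple[str, float], list[float]] = defaultdict(list)
    for p in points:
        groups[(p.branch, p.s0)].append(p.rate)
    rows = [
        {
            "branch": branch,
            "s0": s0,
            "rate_mean": float(np.mean(rates)),
            "rate_sd": float(np.std(rates, ddof=1)) if len(rates) > 1 else 0.0,
            "n_replicates": len(rates),
        }
        for (branch, s0), rates in sorted(groups.items())
    ]
    return pd.DataFrame(
        rows, columns=["branch", "s0", "rate_mean", "rate_sd", "n_replicates"]
    )


def _fit_row(fit: HaldaneFitResult, cfg: PipelineConfig) -> dict:
    nd = REPORT_DECIMALS[fit.params.branch]
    return {
        "branch": fit.params.branch,
        "rate_star": round(fit.params.rate_star, nd),
        "ks": round(fit.params.ks, nd),
        "ki": round(fit.params.ki, nd) if fit.params.ki is not None else float("inf"),
        "s_m": round(fit.derived.s_m, nd),
        "true_max": round(fit.derived.true_max_rate, nd),
        "r2": round(fit.r2, nd),
        "r2_pearson": round(fit.r2_pearson, nd),
        "overestimation_pct": round(overestimation_percent(fit.params), 1),
        "n_points": fit.n_points,
        "converged": fit.converged,
        "n_starts": fit.n_starts_used,
        "seed": cfg.seed,
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns a bundle of output paths and fits.

    Outputs under ``cfg.output_dir``: ``curves.csv`` (when simulated),
    ``rates.csv`` (per-replicate estimates), ``rates_summary.csv``
    (mean +/- SD per level), ``fit_<branch>.csv`` (rounded report tables),
    ``report.txt`` and ``summary.json`` (full precision).
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = _metadata(cfg)
    bundle: dict = {"output_dir": str(outdir), "fits": {}, "paths": {}}

    # --- stage: input -----------------------------------------------------
    try:
        if cfg.input_csv is not None:
            curves = read_curves_csv(
                cfg.input_csv,
                biomass_cal=cfg.biomass_cal,
                phenol_cal=cfg.phenol_cal,
                dilution_factor=cfg.dilution_factor,
            )
        else:
            curves = simulate_scenario(cfg.scenario)
            path = outdir / "curves.csv"
            write_curves_csv(curves, path, metadata=meta)
            bundle["paths"]["curves"] = str(path)
    except PhenokinError as exc:
        raise PipelineStageError("input", str(exc), cfg.input_csv) from exc

    # --- stage: rates -----------------------------------------------------
    try:
        if cfg.rate_source == "direct":
            points = []
            for branch in cfg.branches:
                points.extend(
                    generate_rate_points(cfg.scenario, cfg.scenario.noise_cv, branch)
                )
            skipped = []
        else:
            points, skipped = _extract_rates(curves, cfg)
        rates_frame = pd.DataFrame(
            [
                {
                    "s0": p.s0,
                    "branch": p.branch,
                    "replicate": p.replicate,
                    "rate": p.rate,
                    "r2": p.r2_loglinear,
                    "window_start": p.window[0],
                    "window_end": p.window[1],
                    "n_points": p.n_points,
                    "low_quality": p.low_quality,
                }
                for p in points
            ],
            columns=[
                "s0", "branch", "replicate", "rate", "r2",
                "window_start", "window_end", "n_points", "low_quality",
            ],
        ).sort_values(["branch", "s0", "replicate"], ignore_index=True)
        path = outdir / "rates.csv"
        _write_table(rates_frame, path, meta)
        bundle["paths"]["rates"] = str(path)

        summary_frame = _aggregate(points)
        path = outdir / "rates_summary.csv"
        _write_table(summary_frame, path, meta)
        bundle["paths"]["rates_summary"] = str(path)
    except PhenokinError as exc:
        raise PipelineStageError("rates", str(exc)) from exc

    # --- stage: fit + derive ----------------------------------------------
    fit_rows = []
    for branch in cfg.branches:
        branch_pts = summary_frame[summary_frame["branch"] == branch]
        pairs = list(zip(branch_pts["s0"], branch_pts["rate_mean"]))
        try:
            fit = fit_haldane(
                pairs,
                branch=branch,
                seed=cfg.seed,
                n_starts=cfg.fit_multistart,
                weighting=cfg.fit_weighting,  # type: ignore[arg-type]
            )
        except (InsufficientDataError, PhenokinError) as exc:
            skipped.append({"s0": None, "replicate": None, "branch": branch, "reason": str(exc)})
            continue
        bundle["fits"][branch] = fit
        row = _fit_row(fit, cfg)
        fit_rows.append(row)
        path = outdir / f"fit_{branch}.csv"
        _write_table(pd.DataFrame([row]), path, meta)
        bundle["paths"][f"fit_{branch}"] = str(path)

    # --- stage: report ----------------------------------------------------
    lines = [f"# {k}: {v}" for k, v in meta.items()]
    lines.append("")
    lines.append("Haldane substrate-inhibition fits")
    lines.append("=" * 48)
    for row in fit_rows:
        lines.append(f"branch: {row['branch']}")
        for key in ("rate_star", "ks", "ki", "s_m", "true_max", "r2", "overestimation_pct"):
            lines.append(f"  {key:>18}: {row[key]}")
        lines.append("")
    if skipped:
        lines.append(f"skipped estimates: {len(skipped)} (see summary.json)")
    report_path = outdir / "report.txt"
    report_path.write_text("\n".join(lines) + "\n")
    bundle["paths"]["report"] = str(report_path)

    summary = {
        "meta": meta,
        "fits": {
            b: {
                "rate_star": f.params.rate_star,
                "ks": f.params.ks,
                "ki": f.params.ki,
                "s_m": f.derived.s_m,
                "true_max": f.derived.true_max_rate,
                "overestimation_pct": overestimation_percent(f.params),
                "r2": f.r2,
                "r2_pearson": f.r2_pearson,
                "converged": f.converged,
                "n_points": f.n_points,
            }
            for b, f in bundle["fits"].items()
        },
        "skipped": skipped,
    }
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    bundle["paths"]["summary"] = str(summary_path)
    bundle["skipped"] = skipped
    return bundle
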