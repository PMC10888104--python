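"""End-to-end pipeline: generate -> extract -> measure -> analyze.

`run_phantom_series` performs one specimen's chain in memory (the unit the
acceptance analysis aggregates over); `run_pipeline` executes a whole
:class:`~bruise_evolve.config.RunConfig` with on-disk outputs, logging and
provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, extraction, io, metrics
from .config import PhantomConfig, RunConfig, scenario_config
from .phantom import PhantomSeries, render_series

logger = logging.getLogger("bruise_evolve")


@dataclass
class SeriesResult:
    """Measured trace plus intermediates for one specimen series."""

    scenario: str
    seed: int
    trace: pd.DataFrame
    extraction: extraction.ExtractionResult
    phantom: PhantomSeries
    surface: np.ndarray


def run_phantom_series(
    config: PhantomConfig,
    scenario: str = "upper",
    run: RunConfig | None = None,
) -> SeriesResult:
    """Render one phantom and run extraction + measurement on it."""
    rc = run or RunConfig(scenarios=[scenario], seeds=[config.seed])
    phantom = render_series(config)
    ext = extraction.extract_series(
        phantom.t_frames,
        c_frames=phantom.c_frames,
        mode=rc.correction_mode,
        reference_region=rc.reference_region,
        skin_row=config.skin_row,
        threshold_policy=rc.threshold_policy,
        morphology_radius=rc.morphology_radius,
        min_object_px=rc.min_object_px,
    )
    surface = metrics.surface_profile(phantom.t_frames[0])
    trace = metrics.measure_series(
        ext.zone_masks,
        ext.damage_masks,
        surface,
        config.times,
        config.pixel_scale,
        measurability_floor_mm=rc.measurability_floor_mm,
    )
    return SeriesResult(
        scenario=scenario, seed=config.seed, trace=trace,
        extraction=ext, phantom=phantom, surface=surface,
    )


def analyze_trace(trace: pd.DataFrame, run: RunConfig | None = None) -> dict:
    """Fit the growth law to a measured trace and derive the landmarks."""
    rc = run or RunConfig()
    fit = analysis.fit_logistic(trace["time_min"], trace["total_mm"])
    out = {
        "fit": {"model": fit.model, **fit.params,
                "r_squared": fit.r_squared, "p_value": fit.p_value},
    }
    if not fit.degenerate:
        rate = analysis.damage_rate(
            fit, t_max=float(trace["time_min"].max()),
            grid_step=rc.rate_grid_step,
        )
        out["max_rate_time_min"] = rate.t_star
        out["stabilization_time_min"] = analysis.stabilization_time(
            fit, frac=rc.stabilization_frac
        )
        out["peak_rate_mm_per_min"] = float(rate.rates.max())
    band_min, band_max, band_mean = analysis.proportion_band(trace)
    out["core_share"] = {"min": band_min, "max": band_max, "mean": band_mean}
    return out


def _mean_trace(traces: list[pd.DataFrame]) -> pd.DataFrame:
    """Average traces sharing a time grid (seed-averaged progression)."""
    stacked = pd.concat(traces).groupby("time_min", as_index=False).mean(
        numeric_only=True
    )
    # averaging turns the exclusion flag into a fraction; a frame stays
    # excluded when most seeds excluded it
    stacked["excluded"] = stacked["excluded"] >= 0.5
    return stacked


def run_pipeline(run: RunConfig) -> dict:
    """Execute every scenario x seed, write outputs, return the run report.

    Outputs under ``run.out_dir``: per-series trace CSVs and provenance
    JSON (and mask/frame PNGs when ``write_frames``), a resolved config
    YAML, and an aggregated ``results.json`` with per-series fits and the
    cross-scenario Pearson matrix.
    """
    out_dir = Path(run.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    run.to_yaml(str(out_dir / "run_config.yaml"))
    cfg_hash = run.config_hash()
    logging.basicConfig(level=logging.INFO)

    report: dict = {"config_hash": cfg_hash, "series": [], "scenarios": {}}
    scenario_traces: dict[str, list[pd.DataFrame]] = {}
    for scenario in run.scenarios:
        for seed in run.seeds:
            label = f"{scenario.replace(':', '')}_s{seed}"
            logger.info("pipeline: scenario=%s seed=%d", scenario, seed)
            overrides = {"pixel_scale": run.pixel_scale, **run.phantom_overrides}
            cfg = scenario_config(scenario, seed=seed, **overrides)
            try:
                res = run_phantom_series(cfg, scenario=scenario, run=run)
            except Exception:
                logger.exception(
                    "stage failed: scenario=%s seed=%d", scenario, seed
                )
                raise
            series_dir = out_dir / label
            series_dir.mkdir(exist_ok=True)
            io.write_trace(res.trace, series_dir / "trace.csv")
            io.write_json(
                {
                    "config_hash": cfg_hash,
                    "scenario": scenario,
                    "seed": seed,
                    "offsets": res.extraction.offsets.offsets,
                    "thresholds": res.extraction.thresholds,
                    "settings": res.extraction.settings,
                    "phantom": cfg.to_dict(),
                },
                series_dir / "provenance.json",
            )
            if run.write_frames:
                io.write_frames(res.phantom.t_frames, series_dir / "frames", label, "T")
                io.write_frames(res.phantom.c_frames, series_dir / "frames", label, "C")
                io.write_masks(res.extraction.zone_masks, series_dir / "masks", "zone")
                io.write_masks(res.extraction.damage_masks, series_dir / "masks", "damage")
            scenario_traces.setdefault(scenario, []).append(res.trace)
            entry = {"scenario": scenario, "seed": seed, "label": label}
            entry.update(analyze_trace(res.trace, run))
            report["series"].append(entry)

    for scenario, traces in scenario_traces.items():
        mean_tr = _mean_trace(traces)
        report["scenarios"][scenario] = analyze_trace(mean_tr, run)
    if len(scenario_traces) >= 2:
        labels = list(scenario_traces)
        comp = analysis.compare_progressions(
            [_mean_trace(scenario_traces[s]) for s in labels], labels=labels
        )
        report["pearson"] = {
            "labels": comp.labels,
            "matrix": comp.matrix,
            "min_off_diagonal": comp.min_off_diagonal(),
        }
    io.write_json(report, out_dir / "results.json")
    return report
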