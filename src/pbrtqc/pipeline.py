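"""End-to-end orchestration: data, split, scenarios, optimization, validation.

``run_experiment`` reproduces the whole study design on one analyte
stream: keep the most recent ``n_records`` results, split them
chronologically 1:1 into training and validation halves, inject the
step-bias scenario suite into both halves with shared segment layouts,
grid-search each algorithm on training, apply the two-stage selection,
and re-score the winner on validation with everything frozen.
``run_drift_sensitivity`` swaps the step scenarios for
baseline-drift-plateau ramps and re-scores the already-selected monitors
without any retuning.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import injection, synthetic
from .exceptions import ConfigurationError, InputError
from .injection import ErrorScenario, SegmentLayout
from .metrics import DEFAULT_WEIGHTS, MEWeights, PerformanceSummary
from .monitors import plot_control_chart
from .optimize import (
    GridResult,
    ParameterGrid,
    TrainingContext,
    build_grid,
    make_training_context,
    reduced_grid,
    results_table,
    run_grid,
    two_stage_select,
    validate,
)
from .preprocessing import AnalyteSeries, read_results

__all__ = [
    "RunConfig",
    "AlgorithmResult",
    "ExperimentReport",
    "chronological_split",
    "run_experiment",
    "run_drift_sensitivity",
    "write_report",
]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one experiment run."""

    preset: synthetic.AnalytePreset | None = None
    input_path: str | None = None
    n_records: int = 7000
    split_ratio: float = 0.5
    magnitudes: tuple[float, ...] = injection.DEFAULT_MAGNITUDES
    n_segments: int = 5
    length_range: tuple[int, int] = injection.DEFAULT_LENGTH_RANGE
    gap_range: tuple[int, int] = injection.DEFAULT_GAP_RANGE
    seed: int = 0
    algorithms: tuple[str, ...] = ("MA", "MQ", "EWMA")
    grid_preset: str = "full"
    grid_overrides: Mapping[str, Mapping[str, tuple]] = field(default_factory=dict)
    weights: MEWeights = DEFAULT_WEIGHTS
    retain: float | int = 0.05
    min_retain: int = 20
    n_jobs: int | None = 1

    def __post_init__(self) -> None:
        if (self.preset is None) == (self.input_path is None):
            raise ConfigurationError("exactly one of preset or input_path is required")
        if not 0.0 < self.split_ratio < 1.0:
            raise ConfigurationError("split_ratio must lie strictly in (0, 1)")
        if self.grid_preset not in ("full", "reduced"):
            raise ConfigurationError("grid_preset must be 'full' or 'reduced'")


@dataclass(frozen=True)
class AlgorithmResult:
    """Outcome of one algorithm's optimization + validation."""

    algorithm: str
    selected: GridResult
    validation: PerformanceSummary
    grid_results: tuple[GridResult, ...] = field(repr=False, default=())


@dataclass(frozen=True)
class ExperimentReport:
    """Full run state, sufficient to re-derive every exported number."""

    config: RunConfig
    series: AnalyteSeries
    train: AnalyteSeries
    valid: AnalyteSeries
    layouts: Mapping[float, SegmentLayout]
    train_suite: tuple[ErrorScenario, ...]
    valid_suite: tuple[ErrorScenario, ...]
    context: TrainingContext
    algorithms: tuple[AlgorithmResult, ...]
    seeds: Mapping[str, int]


def chronological_split(
    series: AnalyteSeries, ratio: float = 0.5
) -> tuple[AnalyteSeries, AnalyteSeries]:
    """Split into (training, validation) halves with no shuffling.

    The first ``floor(ratio * n)`` records form the training half; the
    remainder the validation half.  Either half being empty is a
    configuration error.
    """
    n = len(series)
    if n < 2:
        raise InputError("need at least 2 records to split")
    k = int(np.floor(ratio * n))
    if k < 1 or k >= n:
        raise ConfigurationError("split leaves an empty half")

    def _slice(lo: int, hi: int) -> AnalyteSeries:
        return AnalyteSeries(
            values=series.values[lo:hi],
            timestamps=None if series.timestamps is None else series.timestamps[lo:hi],
            instrument=series.instrument,
        )

    return _slice(0, k), _slice(k, n)


def _derive_seeds(seed: int) -> dict[str, int]:
    """Named sub-seeds (data synthesis, layouts, tie-breaks) from one seed."""
    rng = np.random.default_rng(seed)
    return {
        "data": int(rng.integers(2**31)),
        "layouts": int(rng.integers(2**31)),
        "misc": int(rng.integers(2**31)),
    }


def _load_series(config: RunConfig, seeds: Mapping[str, int]) -> AnalyteSeries:
    if config.preset is not None:
        preset = dataclasses.replace(
            config.preset, n=config.n_records, seed=seeds["data"]
        )
        return synthetic.generate_analyte(preset)
    series = read_results(config.input_path)
    if len(series) > config.n_records:
        # keep the most recent n_records in chronological order
        start = len(series) - config.n_records
        series = AnalyteSeries(
            values=series.values[start:],
            timestamps=None if series.timestamps is None else series.timestamps[start:],
            instrument=series.instrument,
        )
    return series


def _grid_for(config: RunConfig, algorithm: str) -> ParameterGrid:
    overrides = dict(config.grid_overrides.get(algorithm, {}))
    factory = reduced_grid if config.grid_preset == "reduced" else build_grid
    return factory(algorithm, **overrides)


def run_experiment(config: RunConfig) -> ExperimentReport:
    """Execute the full training/validation experiment for every algorithm."""
    seeds = _derive_seeds(config.seed)
    series = _load_series(config, seeds)
    train, valid = chronological_split(series, config.split_ratio)
    n_half = min(len(train), len(valid))
    if len(valid) > n_half:
        valid = AnalyteSeries(values=valid.values[:n_half], instrument=valid.instrument)
    if len(train) > n_half:
        raise ConfigurationError(
            "training half longer than validation half; use a split that "
            "gives len(train) <= len(valid)"
        )
    layouts = injection.build_layouts(
        n_total=len(train),
        magnitudes=config.magnitudes,
        seed=seeds["layouts"],
        n_segments=config.n_segments,
        length_range=config.length_range,
        gap_range=config.gap_range,
    )
    train_suite = injection.build_scenario_suite(
        train, layout_per_magnitude=layouts, magnitudes=config.magnitudes
    )
    valid_suite = injection.build_scenario_suite(
        valid, layout_per_magnitude=layouts, magnitudes=config.magnitudes
    )
    context = make_training_context(train)
    algo_results = []
    for algorithm in config.algorithms:
        grid = _grid_for(config, algorithm)
        results = run_grid(
            grid, train_suite, context, config.weights, n_jobs=config.n_jobs
        )
        selected = two_stage_select(results, config.retain, config.min_retain)
        summary = validate(selected, valid_suite, config.weights)
        algo_results.append(
            AlgorithmResult(
                algorithm=algorithm,
                selected=selected,
                validation=summary,
                grid_results=tuple(results),
            )
        )
    return ExperimentReport(
        config=config,
        series=series,
        train=train,
        valid=valid,
        layouts=layouts,
        train_suite=tuple(train_suite),
        valid_suite=tuple(valid_suite),
        context=context,
        algorithms=tuple(algo_results),
        seeds=seeds,
    )


def run_drift_sensitivity(
    report: ExperimentReport,
    baseline_bias: float = 0.02,
    ramp_length: int = 100,
) -> pd.DataFrame:
    """Re-score the selected monitors on baseline-drift-plateau scenarios.

    Drift scenarios replace the step scenarios on the same layouts and
    validation half; the selected configurations, transforms, truncation
    bounds and limits are applied unchanged.  Returns a step-vs-drift
    comparison table, one row per algorithm and error model.
    """
    if not report.algorithms:
        raise InputError("report contains no selected configurations")
    ramp = min(ramp_length, min(min(l.lengths) for l in report.layouts.values()))
    drift_suite = injection.build_drift_suite(
        report.valid,
        layout_per_magnitude=report.layouts,
        magnitudes=report.config.magnitudes,
        baseline_bias=baseline_bias,
        ramp_length=ramp,
    )
    rows = []
    for algo in report.algorithms:
        drift_summary = validate(algo.selected, drift_suite, report.config.weights)
        for label, s in (("step", algo.validation), ("drift", drift_summary)):
            rows.append(
                {
                    "algorithm": algo.algorithm,
                    "error_model": label,
                    "ME_Score": s.me_score,
                    "Sensitivity": s.sensitivity,
                    "False-Positive Rate": s.fpr,
                    "MNPed": s.mnped if s.mnped is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _selected_table(report: ExperimentReport) -> pd.DataFrame:
    rows = []
    for algo in report.algorithms:
        c = algo.selected.config
        for label, s in (
            ("Training Set", algo.selected.training),
            ("Validation Set", algo.validation),
        ):
            rows.append(
                {
                    "Algorithm": algo.algorithm,
                    "Window": c.window,
                    "Quantile": c.quantile,
                    "Lambda": c.smoothing,
                    "Upper limit Multiplier (a)": c.upper_multiplier,
                    "Lower limit Multiplier (b)": c.lower_multiplier,
                    "Truncation Factor": c.truncation_factor,
                    "Consecutive Alarm Points": c.consecutive_k,
                    "Data": label,
                    "ME_Score": s.me_score,
                    "Sensitivity": s.sensitivity,
                    "False-Positive Rate": s.fpr,
                    "MNPed": s.mnped if s.mnped is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _selected_json(report: ExperimentReport) -> dict:
    out: dict = {"seeds": dict(report.seeds)}
    for algo in report.algorithms:
        f = algo.selected.fitted
        out[algo.algorithm] = {
            "config": dataclasses.asdict(f.config),
            "transform": dataclasses.asdict(f.transform),
            "truncation": dataclasses.asdict(f.truncation),
            "limits": dataclasses.asdict(f.limits),
        }
    return out


def write_report(
    report: ExperimentReport, outdir: str | Path, charts: bool = False
) -> Path:
    """Export all tables (and optionally control charts) for a run.

    Writes: the layout summary for both halves, per-algorithm full grid
    tables, the selected-configuration table, per-scenario metric tables,
    a JSON snapshot of the frozen selected monitors, and a plain-text
    key=value run configuration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    injection.summarize_layouts(report.train_suite).to_csv(
        outdir / "layout_summary_training.csv"
    )
    injection.summarize_layouts(report.valid_suite).to_csv(
        outdir / "layout_summary_validation.csv"
    )
    _selected_table(report).to_csv(outdir / "selected_configurations.csv", index=False)
    for algo in report.algorithms:
        results_table(algo.grid_results).to_csv(
            outdir / f"grid_{algo.algorithm}.csv", index=False
        )
        per_scen = {
            f"train:{s.name}": s for s in algo.selected.training.per_scenario
        } | {f"valid:{s.name}": s for s in algo.validation.per_scenario}
        pd.DataFrame(
            [
                {
                    "scenario": label,
                    "ME_Score": s.me_score,
                    "Sensitivity": s.sensitivity,
                    "False-Positive Rate": s.fpr,
                    "MNPed": s.mnped if s.mnped is not None else np.nan,
                    "Detected Segments": s.detected_segments,
                    "Total Segments": s.total_segments,
                }
                for label, s in per_scen.items()
            ]
        ).to_csv(outdir / f"scenario_metrics_{algo.algorithm}.csv", index=False)
        if charts:
            for sc in report.valid_suite:
                trace = algo.selected.fitted.monitor(sc.values)
                plot_control_chart(
                    trace,
                    error_flag=sc.error_flag,
                    title=f"{algo.algorithm} {sc.name}",
                    path=outdir / f"chart_{algo.algorithm}_{sc.name}.png",
                )
    with open(outdir / "selected_monitors.json", "w") as fh:
        json.dump(_selected_json(report), fh, indent=2)
    with open(outdir / "run_config.txt", "w") as fh:
        cfg = report.config
        for key in (
            "n_records",
            "split_ratio",
            "magnitudes",
            "n_segments",
            "length_range",
            "gap_range",
            "seed",
            "algorithms",
            "grid_preset",
            "retain",
            "min_retain",
        ):
            fh.write(f"{key}={getattr(cfg, key)}\n")
        if cfg.preset is not None:
            fh.write(f"preset={cfg.preset.name}\n")
        if cfg.input_path is not None:
            fh.write(f"input_path={cfg.input_path}\n")
        for name, value in report.seeds.items():
            fh.write(f"seed_{name}={value}\n")
    return outdir
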