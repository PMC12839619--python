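"""Grid search, composite-score ranking and two-stage selection.

Every candidate parameter combination is pushed through the full
transform-truncate-alarm pipeline on the training scenario suite, scored
with the aggregated composite metric, and ranked.  Selection is
two-stage: the top slice by ME_Score is retained, then re-sorted by the
clinically ordered criteria (lowest FPR, then highest sensitivity, then
shortest MNPed) and the head wins.  Everything fitted on training
(transform, truncation bounds, control limits) is frozen and reused
unchanged on validation streams.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DegenerateDataError, OptimizationError
from .injection import ErrorScenario
from .metrics import DEFAULT_WEIGHTS, MEWeights, PerformanceSummary, aggregate, score_scenario
from .monitors import (
    AlarmTrace,
    ControlLimits,
    MonitorConfig,
    compute_statistic,
    detect_alarms,
    fit_limits,
)
from .preprocessing import (
    AnalyteSeries,
    TransformSpec,
    TruncationRule,
    estimate_transform,
    fit_truncation,
    transform_values,
    winsorize_values,
)

__all__ = [
    "ParameterGrid",
    "GridResult",
    "FittedMonitor",
    "TrainingContext",
    "build_grid",
    "reduced_grid",
    "make_training_context",
    "evaluate_config",
    "run_grid",
    "two_stage_select",
    "validate",
    "results_table",
]

# default search ranges, overridable per field
_DEFAULTS = {
    "windows": (3, 5, 10, 20, 50),
    "quantiles": (0.25, 0.5, 0.75),
    "smoothings": (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    "truncation_factors": (0.0, 0.01, 0.02, 0.05),
    "upper_multipliers": (1.64, 1.96, 2.58, 3.0),
    "lower_multipliers": (1.64, 1.96, 2.58, 3.0),
    "consecutive_ks": (1, 3, 5, 10),
}

_REDUCED = {
    "windows": (3, 5, 10),
    "quantiles": (0.5,),
    "smoothings": (0.5, 0.7, 0.9),
    "truncation_factors": (0.0, 0.02),
    "upper_multipliers": (1.96, 3.0),
    "lower_multipliers": (1.96, 3.0),
    "consecutive_ks": (3, 5),
}


@dataclass(frozen=True)
class ParameterGrid:
    """Per-algorithm value lists spanning a finite Cartesian product."""

    algorithm: str
    windows: tuple[int, ...] = ()
    quantiles: tuple[float, ...] = ()
    smoothings: tuple[float, ...] = ()
    truncation_factors: tuple[float, ...] = (0.0,)
    upper_multipliers: tuple[float, ...] = (3.0,)
    lower_multipliers: tuple[float, ...] = (3.0,)
    consecutive_ks: tuple[int, ...] = (1,)

    def _axes(self) -> list[tuple[str, tuple]]:
        axes: list[tuple[str, tuple]] = []
        if self.algorithm in ("MA", "MQ"):
            axes.append(("window", self.windows))
        if self.algorithm == "MQ":
            axes.append(("quantile", self.quantiles))
        if self.algorithm == "EWMA":
            axes.append(("smoothing", self.smoothings))
        axes.append(("truncation_factor", self.truncation_factors))
        axes.append(("upper_multiplier", self.upper_multipliers))
        axes.append(("lower_multiplier", self.lower_multipliers))
        axes.append(("consecutive_k", self.consecutive_ks))
        for name, values in axes:
            if len(values) == 0:
                raise ConfigurationError(f"empty value list for {name}")
        return axes

    def __len__(self) -> int:
        return math.prod(len(v) for _, v in self._axes())

    def configs(self) -> Iterator[MonitorConfig]:
        axes = self._axes()
        names = [n for n, _ in axes]
        for combo in itertools.product(*(v for _, v in axes)):
            yield MonitorConfig(algorithm=self.algorithm, **dict(zip(names, combo)))


def build_grid(algorithm: str, **overrides) -> ParameterGrid:
    """Default search grid for one algorithm; overrides replace any list."""
    fields = {k: tuple(overrides.get(k, v)) for k, v in _DEFAULTS.items()}
    grid = ParameterGrid(algorithm=algorithm, **fields)
    grid._axes()  # validate now
    return grid


def reduced_grid(algorithm: str, **overrides) -> ParameterGrid:
    """A small grid for fast runs; still contains the strong corner
    (smoothing 0.9, a=b=3, truncation 0, k=5) for EWMA."""
    fields = {k: tuple(overrides.get(k, v)) for k, v in _REDUCED.items()}
    grid = ParameterGrid(algorithm=algorithm, **fields)
    grid._axes()
    return grid


@dataclass(frozen=True)
class FittedMonitor:
    """Everything frozen from training needed to monitor a new stream."""

    config: MonitorConfig
    transform: TransformSpec
    truncation: TruncationRule
    limits: ControlLimits

    def monitor(self, values: np.ndarray) -> AlarmTrace:
        """Run transform -> truncate -> statistic -> alarms on raw values."""
        t = transform_values(np.asarray(values, dtype=float), self.transform)
        w = winsorize_values(t, self.truncation)
        stat = compute_statistic(w, self.config)
        return detect_alarms(stat, self.limits, self.config.consecutive_k)


@dataclass
class TrainingContext:
    """Shared, config-independent state fitted once per training stream."""

    train: AnalyteSeries
    transform: TransformSpec
    train_transformed: np.ndarray
    _rules: dict[float, TruncationRule] = field(default_factory=dict)
    _scenario_cache: dict[int, np.ndarray] = field(default_factory=dict)

    def truncation_rule(self, factor: float) -> TruncationRule:
        if factor not in self._rules:
            self._rules[factor] = fit_truncation(self.train_transformed, factor)
        return self._rules[factor]

    def transformed_scenario(self, scenario: ErrorScenario) -> np.ndarray:
        key = id(scenario)
        if key not in self._scenario_cache:
            self._scenario_cache[key] = transform_values(scenario.values, self.transform)
        return self._scenario_cache[key]


def make_training_context(
    train: AnalyteSeries, transform: TransformSpec | None = None
) -> TrainingContext:
    if transform is None:
        transform = estimate_transform(train)
    return TrainingContext(
        train=train,
        transform=transform,
        train_transformed=transform_values(train.values, transform),
    )


@dataclass(frozen=True)
class GridResult:
    """One evaluated configuration with its training summary and rank."""

    config: MonitorConfig
    training: PerformanceSummary | None
    fitted: FittedMonitor | None
    failed: bool = False
    error: str | None = None
    rank: int | None = None


def evaluate_config(
    config: MonitorConfig,
    scenarios: Sequence[ErrorScenario],
    context: TrainingContext,
    weights: MEWeights = DEFAULT_WEIGHTS,
) -> GridResult:
    """Run the full monitor+metrics pipeline for one configuration.

    Control limits come from the bias-free training stream processed with
    the same truncation and statistic.  Degenerate configurations (zero
    statistic SD) are recorded as failed with a diagnostic rather than
    dropped silently.
    """
    try:
        rule = context.truncation_rule(config.truncation_factor)
        train_w = winsorize_values(context.train_transformed, rule)
        train_stat = compute_statistic(train_w, config)
        limits = fit_limits(
            train_stat, config.upper_multiplier, config.lower_multiplier
        )
    except (DegenerateDataError, ConfigurationError) as exc:
        return GridResult(config=config, training=None, fitted=None, failed=True, error=str(exc))
    fitted = FittedMonitor(config=config, transform=context.transform, truncation=rule, limits=limits)
    per_scenario = []
    for sc in scenarios:
        w = winsorize_values(context.transformed_scenario(sc), rule)
        stat = compute_statistic(w, config)
        trace = detect_alarms(stat, limits, config.consecutive_k)
        per_scenario.append(score_scenario(trace, sc, weights))
    return GridResult(
        config=config,
        training=aggregate(per_scenario, weights),
        fitted=fitted,
    )


def run_grid(
    grid: ParameterGrid,
    scenarios: Sequence[ErrorScenario],
    context: TrainingContext,
    weights: MEWeights = DEFAULT_WEIGHTS,
    n_jobs: int | None = 1,
) -> list[GridResult]:
    """Evaluate every configuration and rank by training ME_Score.

    The evaluation is a pure map over configurations (no shared mutable
    state), so results are identical regardless of order or worker count.
    Failed configurations rank last.  ``n_jobs=None`` uses all available
    processors via joblib.
    """
    configs = list(grid.configs())
    if n_jobs == 1:
        results = [evaluate_config(c, scenarios, context, weights) for c in configs]
    else:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs if n_jobs is not None else -1)(
            delayed(evaluate_config)(c, scenarios, context, weights) for c in configs
        )
    ranked = sorted(
        results,
        key=lambda r: (
            r.failed,
            -(r.training.me_score if r.training is not None else -np.inf),
            r.config.sort_key(),
        ),
    )
    return [replace(r, rank=i + 1) for i, r in enumerate(ranked)]


def _stage2_key(result: GridResult, fpr_granularity: float) -> tuple:
    s = result.training
    return (
        round(s.fpr / fpr_granularity),
        -s.sensitivity,
        s.mnped if s.mnped is not None else np.inf,
        result.config.sort_key(),
    )


def two_stage_select(
    results: Sequence[GridResult],
    retain: float | int = 0.05,
    min_retain: int = 20,
    fpr_granularity: float = 1e-3,
) -> GridResult:
    """Pick the recommended configuration from ranked grid results.

    Stage 1 retains the top slice by ME_Score (a fraction when ``retain``
    < 1, else a count; never fewer than ``min_retain``).  Stage 2 sorts
    the retained slice lexicographically by (FPR ascending, sensitivity
    descending, MNPed ascending, config fields) and returns the head.

    FPR is compared at ``fpr_granularity`` resolution (default 1e-3, the
    operationally acceptable false-alarm tolerance in high-frequency
    monitoring).  A finite suite cannot resolve FPR below one alarm per
    evaluation, so raw comparison would let sampling zeros outrank
    configurations that are both far more sensitive and operationally
    indistinguishable on false alarms — including pathological monitors
    whose truncation clamp sits inside one control limit, making them
    blind to an entire error direction.
    """
    usable = [r for r in results if not r.failed and r.training is not None]
    if not usable:
        raise OptimizationError("every configuration failed; nothing to select")
    usable.sort(key=lambda r: -r.training.me_score)
    if isinstance(retain, float) and retain < 1:
        keep = max(min_retain, math.ceil(retain * len(usable)))
    else:
        keep = max(min_retain, int(retain))
    if fpr_granularity <= 0:
        raise ConfigurationError("fpr_granularity must be positive")
    retained = usable[: min(keep, len(usable))]
    retained.sort(key=lambda r: _stage2_key(r, fpr_granularity))
    return retained[0]


def validate(
    selected: GridResult | FittedMonitor,
    scenarios: Sequence[ErrorScenario],
    weights: MEWeights = DEFAULT_WEIGHTS,
) -> PerformanceSummary:
    """Recompute metrics on a validation suite with training-frozen state.

    No transform re-estimation, no new truncation bounds, no limit
    refitting — the monitor is applied exactly as selected.
    """
    if not scenarios:
        raise OptimizationError("empty validation scenario list")
    fitted = selected.fitted if isinstance(selected, GridResult) else selected
    if fitted is None:
        raise OptimizationError("selected configuration has no fitted monitor")
    per_scenario = [
        score_scenario(fitted.monitor(sc.values), sc, weights) for sc in scenarios
    ]
    return aggregate(per_scenario, weights)


def results_table(results: Sequence[GridResult]) -> pd.DataFrame:
    """Flatten ranked grid results for delimited-text export."""
    rows = []
    for r in results:
        c = r.config
        row = {
            "rank": r.rank,
            "algorithm": c.algorithm,
            "window": c.window,
            "quantile": c.quantile,
            "smoothing": c.smoothing,
            "truncation_factor": c.truncation_factor,
            "upper_multiplier": c.upper_multiplier,
            "lower_multiplier": c.lower_multiplier,
            "consecutive_k": c.consecutive_k,
            "failed": r.failed,
            "error": r.error,
        }
        if r.training is not None:
            row.update(
                {
                    "ME_Score": r.training.me_score,
                    "Sensitivity": r.training.sensitivity,
                    "False-Positive Rate": r.training.fpr,
                    "MNPed": r.training.mnped,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
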