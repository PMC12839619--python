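"""Detection-performance metrics and the composite ME_Score.

An alarm trace is scored against a labelled error scenario along three
axes with distinct clinical meaning: sensitivity (how much of the biased
stream is flagged), false-positive rate (alarm burden on clean results)
and detection delay (MNPed — the median number of patients between error
onset and the attributed start of the first detecting alarm run).  The
composite objective

    ME_Score = 0.0005 * Sensitivity + 0.999 * (1 - FPR)
               - 0.0005 * Sigmoid(MNPed)

with ``Sigmoid(m) = 1 / (1 + exp(-0.05 * (m - 101)))`` dominates on the
false-positive term — reflecting that alarm fatigue, not missed shifts,
is the practical failure mode of high-frequency monitoring — while the
logistic delay penalty (centered at 101 patients) discounts slow
detections smoothly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError
from .injection import ErrorScenario
from .monitors import AlarmTrace

__all__ = [
    "MEWeights",
    "SegmentDetection",
    "ScenarioMetrics",
    "PerformanceSummary",
    "segment_detections",
    "sensitivity",
    "false_positive_rate",
    "mnped",
    "sigmoid_penalty",
    "me_score",
    "score_scenario",
    "aggregate",
]


@dataclass(frozen=True)
class MEWeights:
    """Weights and delay-penalty shape of the composite score."""

    w_sens: float = 0.0005
    w_fpr: float = 0.999
    w_delay: float = 0.0005
    sigmoid_slope: float = 0.05
    sigmoid_center: float = 101.0


DEFAULT_WEIGHTS = MEWeights()


@dataclass(frozen=True)
class SegmentDetection:
    """Detection outcome for one injected error segment."""

    segment_index: int
    start: int
    length: int
    detected: bool
    delay: int | None


@dataclass(frozen=True)
class ScenarioMetrics:
    """All per-scenario quantities needed for ranking and aggregation."""

    name: str
    sensitivity: float
    fpr: float
    mnped: float | None
    detected_segments: int
    total_segments: int
    delays: tuple[int, ...]
    missed_lengths: tuple[int, ...]
    me_score: float


@dataclass(frozen=True)
class PerformanceSummary:
    """Cross-scenario aggregate of a monitor configuration.

    ``sensitivity`` and ``fpr`` are unweighted means over scenarios;
    ``mnped`` is the median of per-segment delays pooled across all
    scenarios' detected segments; ``me_score`` is computed from that
    aggregated triple ("aggregate-then-score"), while
    ``me_score_scenario_mean`` averages the per-scenario scores instead
    ("score-then-average").
    """

    sensitivity: float
    fpr: float
    mnped: float | None
    me_score: float
    me_score_scenario_mean: float
    per_scenario: tuple[ScenarioMetrics, ...] = field(default=(), repr=False)


def _check_alignment(trace: AlarmTrace, scenario: ErrorScenario) -> None:
    if trace.statistic.size != scenario.layout.n_total:
        raise InputError("trace and scenario cover different stream lengths")


def segment_detections(
    trace: AlarmTrace, scenario: ErrorScenario
) -> list[SegmentDetection]:
    """Per-segment detection flags and delays.

    A segment counts as detected when at least one alarm-run START index
    falls inside it; the delay is the earliest such start minus the
    segment start, so a run beginning exactly at error onset has delay 0.
    Runs that start in a gap and merely extend into a segment do not
    count.
    """
    _check_alignment(trace, scenario)
    run_starts = np.asarray([start for start, _ in trace.alarm_runs], dtype=int)
    out = []
    for i, (start, length) in enumerate(scenario.layout.segments, start=1):
        inside = run_starts[(run_starts >= start) & (run_starts < start + length)]
        if inside.size:
            out.append(
                SegmentDetection(
                    segment_index=i,
                    start=start,
                    length=length,
                    detected=True,
                    delay=int(inside.min() - start),
                )
            )
        else:
            out.append(
                SegmentDetection(
                    segment_index=i, start=start, length=length, detected=False, delay=None
                )
            )
    return out


def sensitivity(
    trace: AlarmTrace, scenario: ErrorScenario, mode: str = "observation"
) -> float:
    """True-positive rate on the biased stream.

    ``observation`` mode (default): alarmed-and-biased observations over
    all biased observations.  ``segment`` mode: detected segments over
    total segments.  Warm-up positions (undefined statistic) are excluded
    from both numerator and denominator.
    """
    _check_alignment(trace, scenario)
    if mode == "segment":
        det = segment_detections(trace, scenario)
        if not det:
            raise InputError("scenario has no error segments")
        return sum(d.detected for d in det) / len(det)
    if mode != "observation":
        raise InputError(f"unknown sensitivity mode {mode!r}")
    biased = scenario.error_flag & trace.defined
    denom = int(biased.sum())
    if denom == 0:
        raise InputError("scenario has no biased observations after warm-up")
    return float((trace.alarmed & biased).sum() / denom)


def false_positive_rate(trace: AlarmTrace, scenario: ErrorScenario) -> float:
    """Fraction of unbiased (post-warm-up) observations that alarmed."""
    _check_alignment(trace, scenario)
    unbiased = ~scenario.error_flag & trace.defined
    denom = int(unbiased.sum())
    if denom == 0:
        raise InputError("scenario has no unbiased observations after warm-up")
    return float((trace.alarmed & unbiased).sum() / denom)


def mnped(
    detections: Sequence[SegmentDetection], policy: str = "detected_only"
) -> float | None:
    """Median number of patients before error detection.

    ``detected_only`` (default): median of delays over detected segments,
    ``None`` when nothing was detected.  ``penalize_missed``: missed
    segments contribute their full length as the delay.
    """
    if not detections:
        raise InputError("no segments to summarize")
    if policy == "detected_only":
        delays = [d.delay for d in detections if d.detected]
    elif policy == "penalize_missed":
        delays = [d.delay if d.detected else d.length for d in detections]
    else:
        raise InputError(f"unknown MNPed policy {policy!r}")
    if not delays:
        return None
    return float(np.median(delays))


def sigmoid_penalty(value: float, weights: MEWeights = DEFAULT_WEIGHTS) -> float:
    """Logistic delay penalty in (0, 1); 0.5 exactly at the center."""
    if value is None or not math.isfinite(value):
        raise InputError("sigmoid_penalty requires a finite MNPed")
    return 1.0 / (1.0 + math.exp(-weights.sigmoid_slope * (value - weights.sigmoid_center)))


def me_score(
    sens: float,
    fpr: float,
    mnped_value: float | None,
    weights: MEWeights = DEFAULT_WEIGHTS,
) -> float:
    """Composite score; an undefined MNPed takes the maximal delay penalty.

    Nothing detected must never score better than slow detection, so a
    ``None`` MNPed contributes sigmoid = 1.
    """
    if not 0.0 <= sens <= 1.0 or not 0.0 <= fpr <= 1.0:
        raise InputError("sensitivity and FPR must lie in [0, 1]")
    penalty = 1.0 if mnped_value is None else sigmoid_penalty(mnped_value, weights)
    return weights.w_sens * sens + weights.w_fpr * (1.0 - fpr) - weights.w_delay * penalty


def score_scenario(
    trace: AlarmTrace,
    scenario: ErrorScenario,
    weights: MEWeights = DEFAULT_WEIGHTS,
    sensitivity_mode: str = "observation",
    mnped_policy: str = "detected_only",
) -> ScenarioMetrics:
    """Compute every per-scenario metric for one trace/scenario pair."""
    det = segment_detections(trace, scenario)
    sens = sensitivity(trace, scenario, mode=sensitivity_mode)
    fpr = false_positive_rate(trace, scenario)
    m = mnped(det, policy=mnped_policy)
    return ScenarioMetrics(
        name=scenario.name,
        sensitivity=sens,
        fpr=fpr,
        mnped=m,
        detected_segments=sum(d.detected for d in det),
        total_segments=len(det),
        delays=tuple(d.delay for d in det if d.detected),
        missed_lengths=tuple(d.length for d in det if not d.detected),
        me_score=me_score(sens, fpr, m, weights),
    )


def aggregate(
    per_scenario: Sequence[ScenarioMetrics],
    weights: MEWeights = DEFAULT_WEIGHTS,
    mnped_policy: str = "detected_only",
) -> PerformanceSummary:
    """Aggregate scenario metrics into one summary.

    Sensitivity and FPR are averaged across scenarios; MNPed is the
    median of the pooled per-segment delays (optionally substituting
    segment lengths for missed segments).
    """
    if not per_scenario:
        raise InputError("no scenarios to aggregate")
    sens = float(np.mean([s.sensitivity for s in per_scenario]))
    fpr = float(np.mean([s.fpr for s in per_scenario]))
    pooled: list[float] = []
    for s in per_scenario:
        pooled.extend(s.delays)
        if mnped_policy == "penalize_missed":
            pooled.extend(s.missed_lengths)
    pooled_mnped = float(np.median(pooled)) if pooled else None
    return PerformanceSummary(
        sensitivity=sens,
        fpr=fpr,
        mnped=pooled_mnped,
        me_score=me_score(sens, fpr, pooled_mnped, weights),
        me_score_scenario_mean=float(np.mean([s.me_score for s in per_scenario])),
        per_scenario=tuple(per_scenario),
    )


def metrics_table(summaries: dict[str, PerformanceSummary]) -> pd.DataFrame:
    """Tabulate summaries (rows keyed by label) for delimited-text export."""
    rows = []
    for label, s in summaries.items():
        rows.append(
            {
                "label": label,
                "ME_Score": s.me_score,
                "Sensitivity": s.sensitivity,
                "False-Positive Rate": s.fpr,
                "MNPed": s.mnped if s.mnped is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)
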