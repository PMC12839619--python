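"""Systematic-error injection: stepwise biases and baseline-drift-plateau ramps.

A scenario is a copy of a bias-free stream with proportional systematic
error applied to a handful of contiguous segments, plus per-observation
labels (``error_flag``, ``segment_id``) so detection performance can be
scored exactly.  Bias is applied on the ORIGINAL measurement scale —
a "+30% bias" means every affected result is multiplied by 1.3 before any
transformation — because percent bias is only physically meaningful there.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError
from .preprocessing import AnalyteSeries

__all__ = [
    "SegmentLayout",
    "ErrorScenario",
    "DriftSpec",
    "DEFAULT_MAGNITUDES",
    "generate_segment_layout",
    "inject_step_bias",
    "inject_drift_bias",
    "build_scenario_suite",
    "build_drift_suite",
    "summarize_layouts",
    "write_scenario",
]

#: the five default bias magnitudes, applied in both directions
DEFAULT_MAGNITUDES: tuple[float, ...] = (0.10, 0.30, 0.50, 0.70, 0.90)

#: default error-segment length range (consecutive results, inclusive)
DEFAULT_LENGTH_RANGE: tuple[int, int] = (100, 300)

#: default inter-segment gap range (error-free results, inclusive)
DEFAULT_GAP_RANGE: tuple[int, int] = (250, 500)

#: alternative gap range (a named alternative layout convention)
WIDE_GAP_RANGE: tuple[int, int] = (550, 600)

#: leading error-free stretch is drawn uniformly from [0, this]
DEFAULT_MAX_LEAD = 100


@dataclass(frozen=True)
class SegmentLayout:
    """Placement of error segments inside a stream of ``n_total`` results.

    ``segments`` is an ordered list of 0-based half-open ``(start, length)``
    pairs; everything outside the segments is implicitly error-free.
    """

    n_total: int
    segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ConfigurationError("n_total must be positive")
        segs = tuple((int(s), int(l)) for s, l in self.segments)
        prev_end = 0
        for i, (start, length) in enumerate(segs):
            if length < 1:
                raise ConfigurationError("segment lengths must be positive")
            if start < prev_end:
                raise ConfigurationError("segments must be sorted and non-overlapping")
            if start + length > self.n_total:
                raise ConfigurationError("segment extends past the end of the stream")
            prev_end = start + length
        object.__setattr__(self, "segments", segs)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(l for _, l in self.segments)

    def gaps(self) -> tuple[int, ...]:
        """Error-free stretch sizes: leading, between each pair, trailing."""
        out = []
        prev_end = 0
        for start, length in self.segments:
            out.append(start - prev_end)
            prev_end = start + length
        out.append(self.n_total - prev_end)
        return tuple(out)

    def segment_id_array(self) -> np.ndarray:
        """Per-observation integer labels; 0 marks unbiased positions."""
        ids = np.zeros(self.n_total, dtype=int)
        for i, (start, length) in enumerate(self.segments, start=1):
            ids[start : start + length] = i
        return ids


@dataclass(frozen=True)
class ErrorScenario:
    """A biased copy of a stream with exact per-observation labels."""

    name: str
    magnitude: float
    direction: int
    values: np.ndarray
    error_flag: np.ndarray
    segment_id: np.ndarray
    layout: SegmentLayout

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ConfigurationError("direction must be +1 or -1")
        for name in ("values", "error_flag", "segment_id"):
            arr = getattr(self, name)
            if len(arr) != self.layout.n_total:
                raise InputError(f"{name} length does not match layout.n_total")


@dataclass(frozen=True)
class DriftSpec:
    """Baseline-drift-plateau error shape inside each segment.

    Bias starts at ``baseline_bias``, rises linearly to ``max_bias`` over
    ``ramp_length`` observations, and stays at ``max_bias`` for the rest
    of the segment — emulating progressive instrument deterioration or
    reagent degradation rather than an abrupt shift.
    """

    baseline_bias: float
    max_bias: float
    ramp_length: int

    def __post_init__(self) -> None:
        if self.baseline_bias < 0:
            raise ConfigurationError("baseline_bias must be non-negative")
        if self.max_bias < self.baseline_bias:
            raise ConfigurationError("max_bias must be >= baseline_bias")
        if self.ramp_length < 1:
            raise ConfigurationError("ramp_length must be positive")


def generate_segment_layout(
    n_total: int,
    n_segments: int = 5,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    gap_range: tuple[int, int] = DEFAULT_GAP_RANGE,
    seed: int | np.random.Generator = 0,
    max_lead: int = DEFAULT_MAX_LEAD,
    max_tries: int = 1000,
) -> SegmentLayout:
    """Draw a random but reproducible segment layout.

    Segment lengths are uniform on the closed ``length_range``; inner gaps
    uniform on ``gap_range``; the leading error-free stretch is uniform on
    ``[0, max_lead]`` and the trailing stretch absorbs whatever remains.
    Draws whose total exceeds ``n_total`` are rejected and redrawn, so the
    trailing gap is always the largest slack block.

    Raises
    ------
    ConfigurationError
        If even the minimal layout (zero lead, minimum lengths and gaps)
        cannot fit inside ``n_total``, or rejection never succeeds.
    """
    if n_segments < 1:
        raise ConfigurationError("n_segments must be positive")
    lo_len, hi_len = length_range
    lo_gap, hi_gap = gap_range
    if not (1 <= lo_len <= hi_len) or not (0 <= lo_gap <= hi_gap):
        raise ConfigurationError("invalid length_range or gap_range")
    minimal = n_segments * lo_len + (n_segments - 1) * lo_gap
    if minimal > n_total:
        raise ConfigurationError(
            f"infeasible geometry: {n_segments} segments of >= {lo_len} with gaps "
            f">= {lo_gap} need {minimal} > n_total={n_total}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(max_tries):
        lead = int(rng.integers(0, max_lead + 1))
        lengths = rng.integers(lo_len, hi_len + 1, size=n_segments)
        gaps = rng.integers(lo_gap, hi_gap + 1, size=n_segments - 1)
        if lead + lengths.sum() + gaps.sum() <= n_total:
            segments = []
            pos = lead
            for i in range(n_segments):
                segments.append((pos, int(lengths[i])))
                pos += int(lengths[i])
                if i < n_segments - 1:
                    pos += int(gaps[i])
            return SegmentLayout(n_total=n_total, segments=tuple(segments))
    raise ConfigurationError(
        f"could not place {n_segments} segments in {n_total} results "
        f"after {max_tries} attempts"
    )


def _scenario_name(direction: int, magnitude: float, kind: str = "error") -> str:
    word = "increase" if direction > 0 else "decrease"
    return f"{kind}_{word}_{round(magnitude * 100):d}"


def inject_step_bias(
    series: AnalyteSeries,
    layout: SegmentLayout,
    magnitude: float,
    direction: int,
) -> ErrorScenario:
    """Multiply on-segment values by ``1 + direction * magnitude``.

    Off-segment values are untouched, so the biased stream equals the
    source exactly outside the labelled segments.
    """
    if not 0.0 < magnitude < 1.0:
        raise ConfigurationError("magnitude must lie in (0, 1)")
    if direction not in (-1, 1):
        raise ConfigurationError("direction must be +1 or -1")
    if len(series) != layout.n_total:
        raise InputError("series length does not match layout.n_total")
    values = series.values.copy()
    segment_id = layout.segment_id_array()
    flag = segment_id > 0
    values[flag] *= 1.0 + direction * magnitude
    return ErrorScenario(
        name=_scenario_name(direction, magnitude),
        magnitude=magnitude,
        direction=direction,
        values=values,
        error_flag=flag,
        segment_id=segment_id,
        layout=layout,
    )


def inject_drift_bias(
    series: AnalyteSeries,
    layout: SegmentLayout,
    spec: DriftSpec,
    direction: int,
) -> ErrorScenario:
    """Apply the baseline-drift-plateau bias profile inside each segment.

    The per-observation bias fraction at 0-based in-segment position *i*
    is ``baseline + (max - baseline) * min(i, ramp) / ramp``, so the
    profile starts at the baseline deviation, climbs linearly, and holds
    at ``max_bias`` from position ``ramp_length`` onward.
    """
    if direction not in (-1, 1):
        raise ConfigurationError("direction must be +1 or -1")
    if len(series) != layout.n_total:
        raise InputError("series length does not match layout.n_total")
    if spec.ramp_length > min(layout.lengths):
        raise ConfigurationError(
            "ramp_length exceeds the shortest error segment"
        )
    values = series.values.copy()
    segment_id = layout.segment_id_array()
    flag = segment_id > 0
    for start, length in layout.segments:
        i = np.arange(length)
        frac = np.minimum(i, spec.ramp_length) / spec.ramp_length
        bias = spec.baseline_bias + (spec.max_bias - spec.baseline_bias) * frac
        values[start : start + length] *= 1.0 + direction * bias
    return ErrorScenario(
        name=_scenario_name(direction, spec.max_bias, kind="drift"),
        magnitude=spec.max_bias,
        direction=direction,
        values=values,
        error_flag=flag,
        segment_id=segment_id,
        layout=layout,
    )


def build_layouts(
    n_total: int,
    magnitudes: Sequence[float] = DEFAULT_MAGNITUDES,
    seed: int = 0,
    **layout_kwargs,
) -> dict[float, SegmentLayout]:
    """One independent layout per magnitude (shared by both directions)."""
    rng = np.random.default_rng(seed)
    return {
        m: generate_segment_layout(n_total, seed=rng, **layout_kwargs)
        for m in magnitudes
    }


def build_scenario_suite(
    series: AnalyteSeries,
    layout_per_magnitude: Mapping[float, SegmentLayout] | None = None,
    magnitudes: Sequence[float] = DEFAULT_MAGNITUDES,
    seed: int = 0,
    **layout_kwargs,
) -> list[ErrorScenario]:
    """Build the full step-bias suite: one scenario per (magnitude, direction).

    Scenarios of equal magnitude and opposite direction share a layout,
    so the increase/decrease rows of the layout summary are identical.
    With the default five magnitudes this yields exactly 10 scenarios.
    """
    if len(magnitudes) == 0:
        return []
    if layout_per_magnitude is None:
        layout_per_magnitude = build_layouts(
            len(series), magnitudes=magnitudes, seed=seed, **layout_kwargs
        )
    suite = []
    for m in magnitudes:
        layout = layout_per_magnitude[m]
        for direction in (-1, 1):
            suite.append(inject_step_bias(series, layout, m, direction))
    return suite


def build_drift_suite(
    series: AnalyteSeries,
    layout_per_magnitude: Mapping[float, SegmentLayout],
    magnitudes: Sequence[float] = DEFAULT_MAGNITUDES,
    baseline_bias: float = 0.02,
    ramp_length: int = 100,
) -> list[ErrorScenario]:
    """Drift analogue of :func:`build_scenario_suite` on shared layouts.

    Each magnitude becomes the plateau (``max_bias``) of a baseline-drift-
    plateau profile with the given baseline and ramp.
    """
    suite = []
    for m in magnitudes:
        layout = layout_per_magnitude[m]
        spec = DriftSpec(
            baseline_bias=min(baseline_bias, m), max_bias=m, ramp_length=ramp_length
        )
        for direction in (-1, 1):
            suite.append(inject_drift_bias(series, layout, spec, direction))
    return suite


def summarize_layouts(suite: Sequence[ErrorScenario]) -> pd.DataFrame:
    """Tabulate segment lengths and gaps, one row per scenario.

    Columns follow the conventional layout-summary shape: leading gap,
    then alternating segment counts and inter-segment gaps, then the
    trailing gap.  Every row sums to the stream length.
    """
    if len(suite) == 0:
        raise InputError("suite is empty")
    n_seg = suite[0].layout.n_segments
    columns = ["Gap-1"]
    for i in range(1, n_seg + 1):
        columns.append(f"Segment {i} Count")
        if i < n_seg:
            columns.append(f"Gap {i}-{i + 1}")
    columns.append(f"Gap {n_seg}-")
    rows = []
    for sc in suite:
        gaps = sc.layout.gaps()
        lengths = sc.layout.lengths
        row: list[int] = [gaps[0]]
        for i in range(n_seg):
            row.append(lengths[i])
            row.append(gaps[i + 1])
        rows.append(row)
    frame = pd.DataFrame(rows, columns=columns, index=[sc.name for sc in suite])
    frame.index.name = "Error Type"
    return frame


def write_scenario(scenario: ErrorScenario, path: str | Path) -> None:
    """Export one scenario as (index, value, error_flag, segment_id) text."""
    pd.DataFrame(
        {
            "index": np.arange(1, len(scenario.values) + 1),
            "value": scenario.values,
            "error_flag": scenario.error_flag.astype(int),
            "segment_id": scenario.segment_id,
        }
    ).to_csv(path, index=False)
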