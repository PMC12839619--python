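"""Monitoring statistics, control limits and the consecutive-alarm rule.

Three classical process-control statistics run over the preprocessed
stream: the trailing moving average (MA), the trailing moving quantile
(MQ) and the exponentially weighted moving average (EWMA,
``s_t = lam * x_t + (1 - lam) * s_{t-1}`` with ``s_1 = x_1``).  Control
limits are frozen from the bias-free training stream as
``mean ± multiplier × SD`` of the statistic's own empirical distribution,
with separate upper (a) and lower (b) multipliers, so values like 1.64,
1.96 and 3 behave as z-quantile multipliers.  An alarm fires only when
the statistic sits outside the limits for ``k`` consecutive results; the
run is retrospectively attributed to its first point.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DegenerateDataError, InputError

__all__ = [
    "ALGORITHMS",
    "MonitorConfig",
    "ControlLimits",
    "AlarmTrace",
    "compute_ma",
    "compute_mq",
    "compute_ewma",
    "compute_statistic",
    "fit_limits",
    "detect_alarms",
    "export_trace",
    "plot_control_chart",
]

ALGORITHMS = ("MA", "MQ", "EWMA")


@dataclass(frozen=True)
class MonitorConfig:
    """One complete parameter combination for a monitor.

    Algorithm-specific fields must be present exactly when required:
    ``window`` for MA and MQ, ``quantile`` for MQ only, ``smoothing``
    (the EWMA weight on the newest observation) for EWMA only.
    """

    algorithm: str
    window: int | None = None
    quantile: float | None = None
    smoothing: float | None = None
    truncation_factor: float = 0.0
    upper_multiplier: float = 3.0
    lower_multiplier: float = 3.0
    consecutive_k: int = 1

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(f"unknown algorithm {self.algorithm!r}")
        if self.algorithm in ("MA", "MQ"):
            if self.window is None or self.window < 1:
                raise ConfigurationError(f"{self.algorithm} requires window >= 1")
            if self.smoothing is not None:
                raise ConfigurationError(f"{self.algorithm} takes no smoothing constant")
        if self.algorithm == "MQ":
            if self.quantile is None or not 0.0 < self.quantile < 1.0:
                raise ConfigurationError("MQ requires quantile in (0, 1)")
        else:
            if self.quantile is not None:
                raise ConfigurationError(f"{self.algorithm} takes no quantile")
        if self.algorithm == "EWMA":
            if self.smoothing is None or not 0.0 < self.smoothing <= 1.0:
                raise ConfigurationError("EWMA requires smoothing in (0, 1]")
            if self.window is not None:
                raise ConfigurationError("EWMA takes no window")
        if not 0.0 <= self.truncation_factor < 0.5:
            raise ConfigurationError("truncation_factor must lie in [0, 0.5)")
        if self.upper_multiplier <= 0 or self.lower_multiplier <= 0:
            raise ConfigurationError("limit multipliers must be positive")
        if self.consecutive_k < 1:
            raise ConfigurationError("consecutive_k must be >= 1")

    def sort_key(self) -> tuple:
        """Deterministic total order over configs (tie-breaking)."""
        return (
            self.algorithm,
            self.window if self.window is not None else -1,
            self.quantile if self.quantile is not None else -1.0,
            self.smoothing if self.smoothing is not None else -1.0,
            self.truncation_factor,
            self.upper_multiplier,
            self.lower_multiplier,
            self.consecutive_k,
        )


@dataclass(frozen=True)
class ControlLimits:
    """Frozen control limits on the monitoring-statistic scale."""

    center: float
    stat_sd: float
    ucl: float
    lcl: float

    def __post_init__(self) -> None:
        if self.stat_sd < 0:
            raise ConfigurationError("stat_sd must be non-negative")
        if not self.lcl <= self.center <= self.ucl:
            raise ConfigurationError("limits must bracket the center")


@dataclass(frozen=True)
class AlarmTrace:
    """Monitoring statistic plus alarm bookkeeping for one stream.

    ``statistic`` is NaN during warm-up; ``outside`` flags points beyond
    the limits; ``alarm_runs`` lists maximal consecutive outside runs of
    length >= k as ``(start_index, length)``; ``alarmed`` marks every
    observation inside a qualifying run.
    """

    statistic: np.ndarray
    outside: np.ndarray
    alarm_runs: tuple[tuple[int, int], ...]
    alarmed: np.ndarray
    limits: ControlLimits
    consecutive_k: int

    @property
    def defined(self) -> np.ndarray:
        """Mask of positions where the statistic exists (post warm-up)."""
        return ~np.isnan(self.statistic)


def _check_window(n: int, window: int) -> None:
    if window < 1:
        raise ConfigurationError("window must be >= 1")
    if window > n:
        raise ConfigurationError(f"window {window} exceeds series length {n}")


def compute_ma(values: np.ndarray | Sequence[float], window: int) -> np.ndarray:
    """Trailing moving average; NaN for the first ``window - 1`` positions."""
    x = np.asarray(values, dtype=float)
    _check_window(x.size, window)
    return pd.Series(x).rolling(window).mean().to_numpy()


def compute_mq(
    values: np.ndarray | Sequence[float], window: int, quantile: float
) -> np.ndarray:
    """Trailing moving quantile (linear interpolation); NaN during warm-up."""
    x = np.asarray(values, dtype=float)
    _check_window(x.size, window)
    if not 0.0 < quantile < 1.0:
        raise ConfigurationError("quantile must lie in (0, 1)")
    return (
        pd.Series(x).rolling(window).quantile(quantile, interpolation="linear").to_numpy()
    )


def compute_ewma(values: np.ndarray | Sequence[float], smoothing: float) -> np.ndarray:
    """EWMA recursion seeded at the first observation; defined everywhere."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise InputError("empty series")
    if not 0.0 < smoothing <= 1.0:
        raise ConfigurationError("smoothing must lie in (0, 1]")
    return pd.Series(x).ewm(alpha=smoothing, adjust=False).mean().to_numpy()


def compute_statistic(values: np.ndarray, config: MonitorConfig) -> np.ndarray:
    """Dispatch to the statistic named by ``config.algorithm``."""
    if config.algorithm == "MA":
        return compute_ma(values, config.window)
    if config.algorithm == "MQ":
        return compute_mq(values, config.window, config.quantile)
    return compute_ewma(values, config.smoothing)


def fit_limits(
    train_statistic: np.ndarray | Sequence[float], a: float, b: float
) -> ControlLimits:
    """Freeze limits from the statistic on the bias-free training stream.

    Center and SD are the mean and sample standard deviation of the
    defined (post-warm-up) statistic values; ``ucl = center + a * sd``,
    ``lcl = center - b * sd``.

    Raises
    ------
    DegenerateDataError
        If fewer than two defined values exist or the SD is zero.
    """
    if a <= 0 or b <= 0:
        raise ConfigurationError("limit multipliers must be positive")
    stat = np.asarray(train_statistic, dtype=float)
    defined = stat[~np.isnan(stat)]
    if defined.size < 2:
        raise DegenerateDataError("need at least 2 defined statistic values")
    sd = float(np.std(defined, ddof=1))
    if sd == 0.0:
        raise DegenerateDataError("constant training statistic: SD is zero")
    center = float(np.mean(defined))
    return ControlLimits(center=center, stat_sd=sd, ucl=center + a * sd, lcl=center - b * sd)


def detect_alarms(
    statistic: np.ndarray, limits: ControlLimits, consecutive_k: int
) -> AlarmTrace:
    """Apply the k-consecutive-points rule to a statistic trace.

    A point is "outside" when the statistic strictly exceeds the UCL or
    strictly undercuts the LCL (warm-up NaNs are never outside); a run of
    consecutive outside points may mix sides.  Maximal runs of length
    >= k become alarm runs attributed to their first point, and every
    point of a qualifying run is marked alarmed.
    """
    if consecutive_k < 1:
        raise ConfigurationError("consecutive_k must be >= 1")
    stat = np.asarray(statistic, dtype=float)
    with np.errstate(invalid="ignore"):
        outside = (stat > limits.ucl) | (stat < limits.lcl)
    outside &= ~np.isnan(stat)
    alarmed = np.zeros_like(outside)
    runs: list[tuple[int, int]] = []
    padded = np.diff(np.concatenate(([0], outside.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    for start, end in zip(starts, ends):
        length = end - start
        if length >= consecutive_k:
            runs.append((int(start), int(length)))
            alarmed[start:end] = True
    return AlarmTrace(
        statistic=stat,
        outside=outside,
        alarm_runs=tuple(runs),
        alarmed=alarmed,
        limits=limits,
        consecutive_k=consecutive_k,
    )


def export_trace(
    trace: AlarmTrace,
    raw: np.ndarray | None = None,
    transformed: np.ndarray | None = None,
    error_flag: np.ndarray | None = None,
    segment_id: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-observation control-chart table for delimited-text export."""
    n = trace.statistic.size
    data: dict[str, np.ndarray] = {"index": np.arange(1, n + 1)}
    if raw is not None:
        data["raw"] = np.asarray(raw, dtype=float)
    if transformed is not None:
        data["transformed"] = np.asarray(transformed, dtype=float)
    data["statistic"] = trace.statistic
    data["ucl"] = np.full(n, trace.limits.ucl)
    data["lcl"] = np.full(n, trace.limits.lcl)
    data["outside"] = trace.outside.astype(int)
    data["alarmed"] = trace.alarmed.astype(int)
    if error_flag is not None:
        data["error_flag"] = np.asarray(error_flag).astype(int)
    if segment_id is not None:
        data["segment_id"] = np.asarray(segment_id, dtype=int)
    return pd.DataFrame(data)


def plot_control_chart(
    trace: AlarmTrace,
    error_flag: np.ndarray | None = None,
    title: str | None = None,
    path: str | Path | None = None,
):
    """Render the statistic with limit lines; biased points in red.

    Side-effect-only helper: saves to ``path`` when given, otherwise
    returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    n = trace.statistic.size
    idx = np.arange(n)
    flag = (
        np.asarray(error_flag, dtype=bool)
        if error_flag is not None
        else np.zeros(n, dtype=bool)
    )
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.scatter(idx[~flag], trace.statistic[~flag], s=4, color="tab:blue", label="unbiased")
    if flag.any():
        ax.scatter(idx[flag], trace.statistic[flag], s=4, color="tab:red", label="biased")
    ax.axhline(trace.limits.ucl, color="black", linestyle="--", linewidth=1, label="UCL")
    ax.axhline(trace.limits.lcl, color="black", linestyle="--", linewidth=1, label="LCL")
    ax.axhline(trace.limits.center, color="gray", linestyle=":", linewidth=1)
    ax.set_xlabel("observation")
    ax.set_ylabel("monitoring statistic")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
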