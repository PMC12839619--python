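"""Cleaning, Box-Cox/log transformation and Winsorizing truncation.

The "transform" and "truncate" stages of the transform-truncate-alarm
workflow.  Raw laboratory result streams are right-skewed with long upper
tails, which destabilizes moving-window statistics and control limits
fitted as mean +/- multiplier * SD.  A maximum-likelihood Box-Cox
transformation (with a log fallback when the estimated exponent is close
to zero) symmetrizes the stream, and truncation with value replacement
(Winsorizing) clamps the residual extremes to training-set quantile
bounds before any monitoring statistic is computed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import ConfigurationError, DegenerateDataError, InputError

logger = logging.getLogger(__name__)

#: characters stripped from the front of a raw result token before parsing
_COMPARATOR_CHARS = "<>≤≥=~ \t"

#: default |lambda| threshold below which the log transform replaces Box-Cox
LOG_FALLBACK_THRESHOLD = 0.05


@dataclass(frozen=True)
class AnalyteSeries:
    """A chronologically ordered stream of patient results for one analyte.

    Parameters
    ----------
    values
        Finite numeric results in measurement order.
    timestamps
        Optional non-decreasing measurement times (any sortable numeric).
    instrument
        Optional analyzer identifier.
    """

    values: np.ndarray
    timestamps: np.ndarray | None = None
    instrument: str | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise InputError("values must be one-dimensional")
        if values.size and not np.all(np.isfinite(values)):
            raise InputError("values must be finite after cleaning")
        object.__setattr__(self, "values", values)
        if self.timestamps is not None:
            ts = np.asarray(self.timestamps)
            if ts.shape != values.shape:
                raise InputError("timestamps must align with values")
            if ts.size > 1 and np.any(np.diff(ts.astype(float)) < 0):
                raise InputError("timestamps must be non-decreasing")
            object.__setattr__(self, "timestamps", ts)

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: np.ndarray) -> "AnalyteSeries":
        """Return a copy carrying ``values`` and the original metadata."""
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class TransformSpec:
    """A fitted Box-Cox (or log-fallback) transformation.

    ``lam`` is the Box-Cox exponent estimated by maximum likelihood;
    ``offset`` is added before transforming and is positive only when the
    input contained non-positive values; ``used_log`` records that
    ``|lam|`` fell below ``log_fallback_threshold`` and the natural log is
    applied instead of the power form.
    """

    lam: float
    offset: float = 0.0
    log_fallback_threshold: float = LOG_FALLBACK_THRESHOLD
    used_log: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ConfigurationError("offset must be non-negative")
        if self.log_fallback_threshold <= 0:
            raise ConfigurationError("log_fallback_threshold must be positive")
        if abs(self.lam) < self.log_fallback_threshold and not self.used_log:
            raise ConfigurationError(
                "lambda below the log-fallback threshold requires used_log=True"
            )


@dataclass(frozen=True)
class TruncationRule:
    """Winsorizing bounds on the transformed scale.

    ``factor`` is the fraction clamped per tail; factor 0 means no
    truncation (infinite bounds).
    """

    factor: float
    lower_bound: float
    upper_bound: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.factor < 0.5:
            raise ConfigurationError("truncation factor must lie in [0, 0.5)")
        if self.lower_bound > self.upper_bound:
            raise ConfigurationError("lower_bound must not exceed upper_bound")


def clean_numeric(
    raw: Sequence[object],
    timestamps: Sequence | None = None,
    instrument: str | None = None,
) -> AnalyteSeries:
    """Parse raw result tokens into a numeric :class:`AnalyteSeries`.

    Leading comparator symbols (``<``, ``>``, ``≤``, ``≥``, ``=``) are
    stripped, so a censored report like ``"<0.01"`` contributes its
    numeric bound.  Unparseable tokens are dropped and counted in a log
    message; order is preserved.

    Raises
    ------
    InputError
        If ``raw`` is empty or nothing parses to a finite number.
    """
    if len(raw) == 0:
        raise InputError("raw input is empty")
    values: list[float] = []
    kept_ts: list = []
    dropped = 0
    ts_seq = list(timestamps) if timestamps is not None else None
    for i, token in enumerate(raw):
        if isinstance(token, (int, float, np.integer, np.floating)):
            parsed = float(token)
        else:
            text = str(token).strip().lstrip(_COMPARATOR_CHARS)
            try:
                parsed = float(text)
            except ValueError:
                dropped += 1
                continue
        if not math.isfinite(parsed):
            dropped += 1
            continue
        values.append(parsed)
        if ts_seq is not None:
            kept_ts.append(ts_seq[i])
    if dropped:
        logger.info("clean_numeric dropped %d unparseable token(s)", dropped)
    if not values:
        raise InputError("no parseable numeric results in input")
    return AnalyteSeries(
        values=np.asarray(values),
        timestamps=np.asarray(kept_ts) if ts_seq is not None else None,
        instrument=instrument,
    )


def _boxcox_negative_llf(lam: float, shifted: np.ndarray) -> float:
    return -stats.boxcox_llf(lam, shifted)


def estimate_transform(
    series: AnalyteSeries,
    threshold: float = LOG_FALLBACK_THRESHOLD,
    lam_bounds: tuple[float, float] = (-5.0, 5.0),
) -> TransformSpec:
    """Fit the Box-Cox exponent by maximum likelihood.

    If the series contains non-positive values a small offset
    (``1e-6 * median(|x|)`` minus the minimum) is added first so every
    shifted value is strictly positive.  When the fitted ``|lambda|`` falls
    below ``threshold`` the spec records a log fallback.

    Raises
    ------
    DegenerateDataError
        For a constant series, where the exponent is unidentifiable.
    """
    x = series.values
    if x.size == 0:
        raise InputError("cannot fit a transform to an empty series")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant series: Box-Cox lambda is undefined")
    xmin = float(np.min(x))
    if xmin > 0:
        offset = 0.0
    else:
        scale = float(np.median(np.abs(x)))
        eps = 1e-6 * scale if scale > 0 else 1e-6
        offset = eps - xmin
    shifted = x + offset
    res = optimize.minimize_scalar(
        _boxcox_negative_llf,
        bounds=lam_bounds,
        args=(shifted,),
        method="bounded",
    )
    lam = float(res.x)
    used_log = abs(lam) < threshold
    return TransformSpec(
        lam=lam, offset=offset, log_fallback_threshold=threshold, used_log=used_log
    )


def transform_values(values: np.ndarray, spec: TransformSpec) -> np.ndarray:
    """Apply a fitted transform to a bare array (helper for hot loops)."""
    shifted = np.asarray(values, dtype=float) + spec.offset
    if np.any(shifted <= 0):
        raise InputError(
            "non-positive value after offset: transform spec does not match data"
        )
    if spec.used_log:
        return np.log(shifted)
    return (np.power(shifted, spec.lam) - 1.0) / spec.lam


def inverse_transform_values(values: np.ndarray, spec: TransformSpec) -> np.ndarray:
    """Invert :func:`transform_values` (up to floating-point error)."""
    y = np.asarray(values, dtype=float)
    if spec.used_log:
        return np.exp(y) - spec.offset
    return np.power(spec.lam * y + 1.0, 1.0 / spec.lam) - spec.offset


def apply_transform(series: AnalyteSeries, spec: TransformSpec) -> AnalyteSeries:
    """Elementwise Box-Cox/log transform; order and metadata preserved."""
    return series.with_values(transform_values(series.values, spec))


def inverse_transform(series: AnalyteSeries, spec: TransformSpec) -> AnalyteSeries:
    return series.with_values(inverse_transform_values(series.values, spec))


def fit_truncation(train: AnalyteSeries | np.ndarray, factor: float) -> TruncationRule:
    """Freeze Winsorizing bounds from training data.

    Bounds are the empirical ``factor`` and ``1 - factor`` quantiles
    (linear interpolation between order statistics) of the training
    values; factor 0 yields infinite bounds (a no-op rule).
    """
    if not 0.0 <= factor < 0.5:
        raise ConfigurationError("truncation factor must lie in [0, 0.5)")
    values = train.values if isinstance(train, AnalyteSeries) else np.asarray(train, float)
    if values.size == 0:
        raise InputError("cannot fit truncation bounds on an empty series")
    if factor == 0.0:
        return TruncationRule(factor=0.0, lower_bound=-np.inf, upper_bound=np.inf)
    lo, hi = np.quantile(values, [factor, 1.0 - factor], method="linear")
    return TruncationRule(factor=factor, lower_bound=float(lo), upper_bound=float(hi))


def winsorize_values(values: np.ndarray, rule: TruncationRule) -> np.ndarray:
    return np.clip(np.asarray(values, dtype=float), rule.lower_bound, rule.upper_bound)


def winsorize(series: AnalyteSeries, rule: TruncationRule) -> AnalyteSeries:
    """Clamp values outside the rule's bounds to the bounds (length preserved)."""
    return series.with_values(winsorize_values(series.values, rule))


def iqr_trim(values: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Drop values beyond ``k`` interquartile ranges from the quartiles.

    Visualization helper only (histogram inspection); it never feeds the
    monitoring pipeline.
    """
    x = np.asarray(values, dtype=float)
    q1, q3 = np.quantile(x, [0.25, 0.75], method="linear")
    iqr = q3 - q1
    return x[(x >= q1 - k * iqr) & (x <= q3 + k * iqr)]


def read_results(
    path: str | Path,
    result_col: str = "result",
    timestamp_col: str | None = "timestamp",
    instrument_col: str | None = None,
) -> AnalyteSeries:
    """Read a delimited-text or spreadsheet result table into a series.

    Column names are mapped through the arguments; the result column is
    passed through :func:`clean_numeric`, so censored tokens survive and
    junk rows are dropped with a logged count.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        frame = pd.read_excel(path)
    else:
        frame = pd.read_csv(path, sep=None, engine="python")
    if result_col not in frame.columns:
        raise InputError(f"result column {result_col!r} not found in {path.name}")
    ts = None
    if timestamp_col is not None and timestamp_col in frame.columns:
        ts = frame[timestamp_col].to_numpy()
    instrument = None
    if instrument_col is not None and instrument_col in frame.columns:
        first = frame[instrument_col].dropna()
        instrument = str(first.iloc[0]) if len(first) else None
    return clean_numeric(frame[result_col].tolist(), timestamps=ts, instrument=instrument)


def write_series(series: AnalyteSeries, path: str | Path) -> None:
    """Write the two-column (result, timestamp) delimited-text layout."""
    data = {"result": series.values}
    if series.timestamps is not None:
        data["timestamp"] = series.timestamps
    pd.DataFrame(data).to_csv(path, index=False)
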