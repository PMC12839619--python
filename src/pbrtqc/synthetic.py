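"""Synthetic analyte-result streams.

Routine clinical chemistry streams are strictly positive and right-skewed
with long upper tails.  The generator samples a log-normal distribution
parameterized directly by the clinically familiar quantities — the
population median and the fractional coefficient of variation — and can
add a sparse multiplicative heavy-tail contamination (``skew_strength``)
to emulate the occasional extreme pathological result that motivates
Winsorizing.

Two presets bracket the analyte landscape: ``tsh_like`` (thyrotropin-like:
high CV, heavy skew, so Box-Cox estimation lands far below 1) and
``pt_like`` (prothrombin-time-like: tight low-CV stream with only mild
skew).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError
from .preprocessing import AnalyteSeries

__all__ = ["AnalytePreset", "generate_analyte", "tsh_like", "pt_like"]


@dataclass(frozen=True)
class AnalytePreset:
    """Parameters of a synthetic analyte stream.

    Parameters
    ----------
    name
        Label carried into outputs.
    median
        Target population median, in analyte units (> 0).
    cv
        Target fractional coefficient of variation (> 0).
    skew_strength
        Non-negative knob for multiplicative upper-tail contamination;
        0 gives a pure log-normal.
    n
        Number of records (>= 1).
    seed
        Seed for the generator; identical seeds give identical streams.
    """

    name: str
    median: float
    cv: float
    skew_strength: float = 0.0
    n: int = 7000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ConfigurationError("median must be positive")
        if self.cv <= 0:
            raise ConfigurationError("cv must be positive")
        if self.skew_strength < 0:
            raise ConfigurationError("skew_strength must be non-negative")
        if self.n < 1:
            raise ConfigurationError("n must be at least 1")


def generate_analyte(preset: AnalytePreset, with_timestamps: bool = True) -> AnalyteSeries:
    """Sample a chronologically ordered stream for ``preset``.

    The base draw is log-normal with ``exp(mu) = median`` and
    ``sigma = sqrt(log(1 + cv^2))`` so the requested median and CV hold
    exactly in distribution.  When ``skew_strength > 0`` a random subset
    of about ``2% * skew_strength`` of the records is inflated by a factor
    ``1 + Exp(skew_strength)``, thickening the upper tail without moving
    the bulk of the distribution.
    """
    rng = np.random.default_rng(preset.seed)
    sigma = float(np.sqrt(np.log1p(preset.cv**2)))
    mu = float(np.log(preset.median))
    values = rng.lognormal(mean=mu, sigma=sigma, size=preset.n)
    if preset.skew_strength > 0:
        p = min(0.05, 0.02 * preset.skew_strength)
        mask = rng.random(preset.n) < p
        if mask.any():
            values[mask] *= 1.0 + rng.exponential(preset.skew_strength, mask.sum())
    timestamps = None
    if with_timestamps:
        # strictly increasing integer arrival times (seconds-like spacing)
        timestamps = np.cumsum(rng.integers(1, 300, size=preset.n))
    return AnalyteSeries(values=values, timestamps=timestamps, instrument=preset.name)


def tsh_like(n: int = 7000, seed: int = 0) -> AnalytePreset:
    """High-CV, heavy-skew preset (thyrotropin-like, mIU/L)."""
    return AnalytePreset(
        name="tsh_like", median=1.8, cv=0.60, skew_strength=1.0, n=n, seed=seed
    )


def pt_like(n: int = 7000, seed: int = 0) -> AnalytePreset:
    """Low-CV, mild-skew preset (prothrombin-time-like, seconds)."""
    return AnalytePreset(
        name="pt_like", median=12.0, cv=0.03, skew_strength=0.2, n=n, seed=seed
    )
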