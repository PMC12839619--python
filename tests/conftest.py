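import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from pbrtqc import (
    AnalyteSeries,
    build_scenario_suite,
    chronological_split,
    generate_analyte,
    pt_like,
    tsh_like,
)


@pytest.fixture(scope="session")
def pt_series() -> AnalyteSeries:
    """A seeded low-CV (prothrombin-time-like) stream of 7000 results."""
    return generate_analyte(pt_like(seed=1))


@pytest.fixture(scope="session")
def tsh_series() -> AnalyteSeries:
    """A seeded high-CV heavy-skew (thyrotropin-like) stream."""
    return generate_analyte(tsh_like(seed=1))


@pytest.fixture(scope="session")
def pt_train(pt_series) -> AnalyteSeries:
    train, _ = chronological_split(pt_series)
    return train


@pytest.fixture(scope="session")
def small_suite(pt_train):
    """A compact labelled scenario suite on the training half."""
    return build_scenario_suite(
        pt_train,
        magnitudes=(0.1, 0.5),
        seed=11,
        n_segments=3,
        length_range=(80, 150),
        gap_range=(200, 300),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
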