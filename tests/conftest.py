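import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from exposcreen import SyntheticDesign, generate, link_outcomes

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_design() -> SyntheticDesign:
    """Down-scaled study conditions for fast per-module tests."""
    return SyntheticDesign(n_counties=400, seed=11)


@pytest.fixture(scope="session")
def small_data(small_design):
    """One generated dataset shared across the suite (read-only)."""
    return generate(small_design)


@pytest.fixture(scope="session")
def small_linked(small_data):
    table, outc, truth = small_data
    return link_outcomes(table, outc, "total")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
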