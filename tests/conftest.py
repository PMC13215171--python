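import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from blockstate import RateSet, build_scheme

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def table_rates() -> RateSet:
    """The published rate-constant set (package defaults)."""
    return RateSet()


@pytest.fixture(scope="session")
def scheme(table_rates):
    return build_scheme(table_rates)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)
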