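import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rhopattern import NondimParams, set2_params

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def p_region_I() -> NondimParams:
    return set2_params(a1=0.2, a5=2.0)


@pytest.fixture(scope="session")
def p_region_II() -> NondimParams:
    return set2_params(a1=2.0, a5=1.0)


@pytest.fixture(scope="session")
def p_region_III() -> NondimParams:
    return set2_params(a1=4.0, a5=1.5)


@pytest.fixture(scope="session")
def p_region_IV() -> NondimParams:
    return set2_params(a1=4.3, a5=2.1)


@pytest.fixture(scope="session")
def p_region_V() -> NondimParams:
    return set2_params(a1=5.0, a5=1.5)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
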