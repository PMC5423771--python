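import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def single_swelling_geometry():
    from svtrack import build_terminal_geometry

    return build_terminal_geometry(1, mean_diameter=2.1, seed=7, diameter_cv=0.0)


@pytest.fixture(scope="session")
def chain_geometry():
    from svtrack import build_terminal_geometry

    return build_terminal_geometry(3, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
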