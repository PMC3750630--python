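import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from situated_hkb import HKBParams
from situated_hkb.dynamics_analysis import (
    find_decoupled_fixed_points,
    find_situated_fixed_points,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Canonical control parameters: a=5, b=1, c=5, delta_omega0=1, s=2.5."""
    return HKBParams()


@pytest.fixture(scope="session")
def decoupled_roots(params):
    return find_decoupled_fixed_points(params)


@pytest.fixture(scope="session")
def situated_fps(params):
    return find_situated_fixed_points(params)


@pytest.fixture(scope="session")
def attractor(situated_fps):
    return next(f for f in situated_fps if f.kind == "attractor")


@pytest.fixture(scope="session")
def repeller(situated_fps):
    return next(f for f in situated_fps if f.kind == "repeller")


@pytest.fixture()
def rng():
    return np.random.default_rng(20230823)
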