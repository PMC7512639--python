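import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sigentropy import FixtureConfig, make_cascade, run_ssa, solve_steady_state

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def driven_spec():
    return make_cascade(FixtureConfig(regime="driven", n=3, totals=1000))


@pytest.fixture(scope="session")
def equilibrium_spec():
    return make_cascade(FixtureConfig(regime="equilibrium", n=3, totals=1000))


@pytest.fixture(scope="session")
def driven_traj(driven_spec):
    return run_ssa(driven_spec, t_max=10.0, seed=42)


@pytest.fixture(scope="session")
def driven_occ(driven_spec):
    return solve_steady_state(driven_spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
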