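import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def double_wall_system():
    from excitube.lattice import TubeSystem

    return TubeSystem.double_wall()


@pytest.fixture(scope="session")
def single_wall_system():
    from excitube.lattice import TubeSystem

    return TubeSystem.single_wall()


@pytest.fixture(scope="session")
def annihilating_ensemble(single_wall_system):
    """Moderately dense single-wall run reused by conservation/observable
    tests: density 83 molecules/exciton, 5 ps, 6 realizations."""
    from excitube.kmc import SimParams, default_time_grid, run_ensemble

    params = SimParams.inner_tube(
        density=83.0, t_max_ps=5.0, n_real=6, seed=20250901
    )
    return run_ensemble(
        single_wall_system, params, default_time_grid(5.0, 25)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
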