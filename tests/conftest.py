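import numpy as np
import pytest

from cstcontrol.model import NoiseSpec, TaskConfig, build_continuous_system, discretize
from cstcontrol.solver import GainCache, make_objective


@pytest.fixture(scope="session")
def gain_cache():
    """Shared cache so gains are solved once per (lambda, objective) per run."""
    return GainCache()


@pytest.fixture(scope="session")
def default_task():
    return TaskConfig(lam=2.0)


@pytest.fixture(scope="session")
def default_noise():
    return NoiseSpec()


@pytest.fixture(scope="session")
def sys_lam2():
    """Delay-augmented discrete system at lambda = 2 with default parameters."""
    return discretize(build_continuous_system(2.0), 0.01, delay_steps=5)


@pytest.fixture(scope="session")
def gains_lam2(sys_lam2, default_noise, gain_cache, default_task):
    cost = make_objective("position", 1e4, 10.0, default_task.n_steps)
    return gain_cache.get_or_solve(sys_lam2, cost, default_noise)
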