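import numpy as np
import pytest

from rnbreed import (
    RNParams,
    build_env_grid,
    allocate_animals,
    proportional_goal,
    resilience_goal,
)


@pytest.fixture(scope="session")
def grid():
    return build_env_grid()


@pytest.fixture(scope="session")
def grid_allocated(grid):
    return allocate_animals(grid, 5000, 100)


@pytest.fixture(scope="session")
def basic_params():
    """Basic genetic architecture: h2 = 0.3 in the average environment."""
    return RNParams(var_int=0.3, var_sl=0.05, cov_int_sl=0.0, var_e=0.7)


@pytest.fixture(scope="session")
def correlated_params():
    """Alternative architecture with intercept-slope correlation 0.5."""
    return RNParams.from_h2(0.3, var_sl=0.05, r_int_sl=0.5)


@pytest.fixture(scope="session")
def prop_goal(grid):
    return proportional_goal(grid)


@pytest.fixture(scope="session")
def resil_goal(grid):
    return resilience_goal(grid)
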