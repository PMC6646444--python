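import numpy as np
import pytest

from efrkit import population


@pytest.fixture(scope="session")
def grid():
    return population.build_cf_grid()


@pytest.fixture(scope="session")
def healthy_pop(grid):
    return population.allocate_fibers(grid, density="uniform")


@pytest.fixture(scope="session")
def levels():
    return np.arange(10, 101, 5, dtype=float)


@pytest.fixture(scope="session")
def window_35_90(levels):
    return (levels >= 35) & (levels <= 90)
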