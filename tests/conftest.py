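import numpy as np
import pytest

from ridmefit import dipolar_core as dc


@pytest.fixture(scope="session")
def t_grid():
    """Coarse time grid (0 to 2.5 us, 16 ns) keeping the suite fast."""
    return dc.default_t_grid(2.5, 0.016)


@pytest.fixture(scope="session")
def r_grid():
    return dc.default_r_grid(1.5, 6.0, 0.05)


@pytest.fixture(scope="session")
def kernel(t_grid, r_grid):
    return dc.build_kernel(t_grid, r_grid)


@pytest.fixture(scope="session")
def gauss_dist(r_grid):
    return dc.DistanceDistribution.gaussian(2.5, 0.15, r_grid)


@pytest.fixture(scope="session")
def form_factor(gauss_dist, kernel):
    """Noise-free form factor at delta = 0.3."""
    return dc.simulate_form_factor(gauss_dist, 0.3, kernel)
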