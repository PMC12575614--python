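import numpy as np
import pytest

import pinvrecon as pr
from pinvrecon.inversion import RegularizationSpec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def random_encode_30x20():
    g = np.random.default_rng(42)
    return g.standard_normal((30, 20)) + 1j * g.standard_normal((30, 20))


@pytest.fixture(scope="session")
def cart16():
    """16x16 Cartesian grid + trajectory + double-precision encode."""
    grid, traj = pr.make_cartesian((16, 16))
    enc = pr.fourier_encode(traj, grid, precision="double")
    return grid, traj, enc


@pytest.fixture(scope="session")
def spiral32():
    """32^2 circular-masked grid, 8-arm spiral, phantom and encode."""
    grid = pr.circular_mask(pr.make_grid((32, 32)), 1.0)
    traj = pr.make_spiral(32, 8, 160)
    phantom = pr.shepp_logan(grid)
    enc = pr.fourier_encode(traj, grid, precision="double")
    return grid, traj, phantom, enc


@pytest.fixture
def tikhonov_reg():
    return RegularizationSpec(method="tikhonov", lambda_rel=1e-3)
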