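import numpy as np
import pytest

from cryodiff import (
    EnsembleSpec,
    ToyComplexSpec,
    VoxelGrid,
    make_ensemble,
    make_toy_complex,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_grid(rng):
    """Small cubic grid of white noise."""
    return VoxelGrid(rng.standard_normal((16, 16, 16)), voxel_size=2.0)


@pytest.fixture
def blob_grid():
    """A centred Gaussian blob on a 16^3 grid, 2 A voxels."""
    n, vs = 16, 2.0
    ax = (np.arange(n) - n / 2) * vs
    d2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    return VoxelGrid(5.0 * np.exp(-0.5 * d2 / 5.0**2), voxel_size=vs)


@pytest.fixture(scope="session")
def toy_complex():
    return make_toy_complex(ToyComplexSpec(seed=5))


@pytest.fixture(scope="session")
def small_null_pair():
    """Two small null ensembles sharing the ground truth (independent noise)."""
    ens_a, gt, _ = make_ensemble(EnsembleSpec(grid_size=24, seed=11, label="A"))
    ens_b, _, _ = make_ensemble(EnsembleSpec(grid_size=24, seed=12, label="B"))
    return ens_a, ens_b, gt
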