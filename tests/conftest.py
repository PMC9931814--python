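import numpy as np
import pytest

from anevrix.dataio import VolumeGrid
from anevrix.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom_case():
    """One deterministic 96^3 phantom with a single aneurysm."""
    return generate_phantom(PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def small_phantom_case():
    """A 64^3 phantom (one window at side 64) for fast inference tests."""
    return generate_phantom(
        PhantomSpec(grid_shape=(64, 64, 64), n_segments=3, seed=7))


@pytest.fixture
def iso_grid():
    """Empty 32^3 grid at 1 mm isotropic spacing."""
    return VolumeGrid(np.zeros((32, 32, 32), dtype=np.float32), np.eye(4))


def sphere_mask(grid_shape, center_vox, radius_vox):
    idx = np.indices(grid_shape)
    d2 = sum((idx[i] - center_vox[i]) ** 2 for i in range(3))
    return (d2 <= radius_vox ** 2).astype(np.uint8)
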