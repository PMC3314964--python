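import numpy as np
import pytest

from bayesmap.fourier import RealVolume
from bayesmap.simulate import PhantomSpec, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def phantom32():
    """Standard 32³ blob phantom at 3 Å/voxel."""
    return make_phantom(PhantomSpec(size=32, voxel_size=3.0), seed=1)


@pytest.fixture(scope="session")
def phantom16():
    return make_phantom(PhantomSpec(size=16, voxel_size=2.0, n_random_blobs=5), seed=3)


@pytest.fixture(scope="session")
def blurred32(phantom32):
    """Desk-scale analogue of a strongly low-pass-filtered starting model."""
    from scipy import ndimage
    return RealVolume(ndimage.gaussian_filter(phantom32.voxels, 1.2), phantom32.voxel_size)


def rotation_angle_deg(a, b):
    """Geodesic angle between two rotation matrices in degrees."""
    c = (np.trace(a @ b.T) - 1.0) / 2.0
    return np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0)))
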