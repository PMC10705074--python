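import numpy as np
import pytest

from oartsim.geometry import GridGeometry, StructureMask, make_sphere


@pytest.fixture(scope="session")
def geom2():
    """Isotropic 2 mm grid, 120 mm cube."""
    return GridGeometry((60, 60, 60), (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def geom1_small():
    """Isotropic 1 mm grid, 80 mm cube (for convergence checks)."""
    return GridGeometry((80, 80, 80), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def sphere20(geom2):
    """Digitized 20 mm-radius sphere centred off-lattice."""
    return make_sphere(geom2, (59.3, 58.1, 60.7), 20.0, "sphere20")


@pytest.fixture(scope="session")
def blob(geom2):
    """Non-convex union of spheres on the 2 mm grid."""
    rng = np.random.default_rng(3)
    vox = np.zeros(geom2.shape, dtype=bool)
    for _ in range(6):
        c = rng.uniform(40.0, 80.0, 3)
        r = rng.uniform(12.0, 22.0)
        vox |= make_sphere(geom2, c, r).voxels
    return StructureMask(geom2, vox, "blob")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
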