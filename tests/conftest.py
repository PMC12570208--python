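import numpy as np
import pytest

from spirecon.geometry import DetectorGeometry, pixel_to_q
from spirecon.simulate import PhantomSpec, make_phantom, design_geometry


VOXEL = 1e-10  # 1 Angstrom voxels throughout the fixtures


@pytest.fixture(scope="session")
def small_phantom():
    """16^3 single-blob-cluster phantom for cheap oracle tests."""
    return make_phantom(PhantomSpec(n_blobs=2, blob_sigma=1.5e-10, seed=11), 16, VOXEL)


@pytest.fixture(scope="session")
def phantom32():
    """The 32^3 reference phantom used by the recovery tests."""
    return make_phantom(PhantomSpec(n_blobs=4, blob_sigma=2.5e-10, seed=3), 32, VOXEL)


@pytest.fixture(scope="session")
def geom64():
    """64x64 detector reaching 90% of the 32^3 phantom's Nyquist."""
    return design_geometry(32, VOXEL, n_pixels=64)


@pytest.fixture(scope="session")
def geom32():
    """Small 32x32 detector for cheap matching tests."""
    return design_geometry(32, VOXEL, n_pixels=32)


@pytest.fixture(scope="session")
def qgrid64(geom64):
    return pixel_to_q(geom64)


def padded_truth(model, M):
    """Centre-embed a density into an M^3 cube (the phasing grid)."""
    out = np.zeros((M, M, M))
    lo = M // 2 - model.N // 2
    out[lo:lo + model.N, lo:lo + model.N, lo:lo + model.N] = model.rho
    return out
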