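import numpy as np
import pytest
from scipy.spatial import Delaunay

from tetvolt.mesh import TetMesh, generate_cylinder_mesh


@pytest.fixture(scope="session")
def random_mesh_factory():
    """Small random tetrahedral meshes via Delaunay of a seeded point cloud."""

    def make(seed=0, npts=30, scale=1.0):
        rng = np.random.default_rng(seed)
        pts = rng.random((npts, 3)) * scale
        return TetMesh.from_arrays(pts, Delaunay(pts).simplices)

    return make


@pytest.fixture(scope="session")
def tiny_cylinder():
    """Small closed cylinder fixture shared across tests."""
    return generate_cylinder_mesh(20e-6, 4e-6, 600, polygon_order=6)


@pytest.fixture(scope="session")
def rod_mesh():
    """Elongated cylinder for ordering benchmarks."""
    return generate_cylinder_mesh(200e-6, 2e-6, 6000, polygon_order=6).mesh
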