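import numpy as np
import pytest
from scipy.spatial import Delaunay

from breastsim import (
    DeformationState,
    PhantomSpec,
    TetMesh,
    make_phantom,
    material_from_young_poisson,
)


@pytest.fixture(scope="session")
def soft_tissue():
    """Literature-average breast soft tissue (E = 0.609 kPa, nu = 0.45)."""
    return material_from_young_poisson(609.0, 0.45)


@pytest.fixture
def unit_tet_mesh():
    """One regular-ish tet with 1 m edges along the axes (vertices in mm)."""
    verts = np.array(
        [[0.0, 0, 0], [1000.0, 0, 0], [0, 1000.0, 0], [0, 0, 1000.0]]
    )
    return TetMesh(verts, np.array([[0, 1, 2, 3]]), rigid_nodes=[0])


@pytest.fixture
def blob_mesh():
    """Small random Delaunay mesh (~50 mm blob) for derivative checks."""
    rng = np.random.default_rng(7)
    pts = rng.uniform(0.0, 50.0, (14, 3))
    tri = Delaunay(pts)
    return TetMesh(pts, tri.simplices, rigid_nodes=[0, 1])


@pytest.fixture(scope="session")
def small_phantom():
    """Noise-free ~500-tet phantom shared across solver-level tests."""
    spec = PhantomSpec(target_tet_count=500, noise_sigma=0.0, seed=3)
    mesh, tumor, chest = make_phantom(spec)
    return mesh, tumor, chest


@pytest.fixture
def perturbed_state(blob_mesh):
    """Feasible (non-inverting) random perturbation of the rest state."""
    rng = np.random.default_rng(11)
    rest = DeformationState.rest(blob_mesh)
    return DeformationState(
        rest.positions + rng.normal(0.0, 2e-4, rest.positions.shape)
    )
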