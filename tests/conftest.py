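import numpy as np
import pytest
from hypothesis import settings

import parcstab as ps

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tetrahedron():
    verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
    faces = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    return ps.TriangleMesh(verts, faces)


@pytest.fixture(scope="session")
def octahedron():
    """Vertices 0..5: +x, -x, +y, -y, +z, -z; 8 faces."""
    verts = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                      [0, -1, 0], [0, 0, 1], [0, 0, -1]], float)
    faces = np.array([[0, 2, 4], [2, 1, 4], [1, 3, 4], [3, 0, 4],
                      [2, 0, 5], [1, 2, 5], [3, 1, 5], [0, 3, 5]])
    return ps.TriangleMesh(verts, faces)


@pytest.fixture(scope="session")
def octahedron_split(octahedron):
    """Two connected 3-vertex parcels: A = {+x, +y, +z}, B = {-x, -y, -z}."""
    return ps.Parcellation(octahedron, np.array([0, 1, 0, 1, 0, 1]))


@pytest.fixture(scope="session")
def icosahedron():
    return ps.make_icosphere(0)


@pytest.fixture(scope="session")
def icosphere3():
    return ps.make_icosphere(3)


@pytest.fixture(scope="session")
def voronoi16(icosphere3):
    return ps.random_parcellation(icosphere3, 16, 0)


@pytest.fixture(scope="session")
def small_scenario():
    return ps.SyntheticScenario(subdivisions=3, n_parcels=16, n_subjects=2,
                                n_timepoints=150, master_seed=9)


@pytest.fixture(scope="session")
def small_timeseries(small_scenario, voronoi16):
    subjects, cov = ps.synthetic_timeseries(small_scenario, voronoi16)
    return subjects, cov
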