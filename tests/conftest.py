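import numpy as np
import pytest
import trimesh as _trimesh
from hypothesis import HealthCheck, settings

from phenomesh.geometry import ColoredPointCloud, TriangleMesh

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def unit_square_mesh() -> TriangleMesh:
    """Two triangles tiling the unit square in the z=0 plane (mm units)."""
    verts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    return TriangleMesh(verts, np.array([[0, 1, 2], [0, 2, 3]]))


@pytest.fixture
def cube_mesh() -> TriangleMesh:
    box = _trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return TriangleMesh(np.asarray(box.vertices) + 0.5, np.asarray(box.faces))


def icosphere_mesh(radius: float = 10.0, subdivisions: int = 4) -> TriangleMesh:
    ico = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


@pytest.fixture
def icosphere() -> TriangleMesh:
    return icosphere_mesh()


def horizontal_plate(side: float = 10.0, z: float = 50.0) -> TriangleMesh:
    """A side x side horizontal square plate at height z."""
    v = np.array(
        [[0, 0, z], [side, 0, z], [side, side, z], [0, side, z]], dtype=float
    )
    return TriangleMesh(v, np.array([[0, 1, 2], [0, 2, 3]]))


def grid_cloud(n: int = 20, spacing: float = 1.0) -> ColoredPointCloud:
    x, y = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
    pts = np.c_[x.ravel(), y.ravel(), np.zeros(n * n)] * spacing
    return ColoredPointCloud(pts)


def double_sided_plate(side: float = 10.0, z: float = 50.0) -> TriangleMesh:
    """A horizontal plate meshed on both faces, like a wrapped thin leaf:
    raw mesh area 2 * side^2, one-sided area side^2."""
    v = np.array(
        [[0, 0, z], [side, 0, z], [side, side, z], [0, side, z]], dtype=float
    )
    faces = np.array([[0, 1, 2], [0, 2, 3], [2, 1, 0], [3, 2, 0]])
    return TriangleMesh(v, faces)
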