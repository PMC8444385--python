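"""Core geometric containers for single-plant 3D phenotyping.

All geometry is carried in millimetres once a reference scaling has been
applied; before that the coordinate frame is whatever arbitrary unit the
dense reconstruction produced. The convention throughout the package is
+z up, with the ground plane at z = 0 after reorientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ColoredPointCloud",
    "TriangleMesh",
    "RigidScaleTransform",
    "apply_transform",
]


class GeometryError(ValueError):
    """Raised when a geometric invariant is violated."""


@dataclass
class ColoredPointCloud:
    """A 3D point cloud with optional per-point RGB color and class labels.

    Parameters
    ----------
    points : (n, 3) float array
        Coordinates, in mm once ``unit_scale_applied`` is True.
    colors : (n, 3) uint8 array or None
        Per-point RGB in [0, 255]. Either every point has a color or none do.
    unit_scale_applied : bool
        True once the cloud has been scaled to mm with a reference length.
    labels : (n,) array or None
        Optional per-point class labels (used by the synthetic generator:
        ``plant`` / ``background`` / ``outlier``); carried through subsetting.
    """

    points: np.ndarray
    colors: np.ndarray | None = None
    unit_scale_applied: bool = False
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise GeometryError("point coordinates must be finite")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.uint8).reshape(-1, 3)
            if len(self.colors) != len(self.points):
                raise GeometryError(
                    f"colors ({len(self.colors)}) and points ({len(self.points)}) "
                    "must have equal length"
                )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.points):
                raise GeometryError("labels and points must have equal length")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def has_colors(self) -> bool:
        return self.colors is not None

    def select(self, indices: np.ndarray) -> "ColoredPointCloud":
        """Return the sub-cloud at ``indices`` (colors/labels carried along)."""
        indices = np.asarray(indices)
        return ColoredPointCloud(
            points=self.points[indices],
            colors=None if self.colors is None else self.colors[indices],
            unit_scale_applied=self.unit_scale_applied,
            labels=None if self.labels is None else self.labels[indices],
        )


@dataclass
class TriangleMesh:
    """An indexed triangle surface; the carrier for all area/volume traits."""

    vertices: np.ndarray
    faces: np.ndarray
    colors: np.ndarray | None = None  # optional per-vertex RGB

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise GeometryError("vertex coordinates must be finite")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise GeometryError("face indices out of range")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.uint8).reshape(-1, 3)
            if len(self.colors) != len(self.vertices):
                raise GeometryError("vertex colors must match vertex count")

    @property
    def n(self) -> int:
        """Number of triangles."""
        return len(self.faces)

    def degenerate_faces(self) -> np.ndarray:
        """Boolean mask of faces that repeat a vertex index."""
        f = self.faces
        return (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])


@dataclass
class RigidScaleTransform:
    """A similarity transform p -> scale * (rotation @ p) + translation."""

    scale: float = 1.0
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.scale = float(self.scale)
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        self.validate()

    def validate(self, tol: float = 1e-8) -> None:
        if self.scale <= 0:
            raise GeometryError("scale must be positive")
        r = self.rotation
        if not np.allclose(r @ r.T, np.eye(3), atol=tol):
            raise GeometryError("rotation matrix is not orthonormal")
        if np.linalg.det(r) < 0:
            raise GeometryError("rotation matrix must have determinant +1")

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        return self.scale * (points @ self.rotation.T) + self.translation

    def compose(self, other: "RigidScaleTransform") -> "RigidScaleTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidScaleTransform(
            scale=self.scale * other.scale,
            rotation=self.rotation @ other.rotation,
            translation=self.scale * (self.rotation @ other.translation)
            + self.translation,
        )


def apply_transform(
    obj: ColoredPointCloud | TriangleMesh, t: RigidScaleTransform
) -> ColoredPointCloud | TriangleMesh:
    """Apply a similarity transform; colors, labels and faces are untouched."""
    t.validate()
    if isinstance(obj, ColoredPointCloud):
        out = replace(obj, points=t.apply_points(obj.points))
        return out
    if isinstance(obj, TriangleMesh):
        return TriangleMesh(
            vertices=t.apply_points(obj.vertices),
            faces=obj.faces.copy(),
            colors=None if obj.colors is None else obj.colors.copy(),
        )
    raise TypeError(f"cannot transform object of type {type(obj).__name__}")
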