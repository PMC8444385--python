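"""Whole-plant architectural traits from a cleaned, reoriented mesh.

All mesh geometry is in mm; traits are reported in the units conventional
for the phenotype: height and width in mm, areas in cm^2, canopy volume in
cm^3. "One-sided" total surface area is half the raw mesh area — a dense
reconstruction wraps each thin leaf, so the raw mesh counts both faces.
Plant area index (PAI) is the one-sided area divided by the top-down
projected (silhouette) area, the whole-plant analogue of leaf area index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.draw import polygon as _sk_polygon

from .distribution import triangle_geometry
from .geometry import GeometryError, TriangleMesh

__all__ = [
    "TraitRecord",
    "total_surface_area",
    "height_and_width",
    "convex_hull_volume",
    "projected_plant_area",
    "plant_area_index",
    "extract_traits",
]

log = logging.getLogger(__name__)

MM2_PER_CM2 = 100.0
MM3_PER_CM3 = 1000.0


@dataclass
class TraitRecord:
    """Trait bundle for one plant at one timepoint."""

    plant_id: str
    timepoint: float  # days post-germination
    height_mm: float
    max_width_mm: float
    width_x_mm: float
    width_y_mm: float
    total_surface_area_cm2: float
    projected_area_cm2: float
    hull_volume_cm3: float
    pai: float

    CSV_HEADER = (
        "plant_id,timepoint,height_mm,max_width_mm,total_surface_area_cm2,"
        "projected_area_cm2,hull_volume_cm3,pai"
    )

    def csv_row(self) -> str:
        return (
            f"{self.plant_id},{self.timepoint:g},{self.height_mm:.6g},"
            f"{self.max_width_mm:.6g},{self.total_surface_area_cm2:.6g},"
            f"{self.projected_area_cm2:.6g},{self.hull_volume_cm3:.6g},"
            f"{self.pai:.6g}"
        )


def total_surface_area(mesh: TriangleMesh) -> float:
    """One-sided total surface area in cm^2: sum of Heron triangle areas
    divided by 2 (one side of each wrapped organ) and converted from mm^2.
    """
    if mesh.n == 0:
        warnings.warn("empty mesh: total surface area is 0", stacklevel=2)
        return 0.0
    return triangle_geometry(mesh).total_area / 2.0 / MM2_PER_CM2


def height_and_width(mesh: TriangleMesh) -> tuple[float, float, float, float]:
    """(height, max width, x extent, y extent) in mm.

    Height is the z extent of the mesh — base of the stem (ground plane
    after reorientation) to the highest canopy point. Width is reported as
    both axis-aligned horizontal extents and their maximum.
    """
    if len(mesh.vertices) == 0:
        raise GeometryError("cannot measure an empty mesh")
    mins = mesh.vertices.min(axis=0)
    maxs = mesh.vertices.max(axis=0)
    ext = maxs - mins
    return float(ext[2]), float(max(ext[0], ext[1])), float(ext[0]), float(ext[1])


def convex_hull_volume(mesh: TriangleMesh) -> float:
    """Canopy volume in cm^3: volume of the 3D convex hull of the vertices."""
    if len(mesh.vertices) < 4:
        warnings.warn("fewer than 4 vertices: hull volume is 0", stacklevel=2)
        return 0.0
    try:
        hull = ConvexHull(mesh.vertices)
    except QhullError:
        warnings.warn("degenerate (coplanar) vertex set: hull volume is 0",
                      stacklevel=2)
        return 0.0
    return float(hull.volume) / MM3_PER_CM3


def projected_plant_area(
    mesh: TriangleMesh, resolution_mm_per_px: float = 0.25
) -> float:
    """Top-down projected plant area in cm^2.

    Orthographic projection of every face along -z onto the x-y plane,
    rasterized into a binary coverage grid; overlapping canopy counts once
    (the union of the projected faces, i.e. the silhouette area).
    """
    if resolution_mm_per_px <= 0:
        raise ValueError("resolution must be positive")
    if mesh.n == 0:
        return 0.0
    res = resolution_mm_per_px
    xy = mesh.vertices[:, :2]
    lo = xy.min(axis=0) - res
    shape = tuple(np.ceil((xy.max(axis=0) - lo) / res + 2).astype(int))
    grid = np.zeros(shape, dtype=bool)
    tri_xy = (xy[mesh.faces] - lo) / res  # (n, 3, 2) in pixel units
    for t in tri_xy:
        rr, cc = _sk_polygon(t[:, 0], t[:, 1], shape=shape)
        grid[rr, cc] = True
    return float(grid.sum()) * res * res / MM2_PER_CM2


def plant_area_index(total_area_cm2: float, projected_area_cm2: float) -> float:
    """PAI = one-sided total surface area / projected plant area (m^2 m^-2)."""
    if projected_area_cm2 <= 0:
        raise GeometryError("PAI undefined: projected area must be positive")
    return total_area_cm2 / projected_area_cm2


def extract_traits(
    mesh: TriangleMesh,
    plant_id: str = "plant",
    timepoint: float = 0.0,
    resolution_mm_per_px: float = 0.25,
) -> TraitRecord:
    """Compute the full trait bundle for one plant mesh."""
    height, max_w, wx, wy = height_and_width(mesh)
    area = total_surface_area(mesh)
    proj = projected_plant_area(mesh, resolution_mm_per_px)
    return TraitRecord(
        plant_id=plant_id,
        timepoint=timepoint,
        height_mm=height,
        max_width_mm=max_w,
        width_x_mm=wx,
        width_y_mm=wy,
        total_surface_area_cm2=area,
        projected_area_cm2=proj,
        hull_volume_cm3=convex_hull_volume(mesh),
        pai=plant_area_index(area, proj) if proj > 0 else float("nan"),
    )
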