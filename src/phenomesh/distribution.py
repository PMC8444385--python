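"""Per-triangle geometry and vertical surface-area distributions.

For every mesh triangle the three edge lengths are computed from the vertex
coordinates and the area follows from Heron's formula,

    s = (A + B + C) / 2,      S = sqrt(s (s-A) (s-B) (s-C)),

with negative radicands from floating-point rounding clamped to zero.
Triangle areas are then binned by the height (z) of the triangle centroid
into 1 mm cross-sections from the plant base, or into 100 bins of 1% of
plant height with areas expressed as fractions of the total — the form used
to compare vertical area allocation across plants of different sizes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import TriangleMesh

__all__ = [
    "TriangleRecords",
    "AreaHeightDistribution",
    "triangle_geometry",
    "bin_by_height",
    "normalize_distribution",
    "export_triangle_csv",
    "export_distribution_csv",
]


@dataclass
class TriangleRecords:
    """Vectorised per-triangle records for a mesh of n triangles.

    Attributes
    ----------
    vertices : (n, 3, 3)
        The three vertex coordinates of each triangle, mm.
    centres : (n, 3)
        Arithmetic mean of the three vertices (the triangle centroid).
    edges : (n, 3)
        Edge lengths A, B, C: |v1-v2|, |v1-v3|, |v2-v3|, mm.
    areas : (n,)
        Heron areas S, mm^2. Degenerate faces yield 0 and are flagged.
    degenerate : (n,) bool
        True where the Heron radicand vanished (zero-area face).
    """

    vertices: np.ndarray
    centres: np.ndarray
    edges: np.ndarray
    areas: np.ndarray
    degenerate: np.ndarray

    def __len__(self) -> int:
        return len(self.areas)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())


@dataclass
class AreaHeightDistribution:
    """Surface area per height bin, absolute (mm) or normalized (%)."""

    mode: str  # "absolute_mm" | "normalized_percent"
    bin_edges: np.ndarray  # ascending, length nbins + 1
    bin_areas: np.ndarray  # mm^2 (absolute) or fraction of total (normalized)
    @property
    def cumulative(self) -> np.ndarray:
        """Running area sum from the plant base upward."""
        return np.cumsum(self.bin_areas)

    @property
    def nbins(self) -> int:
        return len(self.bin_areas)


def triangle_geometry(mesh: TriangleMesh) -> TriangleRecords:
    """Edge lengths and Heron areas for every triangle of ``mesh``."""
    tri = mesh.vertices[mesh.faces]  # (n, 3, 3)
    v1, v2, v3 = tri[:, 0], tri[:, 1], tri[:, 2]
    a = np.linalg.norm(v1 - v2, axis=1)
    b = np.linalg.norm(v1 - v3, axis=1)
    c = np.linalg.norm(v2 - v3, axis=1)
    # Heron's formula evaluated in Kahan's numerically stable arrangement
    # (edges sorted descending); algebraically sqrt(s(s-A)(s-B)(s-C)) but
    # immune to cancellation on needle triangles
    e = np.sort(np.column_stack([a, b, c]), axis=1)[:, ::-1]
    ea, eb, ec = e[:, 0], e[:, 1], e[:, 2]
    radicand = (
        (ea + (eb + ec))
        * (ec - (ea - eb))
        * (ec + (ea - eb))
        * (ea + (eb - ec))
    )
    degenerate = radicand <= 0
    areas = 0.25 * np.sqrt(np.clip(radicand, 0.0, None))
    return TriangleRecords(
        vertices=tri,
        centres=tri.mean(axis=1),
        edges=np.column_stack([a, b, c]),
        areas=areas,
        degenerate=degenerate,
    )


def _bin_assign(z: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open bins [e_k, e_{k+1}), topmost bin closed above."""
    idx = np.searchsorted(edges, z, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def bin_by_height(
    records: TriangleRecords, bin_width_mm: float = 1.0
) -> AreaHeightDistribution:
    """Sum triangle areas into height cross-sections of ``bin_width_mm``.

    Bins start at the plant base (minimum vertex z) and triangles are
    assigned by centroid z; the topmost bin is closed so every triangle
    lands in exactly one bin and the bin sums conserve the total area.
    """
    if bin_width_mm <= 0:
        raise ValueError("bin width must be positive")
    if len(records) == 0:
        return AreaHeightDistribution(
            "absolute_mm", np.array([0.0]), np.array([])
        )
    z_base = float(records.vertices[..., 2].min())
    z_top = float(records.vertices[..., 2].max())
    nbins = max(1, int(np.ceil((z_top - z_base) / bin_width_mm - 1e-12)))
    edges = z_base + bin_width_mm * np.arange(nbins + 1)
    idx = _bin_assign(records.centres[:, 2], edges)
    areas = np.bincount(idx, weights=records.areas, minlength=nbins)
    return AreaHeightDistribution("absolute_mm", edges, areas)


def normalize_distribution(
    records: TriangleRecords,
    plant_height_mm: float | None = None,
    total_area_mm2: float | None = None,
) -> AreaHeightDistribution:
    """Normalized vertical area distribution: 100 bins of 1% plant height,
    per-bin areas as fractions of the total surface area. The cumulative
    curve runs from the base to the top of the plant and ends at 1.
    """
    if len(records) == 0:
        raise ValueError("cannot normalize an empty record set")
    z = records.vertices[..., 2]
    z_base = float(z.min())
    if plant_height_mm is None:
        plant_height_mm = float(z.max()) - z_base
    if total_area_mm2 is None:
        total_area_mm2 = records.total_area
    if plant_height_mm <= 0 or total_area_mm2 <= 0:
        raise ValueError("plant height and total area must be positive")
    edges = np.linspace(0.0, 100.0, 101)
    rel = 100.0 * (records.centres[:, 2] - z_base) / plant_height_mm
    idx = _bin_assign(rel, edges)
    areas = np.bincount(idx, weights=records.areas, minlength=100) / total_area_mm2
    return AreaHeightDistribution("normalized_percent", edges, areas)


def export_triangle_csv(records: TriangleRecords, path: str | Path) -> None:
    """Write the comprehensive per-triangle CSV: the 9 vertex coordinates,
    centroid, edge lengths A/B/C and area S of every triangle.
    """
    cols: dict[str, np.ndarray] = {}
    for v in range(3):
        for k, ax in enumerate("xyz"):
            cols[f"{ax}{v + 1}"] = records.vertices[:, v, k] if len(records) else []
    for k, ax in enumerate("xyz"):
        cols[f"centre_{ax}"] = records.centres[:, k] if len(records) else []
    for k, name in enumerate(("edge_a", "edge_b", "edge_c")):
        cols[name] = records.edges[:, k] if len(records) else []
    cols["area"] = records.areas if len(records) else []
    pd.DataFrame(cols).to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL)


def export_distribution_csv(dist: AreaHeightDistribution, path: str | Path) -> None:
    """Write bin_lo, bin_hi, area (or fraction) and cumulative columns."""
    value_col = "area_mm2" if dist.mode == "absolute_mm" else "area_fraction"
    pd.DataFrame(
        {
            "bin_lo": dist.bin_edges[:-1],
            "bin_hi": dist.bin_edges[1:],
            value_col: dist.bin_areas,
            "cumulative": dist.cumulative,
        }
    ).to_csv(path, index=False)


def plot_profile(
    dist: AreaHeightDistribution,
    path: str | Path,
    mesh: TriangleMesh | None = None,
) -> None:
    """Optional visual summary: per-bin area bars beside a mesh silhouette."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ncols = 2 if mesh is not None else 1
    fig, axes = plt.subplots(1, ncols, figsize=(4 * ncols, 5), sharey=False)
    ax = axes[0] if mesh is not None else axes
    mids = (dist.bin_edges[:-1] + dist.bin_edges[1:]) / 2
    height = np.diff(dist.bin_edges).mean()
    ax.barh(mids, dist.bin_areas, height=height, color="forestgreen")
    if dist.mode == "absolute_mm":
        ax.set_xlabel("surface area per bin (mm$^2$)")
        ax.set_ylabel("height (mm)")
    else:
        ax.set_xlabel("fraction of total area per 1% bin")
        ax.set_ylabel("relative height (%)")
    if mesh is not None:
        ax2 = axes[1]
        tri = mesh.vertices[mesh.faces]
        ax2.plot(tri[..., 0].ravel(), tri[..., 2].ravel(), ",", color="0.4",
                 markersize=0.5)
        ax2.set_xlabel("x (mm)")
        ax2.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
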