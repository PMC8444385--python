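"""End-to-end pipeline: raw colored cloud -> cleaned cloud -> mesh -> traits.

Stage order follows the semi-automated workflow: scale to mm with the pot
reference, reorient so the ground is the x-y plane, keep plant-colored
points, remove statistical outliers, optionally crop, Poisson-disk
subsample, ball-pivot mesh, close holes, then measure traits and the
vertical area distribution. Per-stage retained counts are logged and
returned for provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .cleaning import (
    color_filter,
    crop_box,
    fit_ground_plane,
    poisson_disk_subsample,
    scale_from_reference,
    sor_filter,
)
from .config import PipelineConfig
from .distribution import (
    AreaHeightDistribution,
    bin_by_height,
    export_distribution_csv,
    export_triangle_csv,
    normalize_distribution,
    triangle_geometry,
)
from .geometry import ColoredPointCloud, RigidScaleTransform, TriangleMesh, apply_transform
from .meshing import ball_pivot_mesh, close_holes
from .ply import write_ply
from .traits import TraitRecord, extract_traits

__all__ = ["PipelineResult", "clean_cloud", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    cleaned: ColoredPointCloud
    mesh: TriangleMesh
    traits: TraitRecord
    distribution_mm: AreaHeightDistribution
    distribution_normalized: AreaHeightDistribution
    stage_counts: dict[str, int] = field(default_factory=dict)


def clean_cloud(
    cloud: ColoredPointCloud,
    config: PipelineConfig,
    transform: RigidScaleTransform | None = None,
) -> tuple[ColoredPointCloud, dict[str, int]]:
    """Scaling, reorientation, color denoising, SOR, crop and subsampling.

    ``transform`` overrides the automatic ground-plane reorientation with
    an explicit user transform (the manual Meshlab step).
    """
    p = config.cleaning
    counts = {"input": len(cloud)}

    if config.measured_reference_length is not None:
        t = scale_from_reference(
            config.measured_reference_length, p.reference_length_mm
        )
        cloud = apply_transform(cloud, t)
        cloud.unit_scale_applied = True
    if transform is not None:
        cloud = apply_transform(cloud, transform)
    elif config.orient_to_ground:
        ground = fit_ground_plane(cloud, seed=config.seed)
        cloud = apply_transform(cloud, ground)

    if cloud.has_colors:
        cloud, idx = color_filter(cloud, p)
        counts["color_filter"] = len(idx)
    cloud, idx = sor_filter(cloud, k=p.sor_k, nsigma=p.sor_nsigma)
    counts["sor_filter"] = len(idx)
    if p.crop_min is not None or p.crop_max is not None:
        cloud, idx = crop_box(cloud, p.crop_min, p.crop_max)
        counts["crop_box"] = len(idx)
    cloud, idx = poisson_disk_subsample(
        cloud, p.poisson_radius, p.poisson_oversampling, seed=p.seed
    )
    counts["poisson_subsample"] = len(idx)
    for stage, kept in counts.items():
        log.info("cleaning %-18s %d points", stage, kept)
    return cloud, counts


def run_pipeline(
    cloud: ColoredPointCloud,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    transform: RigidScaleTransform | None = None,
) -> PipelineResult:
    """Run cleaning, meshing and trait extraction; optionally write artifacts.

    When ``out_dir`` is given, the cleaned cloud, the mesh, a one-row trait
    CSV, the per-triangle CSV and both distribution CSVs are written there.
    """
    config = config or PipelineConfig()
    cleaned, counts = clean_cloud(cloud, config, transform=transform)

    mesh = ball_pivot_mesh(cleaned, config.meshing)
    mesh = close_holes(mesh, config.meshing.hole_max_boundary_edges)
    counts["mesh_faces"] = mesh.n

    traits = extract_traits(
        mesh,
        plant_id=config.plant_id,
        timepoint=config.timepoint,
        resolution_mm_per_px=config.projection_resolution_mm_per_px,
    )
    rec = triangle_geometry(mesh)
    dist_mm = bin_by_height(rec, config.bin_width_mm)
    dist_norm = normalize_distribution(rec)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_ply(cleaned, out / "cleaned_cloud.ply")
        write_ply(mesh, out / "mesh.ply")
        (out / "traits.csv").write_text(
            TraitRecord.CSV_HEADER + "\n" + traits.csv_row() + "\n"
        )
        export_triangle_csv(rec, out / "triangles.csv")
        export_distribution_csv(dist_mm, out / "distribution_mm.csv")
        export_distribution_csv(dist_norm, out / "distribution_normalized.csv")
        (out / "run_log.txt").write_text(
            "\n".join(f"{k}={v}" for k, v in counts.items()) + "\n"
        )

    return PipelineResult(
        cleaned=cleaned,
        mesh=mesh,
        traits=traits,
        distribution_mm=dist_mm,
        distribution_normalized=dist_norm,
        stage_counts=counts,
    )
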