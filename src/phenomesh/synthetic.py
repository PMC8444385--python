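"""Parametric chickpea-like plants with exact ground truth.

The generator builds a potted-plant mesh from analytic parts — a vertical
cylindrical stem, slender branches, and many small elliptical leaflets —
and then samples it into a colored point cloud with the nuisance structure
of a real dense SfM reconstruction: white backdrop/ground points, sparse
far outliers, an arbitrary (unscaled) unit system and a small tilt.

Leaflets and branches are thin prisms rather than zero-thickness sheets:
a dense multi-view reconstruction observes both faces of a real leaf, and
two coincident sheets could never be separated by a pivoting ball. The
ground-truth one-sided area is therefore the exact generated-mesh area
divided by two — the same global convention the trait pipeline applies —
and includes prism rims and stem caps.

Every point carries a class label (``plant`` / ``background`` /
``outlier``) so cleaning precision and recall are directly scorable, and
every face an organ id, so colors and per-layer truth are exact. The same
seed reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .distribution import AreaHeightDistribution, normalize_distribution, triangle_geometry
from .geometry import ColoredPointCloud, RigidScaleTransform, TriangleMesh

__all__ = [
    "SyntheticPlantSpec",
    "PlantGroundTruth",
    "CloudFrame",
    "generate_plant_mesh",
    "sample_point_cloud",
    "hard_spec",
]

ORGAN_STEM, ORGAN_BRANCH, ORGAN_LEAFLET = 0, 1, 2

LABEL_PLANT, LABEL_BACKGROUND, LABEL_OUTLIER = "plant", "background", "outlier"


class SpecError(ValueError):
    """Impossible synthetic-plant geometry."""


@dataclass
class SyntheticPlantSpec:
    """Parameters of one synthetic plant.

    Defaults emulate a roughly two-week-old chickpea: a 150 mm stem and 30
    leaflets of ~20 x 12 mm arranged in two canopy layers at 20% and 80% of
    plant height holding 75% and 25% of the leaflets — the discrete-layer
    architecture that the vertical area distribution is designed to expose.
    """

    stem_height_mm: float = 150.0
    stem_radius_mm: float = 1.5
    n_branches: int = 6
    branch_angle_deg: tuple[float, float] = (30.0, 70.0)  # from vertical
    branch_length_mm: float = 18.0
    n_leaflets: int = 30
    leaflet_semiaxes_mm: tuple[float, float] = (10.0, 6.0)  # ~20 x 12 mm
    leaflet_thickness_mm: float = 1.2
    leaflet_height_distribution: str = "bimodal"  # uniform | basal_skew | bimodal
    layer_rel_heights: tuple[float, float] = (0.2, 0.8)
    layer_fractions: tuple[float, float] = (0.75, 0.25)
    layer_band_halfwidth: float = 0.05  # relative-height jitter within a layer
    max_leaflet_tilt_deg: float = 18.0
    curled: bool = False  # fold leaflets along the minor axis ("hard mode")
    curl_angle_deg: float = 35.0
    pot_width_mm: float = 150.0
    background_fraction: float = 0.2
    outlier_fraction: float = 0.02
    outlier_distance_factor: float = 1.5  # x cloud radius
    ngon: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_branches < 0 or self.n_leaflets < 0:
            raise SpecError("counts must be >= 0")
        for f in (self.background_fraction, self.outlier_fraction):
            if not 0 <= f < 1:
                raise SpecError("fractions must lie in [0, 1)")
        if self.background_fraction + self.outlier_fraction >= 1:
            raise SpecError("background + outlier fraction must be < 1")
        if self.stem_height_mm <= 0 or self.stem_radius_mm <= 0:
            raise SpecError("stem dimensions must be positive")
        if self.leaflet_height_distribution not in (
            "uniform", "basal_skew", "bimodal"
        ):
            raise SpecError(
                f"unknown height distribution {self.leaflet_height_distribution!r}"
            )


@dataclass
class PlantGroundTruth:
    """Exact-by-construction truth for a generated plant mesh."""

    height_mm: float
    one_sided_area_mm2: float
    mesh_area_mm2: float
    leaflet_one_sided_area_mm2: float
    layer_leaflet_areas_mm2: tuple[float, ...]  # one-sided, per layer
    layer_rel_heights: tuple[float, ...]
    face_organ: np.ndarray  # per-face organ id
    normalized_distribution: AreaHeightDistribution


@dataclass
class CloudFrame:
    """How the sampled cloud relates to the mm-scale upright mesh frame.

    Cloud coordinates are ``unit_scale * (tilt @ p_mm)``: an arbitrary
    model unit and a small tilt, as delivered by an unscaled SfM solve.
    ``pot_width_model_units`` is the reference length a user would measure
    in the cloud to recover mm.
    """

    unit_scale: float
    tilt: np.ndarray
    pot_width_mm: float

    @property
    def pot_width_model_units(self) -> float:
        return self.pot_width_mm * self.unit_scale

    def to_mm_transform(self) -> RigidScaleTransform:
        """Exact inverse: cloud frame back to the upright mm frame."""
        return RigidScaleTransform(
            scale=1.0 / self.unit_scale, rotation=self.tilt.T
        )


# ---------------------------------------------------------------------------
# mesh parts
# ---------------------------------------------------------------------------


def _prism(polygon2d: np.ndarray, thickness: float) -> tuple[np.ndarray, np.ndarray]:
    """Closed prism over a convex CCW polygon, extruded along local z."""
    k = len(polygon2d)
    t2 = thickness / 2.0
    top = np.c_[polygon2d, np.full(k, t2)]
    bot = np.c_[polygon2d, np.full(k, -t2)]
    verts = np.vstack([top, bot])
    faces = []
    for i in range(1, k - 1):  # top fan, CCW from +z
        faces.append((0, i, i + 1))
    for i in range(1, k - 1):  # bottom fan, reversed
        faces.append((k, k + i + 1, k + i))
    for i in range(k):  # side wall
        j = (i + 1) % k
        faces.append((i, k + i, k + j))
        faces.append((i, k + j, j))
    return verts, np.asarray(faces, dtype=np.int64)


def _rot_from_axes(z_axis: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Orthonormal frame with the given z axis and a random in-plane roll."""
    z = z_axis / np.linalg.norm(z_axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(z @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    x = np.cross(ref, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    roll = rng.uniform(0, 2 * np.pi)
    xr = np.cos(roll) * x + np.sin(roll) * y
    yr = np.cross(z, xr)
    return np.column_stack([xr, yr, z])


def _stem(spec: SyntheticPlantSpec) -> tuple[np.ndarray, np.ndarray]:
    """Closed cylinder tessellated into ~2 mm vertical segments."""
    k = spec.ngon
    nseg = max(1, int(np.ceil(spec.stem_height_mm / 2.0)))
    zs = np.linspace(0.0, spec.stem_height_mm, nseg + 1)
    ang = 2 * np.pi * np.arange(k) / k
    ring = np.c_[np.cos(ang), np.sin(ang)] * spec.stem_radius_mm
    verts = np.vstack([np.c_[ring, np.full(k, z)] for z in zs])
    faces = []
    for s in range(nseg):
        a, b = s * k, (s + 1) * k
        for i in range(k):
            j = (i + 1) % k
            faces.append((a + i, b + i, b + j))
            faces.append((a + i, b + j, a + j))
    # end caps
    for i in range(1, k - 1):
        faces.append((0, i + 1, i))  # bottom, facing -z
        top = nseg * k
        faces.append((top, top + i, top + i + 1))
    return verts, np.asarray(faces, dtype=np.int64)


def _leaflet_rel_heights(spec: SyntheticPlantSpec, rng: np.random.Generator):
    n = spec.n_leaflets
    mode = spec.leaflet_height_distribution
    if mode == "uniform":
        rel = rng.uniform(0.15, 0.95, n)
        layer = np.zeros(n, dtype=int)
    elif mode == "basal_skew":
        rel = 0.15 + 0.8 * rng.beta(1.5, 3.0, n)
        layer = np.zeros(n, dtype=int)
    else:  # bimodal
        counts = [int(round(f * n)) for f in spec.layer_fractions]
        counts[-1] = n - sum(counts[:-1])
        rel_parts, layer_parts = [], []
        for li, (h, c) in enumerate(zip(spec.layer_rel_heights, counts)):
            rel_parts.append(h + rng.uniform(-1, 1, c) * spec.layer_band_halfwidth)
            layer_parts.append(np.full(c, li, dtype=int))
        rel = np.concatenate(rel_parts)
        layer = np.concatenate(layer_parts)
    return rel, layer


def generate_plant_mesh(
    spec: SyntheticPlantSpec,
) -> tuple[TriangleMesh, PlantGroundTruth]:
    """Build the plant mesh and its exact ground-truth record."""
    rng = np.random.default_rng(spec.seed)
    all_verts: list[np.ndarray] = []
    all_faces: list[np.ndarray] = []
    organ: list[np.ndarray] = []
    offset = 0

    def _add(verts, faces, org):
        nonlocal offset
        all_verts.append(verts)
        all_faces.append(faces + offset)
        organ.append(np.full(len(faces), org, dtype=np.int8))
        offset += len(verts)

    sv, sf = _stem(spec)
    _add(sv, sf, ORGAN_STEM)

    rel, layer = _leaflet_rel_heights(spec, rng)

    # branches: slender boxes from the stem toward the canopy
    for _ in range(spec.n_branches):
        ang_v = np.deg2rad(rng.uniform(*spec.branch_angle_deg))
        az = rng.uniform(0, 2 * np.pi)
        direction = np.array(
            [np.sin(ang_v) * np.cos(az), np.sin(ang_v) * np.sin(az), np.cos(ang_v)]
        )
        # keep branches between the canopy layers so they do not pierce
        # leaflets (the union surface would hide the buried geometry)
        z0 = rng.uniform(0.30, 0.55) * spec.stem_height_mm
        length = spec.branch_length_mm
        half_w = length / 14.4  # 2.5 mm wide, 1.2 mm thick at default length
        rect = np.array(
            [[-length / 2, -half_w], [length / 2, -half_w], [length / 2, half_w],
             [-length / 2, half_w]]
        )
        bv, bf = _prism(rect, length / 15.0)
        frame = _rot_from_axes(direction, rng)
        # local x of the rectangle along the branch direction
        swap = np.column_stack([frame[:, 2], frame[:, 1], -frame[:, 0]])
        start = np.array([0.0, 0.0, z0]) + direction * (length / 2 + spec.stem_radius_mm)
        _add(bv @ swap.T + start, bf, ORGAN_BRANCH)

    # leaflets: elliptical prisms, near-horizontal with a random tilt
    a_ax, b_ax = spec.leaflet_semiaxes_mm
    ang = 2 * np.pi * np.arange(spec.ngon) / spec.ngon
    ellipse = np.c_[a_ax * np.cos(ang), b_ax * np.sin(ang)]
    leaf_faces_range: list[tuple[int, int, int]] = []  # (layer, f_lo, f_hi)
    nfaces_so_far = sum(len(f) for f in all_faces)
    placed: list[np.ndarray] = []

    def _place_centre(z_c: float) -> np.ndarray:
        """Rejection-sample a leaflet centre that does not interpenetrate
        already-placed leaflets (real leaflets touch but do not merge)."""
        best, best_sep = None, -np.inf
        for _ in range(200):
            radial = rng.uniform(spec.stem_radius_mm + 4, 0.35 * spec.pot_width_mm)
            az = rng.uniform(0, 2 * np.pi)
            c = np.array([radial * np.cos(az), radial * np.sin(az),
                          z_c + rng.uniform(-2, 2)])
            sep = np.inf
            for q in placed:
                dxy = np.hypot(c[0] - q[0], c[1] - q[1])
                dz = abs(c[2] - q[2])
                if dxy < 2.1 * a_ax and dz < 5.5:
                    sep = min(sep, dxy + 4 * dz)
            if sep == np.inf:
                return c
            if sep > best_sep:
                best, best_sep = c, sep
        return best

    for li in range(spec.n_leaflets):
        lv, lf = _prism(ellipse, spec.leaflet_thickness_mm)
        if spec.curled:
            fold = np.deg2rad(spec.curl_angle_deg)
            right = lv[:, 0] > 0
            x, z = lv[right, 0].copy(), lv[right, 2].copy()
            lv[right, 0] = x * np.cos(fold)  # fold up about the minor axis
            lv[right, 2] = z + x * np.sin(fold)
        tilt = np.deg2rad(rng.uniform(0, spec.max_leaflet_tilt_deg))
        axis = _rot_from_axes(
            np.array([np.sin(tilt), 0.0, np.cos(tilt)]), rng
        )
        centre = _place_centre(rel[li] * spec.stem_height_mm)
        placed.append(centre)
        verts = lv @ axis.T + centre
        if verts[:, 2].min() < 0:
            raise SpecError("leaflet extends below the ground plane")
        leaf_faces_range.append((layer[li], nfaces_so_far, nfaces_so_far + len(lf)))
        nfaces_so_far += len(lf)
        _add(verts, lf, ORGAN_LEAFLET)

    mesh = TriangleMesh(np.vstack(all_verts), np.vstack(all_faces))
    face_organ = np.concatenate(organ)

    rec = triangle_geometry(mesh)
    mesh_area = rec.total_area
    leaf_area = rec.areas[face_organ == ORGAN_LEAFLET].sum()
    n_layers = (
        len(spec.layer_rel_heights)
        if spec.leaflet_height_distribution == "bimodal"
        else 1
    )
    layer_areas = np.zeros(n_layers)
    for lay, lo, hi in leaf_faces_range:
        layer_areas[lay if n_layers > 1 else 0] += rec.areas[lo:hi].sum()
    truth = PlantGroundTruth(
        height_mm=float(mesh.vertices[:, 2].max() - mesh.vertices[:, 2].min()),
        one_sided_area_mm2=mesh_area / 2.0,
        mesh_area_mm2=mesh_area,
        leaflet_one_sided_area_mm2=float(leaf_area) / 2.0,
        layer_leaflet_areas_mm2=tuple(layer_areas / 2.0),
        layer_rel_heights=tuple(
            spec.layer_rel_heights[:n_layers] if n_layers > 1 else (0.5,)
        ),
        face_organ=face_organ,
        normalized_distribution=normalize_distribution(rec),
    )
    return mesh, truth


# ---------------------------------------------------------------------------
# point-cloud sampling
# ---------------------------------------------------------------------------


def _organ_colors(organ_of_point: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = len(organ_of_point)
    hsv = np.empty((n, 3))
    green = organ_of_point == ORGAN_LEAFLET
    hsv[green, 0] = rng.uniform(90, 140, green.sum()) / 360.0
    hsv[green, 1] = rng.uniform(0.45, 0.85, green.sum())
    hsv[green, 2] = rng.uniform(0.25, 0.65, green.sum())
    brown = ~green
    hsv[brown, 0] = rng.uniform(20, 40, brown.sum()) / 360.0
    hsv[brown, 1] = rng.uniform(0.40, 0.70, brown.sum())
    hsv[brown, 2] = rng.uniform(0.25, 0.50, brown.sum())
    return (hsv_to_rgb(hsv) * 255).astype(np.uint8)


def sample_point_cloud(
    mesh: TriangleMesh,
    truth: PlantGroundTruth,
    spec: SyntheticPlantSpec,
    density_pts_per_mm2: float = 8.0,
    seed: int | None = None,
) -> tuple[ColoredPointCloud, CloudFrame]:
    """Sample the plant surface into a labelled, colored, unscaled cloud.

    Plant points are area-weighted uniform samples of the mesh faces with
    organ-dependent green/brown colors; white-ish background points lie on
    the ground plane; plant-colored outliers sit on a far shell at
    >= ``outlier_distance_factor`` x the cloud radius. The returned
    :class:`CloudFrame` records the arbitrary unit scale and tilt applied.
    """
    if density_pts_per_mm2 <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)

    rec = triangle_geometry(mesh)
    n_plant = rng.poisson(density_pts_per_mm2 * rec.total_area)
    fi = rng.choice(mesh.n, size=n_plant, p=rec.areas / rec.total_area)
    r1 = np.sqrt(rng.uniform(size=n_plant))
    r2 = rng.uniform(size=n_plant)
    tri = rec.vertices[fi]
    pts_plant = (
        (1 - r1)[:, None] * tri[:, 0]
        + (r1 * (1 - r2))[:, None] * tri[:, 1]
        + (r1 * r2)[:, None] * tri[:, 2]
    )
    col_plant = _organ_colors(truth.face_organ[fi], rng)

    frac_rest = 1.0 - spec.background_fraction - spec.outlier_fraction
    n_total = n_plant / frac_rest if frac_rest > 0 else n_plant
    n_bg = int(round(n_total * spec.background_fraction))
    n_out = int(round(n_total * spec.outlier_fraction))

    horiz_r = np.linalg.norm(pts_plant[:, :2], axis=1).max()
    # background: white-ish ground plane disk around the pot
    r_bg = np.sqrt(rng.uniform(size=n_bg)) * 2.5 * max(horiz_r, spec.pot_width_mm)
    az_bg = rng.uniform(0, 2 * np.pi, n_bg)
    pts_bg = np.c_[r_bg * np.cos(az_bg), r_bg * np.sin(az_bg), np.zeros(n_bg)]
    hsv_bg = np.c_[
        rng.uniform(0, 1, n_bg), rng.uniform(0, 0.06, n_bg), rng.uniform(0.85, 1, n_bg)
    ]
    col_bg = (hsv_to_rgb(hsv_bg) * 255).astype(np.uint8)

    # outliers: plant-colored speckle far outside the scene
    centre = pts_plant.mean(axis=0)
    cloud_radius = np.linalg.norm(pts_plant - centre, axis=1).max()
    dirs = rng.normal(size=(n_out, 3))
    # upward-biased directions keep outliers above the ground plane and
    # clear of the backdrop, preserving the >= factor x radius guarantee
    dirs[:, 2] = 0.15 + np.abs(dirs[:, 2])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = cloud_radius * spec.outlier_distance_factor * rng.uniform(1.0, 1.8, n_out)
    pts_out = centre + dirs * radii[:, None]
    col_out = _organ_colors(np.full(n_out, ORGAN_LEAFLET, dtype=np.int8), rng)

    points = np.vstack([pts_plant, pts_bg, pts_out])
    colors = np.vstack([col_plant, col_bg, col_out])
    labels = np.concatenate(
        [
            np.full(n_plant, LABEL_PLANT),
            np.full(n_bg, LABEL_BACKGROUND),
            np.full(n_out, LABEL_OUTLIER),
        ]
    )

    # arbitrary model units and a small tilt, like a raw SfM solve
    unit_scale = rng.uniform(0.005, 0.02)
    tilt_angle = np.deg2rad(rng.uniform(0.5, 3.0))
    tilt_az = rng.uniform(0, 2 * np.pi)
    axis = np.array([np.cos(tilt_az), np.sin(tilt_az), 0.0])
    kx = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    tilt = np.eye(3) + np.sin(tilt_angle) * kx + (1 - np.cos(tilt_angle)) * kx @ kx
    cloud = ColoredPointCloud(
        points=unit_scale * points @ tilt.T,
        colors=colors,
        unit_scale_applied=False,
        labels=labels,
    )
    return cloud, CloudFrame(unit_scale=unit_scale, tilt=tilt,
                             pot_width_mm=spec.pot_width_mm)


def hard_spec(seed: int = 0) -> SyntheticPlantSpec:
    """Preset emulating the difficult regime: curled, clustered leaflets."""
    return SyntheticPlantSpec(
        curled=True,
        max_leaflet_tilt_deg=35.0,
        layer_band_halfwidth=0.03,
        seed=seed,
    )
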