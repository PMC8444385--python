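"""Point-cloud cleaning chain for single-plant SfM reconstructions.

The chain mirrors the standard semi-automated workflow for potted plants:

1. scale to mm with a known reference length (the pot width),
2. keep only plant-colored (green/brown) points,
3. reorient so the ground is the x-y plane at z = 0,
4. statistical outlier removal (mean k-NN distance test),
5. Poisson-disk subsampling to a uniform target spacing.

Every filter returns the kept sub-cloud together with the indices of the
retained points in the input, so retained-index lists compose and labelled
synthetic clouds can be scored for precision/recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.colors import rgb_to_hsv
from scipy.spatial import cKDTree

from .geometry import ColoredPointCloud, GeometryError, RigidScaleTransform

__all__ = [
    "CleaningParams",
    "scale_from_reference",
    "color_filter",
    "fit_ground_plane",
    "sor_filter",
    "poisson_disk_subsample",
    "crop_box",
]


@dataclass
class CleaningParams:
    """Tunable parameters of the cleaning chain.

    Defaults follow the published workflow where values are printed
    (Poisson radius 0.5 mm, Monte-Carlo oversampling 20) and the tools'
    own defaults elsewhere (SOR k=6, nsigma=1). The hue window [15, 170]
    degrees with modest saturation/value floors spans brown through green
    while rejecting a white/grey backdrop.
    """

    reference_length_mm: float = 150.0
    hue_range_deg: tuple[float, float] = (15.0, 170.0)
    min_saturation: float = 0.15
    min_value: float = 0.10
    sor_k: int = 6
    sor_nsigma: float = 1.0
    poisson_radius: float = 0.5
    poisson_oversampling: int = 20
    seed: int = 0
    crop_min: tuple[float, float, float] | None = None
    crop_max: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        h_lo, h_hi = self.hue_range_deg
        if not (0 <= h_lo < h_hi <= 360):
            raise ValueError("hue range must satisfy 0 <= lo < hi <= 360")
        if self.sor_k < 1:
            raise ValueError("sor_k must be >= 1")
        if self.poisson_radius <= 0:
            raise ValueError("poisson_radius must be positive")


def scale_from_reference(
    measured_length: float, known_length_mm: float
) -> RigidScaleTransform:
    """Similarity transform scaling the cloud so a measured reference length
    (e.g. the pot width picked between two points) becomes its known mm size.
    """
    if measured_length <= 0 or known_length_mm <= 0:
        raise GeometryError("reference lengths must be positive")
    return RigidScaleTransform(scale=known_length_mm / measured_length)


def color_filter(
    cloud: ColoredPointCloud, params: CleaningParams | None = None
) -> tuple[ColoredPointCloud, np.ndarray]:
    """Keep plant-colored points: HSV hue inside the configured window with
    saturation and value above their floors. White/grey backdrop points have
    near-zero saturation and are removed.
    """
    params = params or CleaningParams()
    if not cloud.has_colors:
        raise GeometryError("color_filter requires a cloud with colors")
    hsv = rgb_to_hsv(cloud.colors.astype(np.float64) / 255.0)
    hue = hsv[:, 0] * 360.0
    h_lo, h_hi = params.hue_range_deg
    keep = (
        (hue >= h_lo)
        & (hue <= h_hi)
        & (hsv[:, 1] >= params.min_saturation)
        & (hsv[:, 2] >= params.min_value)
    )
    idx = np.flatnonzero(keep)
    return cloud.select(idx), idx


def fit_ground_plane(
    cloud: ColoredPointCloud,
    inlier_tol_mm: float = 2.0,
    seed: int = 0,
    n_iter: int = 200,
) -> RigidScaleTransform:
    """RANSAC-fit a plane to the lowest decile of points and return the
    rigid transform that maps the plane to z = 0 with its normal along +z.
    """
    pts = cloud.points
    if len(pts) < 3:
        raise GeometryError("ground-plane fit needs at least 3 points")
    z = pts[:, 2]
    cut = np.quantile(z, 0.1)
    support = pts[z <= cut]
    if len(support) < 3:
        support = pts

    rng = np.random.default_rng(seed)
    best_inliers: np.ndarray | None = None
    for _ in range(n_iter):
        tri = support[rng.choice(len(support), 3, replace=False)]
        n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        nn = np.linalg.norm(n)
        if nn < 1e-12:
            continue
        n = n / nn
        d = np.abs((support - tri[0]) @ n)
        inliers = d < inlier_tol_mm
        if best_inliers is None or inliers.sum() > best_inliers.sum():
            best_inliers = inliers
    if best_inliers is None or best_inliers.sum() < 3:
        raise GeometryError("degenerate support: could not fit a ground plane")

    # refine on inliers by total least squares (SVD of centered points)
    sel = support[best_inliers]
    centroid = sel.mean(axis=0)
    _, _, vt = np.linalg.svd(sel - centroid, full_matrices=False)
    normal = vt[-1]
    if normal[2] < 0:
        normal = -normal

    rotation = _rotation_to_z(normal)
    # after rotation the plane is horizontal; shift it to z = 0
    z_plane = (rotation @ centroid)[2]
    return RigidScaleTransform(rotation=rotation, translation=[0.0, 0.0, -z_plane])


def _rotation_to_z(normal: np.ndarray) -> np.ndarray:
    """Smallest rotation taking ``normal`` to (0, 0, 1) (Rodrigues)."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(normal, z)
    s = np.linalg.norm(v)
    c = float(normal @ z)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def sor_filter(
    cloud: ColoredPointCloud, k: int = 6, nsigma: float = 1.0
) -> tuple[ColoredPointCloud, np.ndarray]:
    """Statistical outlier removal.

    For every point compute the mean distance to its k nearest neighbors;
    points whose mean exceeds (global mean + nsigma * global std) of those
    per-point means are discarded. Permutation-invariant.
    """
    pts = cloud.points
    if len(pts) <= k:
        raise GeometryError(f"sor_filter needs more than k={k} points")
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=k + 1)  # first neighbor is the point itself
    mean_d = dists[:, 1:].mean(axis=1)
    thresh = mean_d.mean() + nsigma * mean_d.std()
    idx = np.flatnonzero(mean_d <= thresh)
    return cloud.select(idx), idx


def poisson_disk_subsample(
    cloud: ColoredPointCloud,
    radius: float,
    oversampling: int = 20,
    seed: int = 0,
) -> tuple[ColoredPointCloud, np.ndarray]:
    """Poisson-disk subsampling by seeded greedy dart throwing.

    Every input point is a candidate dart; candidates are visited in a
    seeded random order and accepted when no previously accepted point lies
    within ``radius``. The retained set therefore has minimum pairwise
    distance >= radius and, on dense input, reaches random-sequential-
    adsorption saturation density. ``oversampling`` is accepted for
    configuration compatibility with Monte-Carlo samplers; the full input
    cloud already serves as the candidate pool.
    """
    if radius <= 0:
        raise GeometryError("radius must be positive")
    pts = cloud.points
    n = len(pts)
    if n == 0:
        return cloud.select(np.array([], dtype=int)), np.array([], dtype=int)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    tree = cKDTree(pts)
    blocked = np.zeros(n, dtype=bool)
    kept: list[int] = []
    for i in order:
        if blocked[i]:
            continue
        kept.append(i)
        blocked[tree.query_ball_point(pts[i], radius)] = True
    idx = np.sort(np.array(kept, dtype=int))
    return cloud.select(idx), idx


def crop_box(
    cloud: ColoredPointCloud,
    lo: tuple[float, float, float] | None,
    hi: tuple[float, float, float] | None,
) -> tuple[ColoredPointCloud, np.ndarray]:
    """Axis-aligned crop, the headless stand-in for interactive removal of
    residual non-plant points (pot rim, clips). ``None`` bounds are open.
    """
    pts = cloud.points
    keep = np.ones(len(pts), dtype=bool)
    if lo is not None:
        keep &= np.all(pts >= np.asarray(lo, dtype=float), axis=1)
    if hi is not None:
        keep &= np.all(pts <= np.asarray(hi, dtype=float), axis=1)
    idx = np.flatnonzero(keep)
    return cloud.select(idx), idx
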