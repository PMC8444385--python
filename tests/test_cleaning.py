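"""Cleaning chain: scaling, color denoising, reorientation, SOR, subsampling."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from conftest import grid_cloud
from phenomesh.cleaning import (
    CleaningParams,
    color_filter,
    crop_box,
    fit_ground_plane,
    poisson_disk_subsample,
    scale_from_reference,
    sor_filter,
)
from phenomesh.geometry import ColoredPointCloud, GeometryError, apply_transform
from phenomesh.synthetic import (
    LABEL_BACKGROUND,
    SyntheticPlantSpec,
    generate_plant_mesh,
    sample_point_cloud,
)


class TestScaleFromReference:
    def test_pot_width_scaling(self):
        t = scale_from_reference(50.0, 200.0)
        assert t.scale == pytest.approx(4.0)

    def test_equal_lengths_give_identity(self):
        t = scale_from_reference(150.0, 150.0)
        assert t.scale == pytest.approx(1.0)

    def test_picked_points_reach_known_length(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(50, 3))
        i, j = 3, 17
        measured = np.linalg.norm(pts[i] - pts[j])
        t = scale_from_reference(measured, 150.0)
        out = t.apply_points(pts)
        assert np.linalg.norm(out[i] - out[j]) == pytest.approx(150.0, abs=1e-9)

    def test_non_positive_length_rejected(self):
        with pytest.raises(GeometryError):
            scale_from_reference(0.0, 100.0)


class TestColorFilter:
    def test_pure_green_retained_white_removed(self):
        cloud = ColoredPointCloud(
            np.zeros((2, 3)), np.array([[0, 255, 0], [255, 255, 255]], np.uint8)
        )
        kept, idx = color_filter(cloud)
        assert list(idx) == [0]

    def test_brown_retained(self):
        cloud = ColoredPointCloud(np.zeros((1, 3)), np.array([[120, 80, 40]], np.uint8))
        _, idx = color_filter(cloud)
        assert list(idx) == [0]

    def test_synthetic_background_exactly_removed(self):
        spec = SyntheticPlantSpec(seed=4, outlier_fraction=0.0)
        mesh, truth = generate_plant_mesh(spec)
        cloud, _ = sample_point_cloud(mesh, truth, spec, density_pts_per_mm2=1.0)
        kept, idx = color_filter(cloud)
        assert not np.any(kept.labels == LABEL_BACKGROUND)
        removed = np.setdiff1d(np.arange(len(cloud)), idx)
        assert np.all(cloud.labels[removed] == LABEL_BACKGROUND)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        cloud = ColoredPointCloud(
            rng.normal(size=(200, 3)),
            rng.integers(0, 256, (200, 3), dtype=np.uint8),
        )
        once, idx1 = color_filter(cloud)
        twice, idx2 = color_filter(once)
        assert len(idx2) == len(once)
        assert np.array_equal(twice.points, once.points)

    def test_colorless_cloud_rejected(self):
        with pytest.raises(GeometryError):
            color_filter(ColoredPointCloud(np.zeros((5, 3))))


class TestGroundPlane:
    def test_already_flat_gives_identity_rotation(self):
        cloud = grid_cloud()
        t = fit_ground_plane(cloud, seed=0)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-6)
        assert abs(t.translation[2]) < 1e-6

    def test_recovers_30_degree_tilt(self):
        theta = np.deg2rad(30)
        rot = np.array(
            [[1, 0, 0], [0, np.cos(theta), -np.sin(theta)],
             [0, np.sin(theta), np.cos(theta)]]
        )
        cloud = grid_cloud()
        tilted = ColoredPointCloud(cloud.points @ rot.T)
        t = fit_ground_plane(tilted, seed=0)
        flat = apply_transform(tilted, t)
        # the recovered frame should make the plane horizontal at z=0
        z = flat.points[:, 2]
        assert np.abs(z).max() < 1e-6
        normal_err = np.degrees(np.arccos(np.clip((t.rotation @ rot)[2, 2], -1, 1)))
        assert normal_err < 0.1

    def test_offset_plane_translated_to_zero(self):
        cloud = grid_cloud()
        lifted = ColoredPointCloud(cloud.points + [0, 0, 5.0])
        t = fit_ground_plane(lifted, seed=0)
        assert t.translation[2] == pytest.approx(-5.0, abs=1e-6)

    def test_collinear_support_rejected(self):
        pts = np.c_[np.arange(10.0), np.zeros(10), np.zeros(10)]
        with pytest.raises(GeometryError):
            fit_ground_plane(ColoredPointCloud(pts), seed=0)


class TestSorFilter:
    def test_single_far_point_removed(self):
        cloud = grid_cloud(n=10)
        pts = np.vstack([cloud.points, [[100.0, 0, 0]]])
        kept, idx = sor_filter(ColoredPointCloud(pts), k=6, nsigma=1.0)
        assert len(idx) == 100
        assert 100 not in idx

    def test_clean_grid_untouched_at_high_nsigma(self):
        kept, idx = sor_filter(grid_cloud(n=10), k=6, nsigma=10.0)
        assert len(idx) == 100

    def test_permutation_invariant(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(300, 3))
        _, idx = sor_filter(ColoredPointCloud(pts), k=6, nsigma=1.0)
        perm = rng.permutation(300)
        _, idx_p = sor_filter(ColoredPointCloud(pts[perm]), k=6, nsigma=1.0)
        assert set(perm[idx_p]) == set(idx)

    def test_too_few_points_rejected(self):
        with pytest.raises(GeometryError):
            sor_filter(ColoredPointCloud(np.zeros((5, 3))), k=6)

    def test_labeled_outliers_removed_plant_kept(self):
        # SOR runs after color denoising in the chain: the sparse white
        # backdrop is already gone and the far speckle is what remains
        spec = SyntheticPlantSpec(seed=2)
        mesh, truth = generate_plant_mesh(spec)
        cloud, _ = sample_point_cloud(mesh, truth, spec, density_pts_per_mm2=2.0)
        colored, _ = color_filter(cloud)
        kept, _ = sor_filter(colored, k=6, nsigma=1.0)
        out_total = (colored.labels == "outlier").sum()
        out_kept = (kept.labels == "outlier").sum()
        plant_total = (colored.labels == "plant").sum()
        plant_kept = (kept.labels == "plant").sum()
        assert 1 - out_kept / out_total >= 0.95
        assert plant_kept / plant_total >= 0.99


class TestPoissonDisk:
    def test_close_pair_keeps_exactly_one(self):
        pts = np.array([[0.0, 0, 0], [0.1, 0, 0]])
        kept, idx = poisson_disk_subsample(ColoredPointCloud(pts), 0.5, seed=0)
        assert len(idx) == 1

    def test_sparse_points_all_retained(self):
        kept, idx = poisson_disk_subsample(grid_cloud(n=5, spacing=2.0), 0.5, seed=0)
        assert len(idx) == 25

    def test_empty_input_empty_output(self):
        kept, idx = poisson_disk_subsample(
            ColoredPointCloud(np.zeros((0, 3))), 0.5, seed=0
        )
        assert len(kept) == 0

    def test_minimum_spacing_and_density(self):
        rng = np.random.default_rng(3)
        pts = np.c_[rng.uniform(0, 20, 60_000), rng.uniform(0, 20, 60_000),
                    np.zeros(60_000)]
        kept, _ = poisson_disk_subsample(ColoredPointCloud(pts), 0.5, seed=1)
        d, _ = cKDTree(kept.points).query(kept.points, k=2)
        assert d[:, 1].min() >= 0.45
        # density close to the 2D random-sequential-adsorption saturation bound
        rsa = 0.5472 * 4 * 400 / (np.pi * 0.5**2)
        assert abs(len(kept) / rsa - 1) < 0.25

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        cloud = ColoredPointCloud(rng.uniform(0, 10, (5000, 3)))
        _, a = poisson_disk_subsample(cloud, 0.5, seed=9)
        _, b = poisson_disk_subsample(cloud, 0.5, seed=9)
        assert np.array_equal(a, b)


class TestCropAndComposition:
    def test_crop_box_bounds(self):
        cloud = grid_cloud(n=10)
        kept, idx = crop_box(cloud, (2, 2, -1), (7, 7, 1))
        assert np.all(kept.points[:, 0] >= 2) and np.all(kept.points[:, 0] <= 7)

    def test_retained_indices_compose(self):
        rng = np.random.default_rng(11)
        cloud = ColoredPointCloud(
            rng.normal(size=(500, 3)),
            rng.integers(0, 256, (500, 3), dtype=np.uint8),
        )
        c1, i1 = color_filter(cloud)
        c2, i2 = sor_filter(c1, k=6, nsigma=2.0)
        assert np.array_equal(c2.points, cloud.points[i1[i2]])
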