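"""Per-triangle Heron geometry, height binning and normalized distributions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phenomesh.distribution import (
    bin_by_height,
    export_distribution_csv,
    export_triangle_csv,
    normalize_distribution,
    triangle_geometry,
)
from phenomesh.geometry import TriangleMesh
from phenomesh.synthetic import SyntheticPlantSpec, generate_plant_mesh


def _mesh_of(*tris):
    verts = np.array([v for tri in tris for v in tri], dtype=float)
    faces = np.arange(len(verts)).reshape(-1, 3)
    return TriangleMesh(verts, faces)


def _cross_area(tri):
    return 0.5 * np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0]))


class TestTriangleGeometry:
    def test_right_triangle_heron_classic(self):
        mesh = _mesh_of([[0, 0, 0], [3, 0, 0], [0, 4, 0]])
        rec = triangle_geometry(mesh)
        assert sorted(rec.edges[0]) == [3.0, 4.0, 5.0]
        assert rec.areas[0] == 6.0

    def test_equilateral_side_two(self):
        mesh = _mesh_of([[0, 0, 0], [2, 0, 0], [1, np.sqrt(3), 0]])
        assert triangle_geometry(mesh).areas[0] == pytest.approx(
            np.sqrt(3), rel=1e-12
        )

    def test_matches_cross_product_oracle_on_random_triangles(self):
        rng = np.random.default_rng(42)
        tris = rng.normal(scale=50, size=(10_000, 3, 3))
        mesh = TriangleMesh(
            tris.reshape(-1, 3), np.arange(30_000).reshape(-1, 3)
        )
        areas = triangle_geometry(mesh).areas
        oracle = np.array([_cross_area(t) for t in tris])
        assert np.max(np.abs(areas - oracle) / oracle) < 1e-10

    def test_needle_triangles_stay_accurate(self):
        # aspect ratio up to 1e4: base 1, height down to 1e-4
        rng = np.random.default_rng(7)
        heights = 10.0 ** rng.uniform(-4, 0, 500)
        for h in heights:
            mesh = _mesh_of([[0, 0, 0], [1, 0, 0], [0.5, h, 0]])
            area = triangle_geometry(mesh).areas[0]
            assert area == pytest.approx(h / 2, rel=1e-10)

    def test_degenerate_face_flagged_zero(self):
        mesh = _mesh_of([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        rec = triangle_geometry(mesh)
        assert rec.areas[0] == 0.0
        assert rec.degenerate[0]

    def test_centre_is_vertex_mean(self):
        mesh = _mesh_of([[0, 0, 0], [3, 0, 3], [0, 3, 6]])
        assert np.allclose(triangle_geometry(mesh).centres[0], [1, 1, 3])

    @given(st.integers(0, 2**32 - 1))
    def test_heron_equals_cross_product_property(self, seed):
        tri = np.random.default_rng(seed).normal(size=(3, 3))
        mesh = _mesh_of(tri)
        oracle = _cross_area(tri)
        if oracle > 1e-12:
            assert triangle_geometry(mesh).areas[0] == pytest.approx(
                oracle, rel=1e-10
            )


class TestBinByHeight:
    def test_two_triangles_two_bins(self):
        # centroids at z = 0.5 and 1.5; bins of 1 mm from the base (z = 0)
        mesh = _mesh_of(
            [[0, 0, 0.0], [1, 0, 0.5], [0, 1, 1.0]],
            [[0, 0, 1.0], [1, 0, 1.5], [0, 1, 2.0]],
        )
        dist = bin_by_height(triangle_geometry(mesh), 1.0)
        assert dist.nbins == 2
        assert (dist.bin_areas > 0).sum() == 2
        rec = triangle_geometry(mesh)
        assert dist.bin_areas[0] == pytest.approx(rec.areas[0])
        assert dist.bin_areas[1] == pytest.approx(rec.areas[1])

    def test_conservation_of_total_area(self):
        mesh, _ = generate_plant_mesh(SyntheticPlantSpec(seed=5))
        rec = triangle_geometry(mesh)
        dist = bin_by_height(rec, 1.0)
        assert dist.bin_areas.sum() == pytest.approx(rec.total_area, rel=1e-12)

    def test_uniform_vertical_strip_flat_profile(self):
        # vertical wall of identical square cells, 1 mm tall each
        tris = []
        for k in range(20):
            z = float(k)
            tris += [
                [[0, 0, z], [1, 0, z], [1, 0, z + 1]],
                [[0, 0, z], [1, 0, z + 1], [0, 0, z + 1]],
            ]
        dist = bin_by_height(triangle_geometry(_mesh_of(*tris)), 1.0)
        assert np.allclose(dist.bin_areas, 1.0)

    def test_top_edge_triangle_included(self):
        mesh = _mesh_of([[0, 0, 2.0], [1, 0, 2.0], [0, 1, 2.0]],
                        [[0, 0, 0.0], [1, 0, 0.0], [0, 1, 0.0]])
        dist = bin_by_height(triangle_geometry(mesh), 1.0)
        assert dist.bin_areas.sum() == pytest.approx(1.0)


class TestNormalizeDistribution:
    def test_single_triangle_step_at_midheight(self):
        eps = 1e-4
        mesh = _mesh_of(
            [[0, 0, 0], [eps, 0, 0], [0, eps, 0]],       # tiny base marker
            [[0, 0, 50], [1, 0, 50], [0, 1, 50]],        # the mass, at 50%
            [[0, 0, 100], [eps, 0, 100], [0, eps, 100]],  # tiny top marker
        )
        rec = triangle_geometry(mesh)
        dist = normalize_distribution(rec)
        cum = dist.cumulative
        assert cum[-1] == pytest.approx(1.0, abs=1e-9)
        mids = (dist.bin_edges[:-1] + dist.bin_edges[1:]) / 2
        step_bin = np.argmax(np.diff(np.concatenate([[0], cum])) > 0.4)
        assert 45 <= mids[step_bin] <= 55

    def test_cumulative_terminates_at_one(self):
        mesh, _ = generate_plant_mesh(SyntheticPlantSpec(seed=6))
        dist = normalize_distribution(triangle_geometry(mesh))
        assert dist.cumulative[-1] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(dist.cumulative) >= -1e-15)

    def test_two_layer_plant_mass_split(self):
        spec = SyntheticPlantSpec(
            seed=8, layer_fractions=(2 / 3, 1 / 3), n_branches=0
        )
        mesh, truth = generate_plant_mesh(spec)
        dist = normalize_distribution(triangle_geometry(mesh))
        mids = (dist.bin_edges[:-1] + dist.bin_edges[1:]) / 2
        low = dist.bin_areas[(mids > 10) & (mids < 30)].sum()
        up = dist.bin_areas[(mids > 70) & (mids < 90)].sum()
        leaf_total = 2 * truth.leaflet_one_sided_area_mm2
        expect_low = 2 * truth.layer_leaflet_areas_mm2[0] / truth.mesh_area_mm2
        expect_up = 2 * truth.layer_leaflet_areas_mm2[1] / truth.mesh_area_mm2
        assert low == pytest.approx(expect_low, abs=0.03)
        assert up == pytest.approx(expect_up, abs=0.03)
        assert low / (low + up) == pytest.approx(2 / 3, abs=0.03)

    def test_scale_invariance(self):
        mesh, _ = generate_plant_mesh(SyntheticPlantSpec(seed=9, n_leaflets=10))
        rec1 = triangle_geometry(mesh)
        mesh2 = TriangleMesh(mesh.vertices * 3.0, mesh.faces)
        rec2 = triangle_geometry(mesh2)
        d1, d2 = normalize_distribution(rec1), normalize_distribution(rec2)
        assert np.allclose(d1.bin_areas, d2.bin_areas, atol=1e-12)

    def test_zero_height_rejected(self, unit_square_mesh):
        rec = triangle_geometry(unit_square_mesh)
        with pytest.raises(ValueError):
            normalize_distribution(rec)  # flat mesh: zero height


class TestCsvExport:
    def test_single_triangle_row_and_columns(self, tmp_path):
        mesh = _mesh_of([[0, 0, 0], [3, 0, 0], [0, 4, 0]])
        path = tmp_path / "tri.csv"
        export_triangle_csv(triangle_geometry(mesh), path)
        df = pd.read_csv(path)
        assert df.shape == (1, 16)
        assert df["area"].iloc[0] == 6.0

    def test_reimport_reproduces_total_area(self, tmp_path):
        mesh, _ = generate_plant_mesh(SyntheticPlantSpec(seed=10, n_leaflets=8))
        rec = triangle_geometry(mesh)
        path = tmp_path / "t.csv"
        export_triangle_csv(rec, path)
        df = pd.read_csv(path)
        assert len(df) == mesh.n
        assert df["area"].sum() == pytest.approx(rec.total_area, rel=1e-12)

    def test_empty_mesh_header_only(self, tmp_path):
        mesh = TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        path = tmp_path / "e.csv"
        export_triangle_csv(triangle_geometry(mesh), path)
        assert len(path.read_text().strip().splitlines()) == 1

    def test_distribution_csv_columns(self, tmp_path):
        mesh, _ = generate_plant_mesh(SyntheticPlantSpec(seed=11, n_leaflets=5))
        dist = bin_by_height(triangle_geometry(mesh), 1.0)
        path = tmp_path / "d.csv"
        export_distribution_csv(dist, path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["bin_lo", "bin_hi", "area_mm2", "cumulative"]
        assert df["cumulative"].iloc[-1] == pytest.approx(
            df["area_mm2"].sum(), rel=1e-12
        )
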