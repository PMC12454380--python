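"""Alignment, scaling and trait-extraction oracles."""

import numpy as np
import pytest

from corncloud.cloudio import LabeledCloud
from corncloud.pheno import (
    PhenoConfig, PlaneDetectionError, align_to_z, bpa_surface_area,
    canopy_width, compute_scale, detect_ground_plane, heron_area,
    phenotype_scene, plant_height, rodrigues_matrix, voxel_volume,
)
from corncloud.synthgen import SceneSpec, generate_scene

RNG = np.random.default_rng(0)


def _cloud(points):
    return LabeledCloud(points=points, normals=np.zeros((len(points), 3)))


class TestAlignment:
    def test_identity_when_normal_is_z(self):
        _, tr = align_to_z(_cloud(np.zeros((1, 3))), [0, 0, 1])
        assert tr.theta == 0.0
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-12)

    def test_quarter_turn_from_y_normal(self):
        _, tr = align_to_z(_cloud(np.zeros((1, 3))), [0, 1, 0])
        assert tr.theta == pytest.approx(np.pi / 2)
        np.testing.assert_allclose(tr.rotation @ [0, 1, 0], [0, 0, 1], atol=1e-9)

    def test_antiparallel_normal_flips(self):
        _, tr = align_to_z(_cloud(np.zeros((1, 3))), [0, 0, -1])
        np.testing.assert_allclose(tr.rotation @ [0, 0, -1], [0, 0, 1], atol=1e-12)

    def test_thousand_random_tilts_map_to_z_orthonormally(self):
        for _ in range(1000):
            m = RNG.normal(size=3)
            m /= np.linalg.norm(m)
            _, tr = align_to_z(_cloud(np.zeros((1, 3))), m)
            np.testing.assert_allclose(tr.rotation @ m, [0, 0, 1], atol=1e-9)
            np.testing.assert_allclose(tr.rotation.T @ tr.rotation, np.eye(3),
                                       atol=1e-9)
            assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rodrigues_rejects_zero_axis(self):
        with pytest.raises(ValueError):
            rodrigues_matrix([0, 0, 0], 0.3)


class TestRansac:
    def test_horizontal_plane_with_outliers(self):
        pts = np.column_stack([RNG.uniform(-5, 5, 1000), RNG.uniform(-5, 5, 1000),
                               np.zeros(1000)])
        out = np.column_stack([RNG.uniform(-5, 5, 50), RNG.uniform(-5, 5, 50),
                               RNG.uniform(1, 5, 50)])
        normal, _, mask = detect_ground_plane(np.vstack([pts, out]), seed=1)
        np.testing.assert_allclose(np.abs(normal), [0, 0, 1], atol=1e-6)
        assert normal[2] > 0          # oriented toward the plants
        assert mask[:1000].sum() >= 950

    def test_vertical_plane_orientation(self):
        pts = np.column_stack([np.zeros(500), RNG.uniform(-5, 5, 500),
                               RNG.uniform(-5, 5, 500)])
        out = np.column_stack([RNG.uniform(1, 4, 30), RNG.uniform(-5, 5, 30),
                               RNG.uniform(-5, 5, 30)])
        normal, _, _ = detect_ground_plane(np.vstack([pts, out]), seed=2)
        np.testing.assert_allclose(normal, [1, 0, 0], atol=1e-6)

    def test_three_exact_points(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]])
        normal, d, mask = detect_ground_plane(pts, seed=0)
        np.testing.assert_allclose(np.abs(normal), [0, 0, 1], atol=1e-9)
        assert mask.all()

    def test_too_few_points_raises(self):
        with pytest.raises(PlaneDetectionError):
            detect_ground_plane(np.zeros((2, 3)))


class TestScaleAndSimpleTraits:
    def test_scale_factor_arithmetic(self):
        assert compute_scale(50.0, 25.0) == 0.5
        assert compute_scale(25.0, 25.0) == 1.0
        assert compute_scale(100.0, 25.0) == compute_scale(50.0, 25.0) / 2
        with pytest.raises(ValueError):
            compute_scale(0.0, 25.0)

    def test_height_examples(self):
        pts = np.array([[0, 0, 0], [0, 0, 1.3], [0, 0, 5.2]])
        assert plant_height(pts, 1.0) == pytest.approx(5.2)
        assert plant_height(np.array([[1, 2, 3.0]])) == 0.0
        with pytest.raises(ValueError):
            plant_height(np.empty((0, 3)))

    def test_canopy_345(self):
        pts = np.array([[0, 0, 0], [3, 0, 2], [0, 4, 5.0]])
        assert canopy_width(pts, 1.0) == pytest.approx(5.0)
        line = np.array([[1, 1, 0], [1, 1, 9.0]])
        assert canopy_width(line) == 0.0

    def test_canopy_invariant_under_quarter_turns(self):
        pts = RNG.normal(size=(100, 3))
        base = canopy_width(pts)
        for k in (1, 2, 3):
            th = k * np.pi / 2
            rot = np.array([[np.cos(th), -np.sin(th), 0],
                            [np.sin(th), np.cos(th), 0], [0, 0, 1]])
            assert canopy_width(pts @ rot.T) == pytest.approx(base, abs=1e-9)

    def test_height_canopy_translation_invariance(self):
        pts = RNG.normal(size=(50, 3))
        shifted = pts + np.array([10.0, -4.0, 2.5])
        assert plant_height(shifted) == pytest.approx(plant_height(pts), abs=1e-12)
        assert canopy_width(shifted) == pytest.approx(canopy_width(pts), abs=1e-12)


class TestVoxelVolume:
    @staticmethod
    def cube_grid(step=0.05):
        g = np.arange(0, 1.0, step)
        x, y, z = np.meshgrid(g, g, g)
        return np.column_stack([x.ravel(), y.ravel(), z.ravel()])

    def test_unit_cube_exactly_1000_voxels(self):
        vol = voxel_volume(self.cube_grid(), 1.0, 0.1)
        assert vol == pytest.approx(1.000, abs=1e-12)

    def test_single_point_one_voxel(self):
        assert voxel_volume(np.array([[0.3, 0.4, 0.5]])) == pytest.approx(0.001)

    def test_monotone_under_added_points(self):
        pts = RNG.uniform(0, 1, size=(100, 3))
        v1 = voxel_volume(pts)
        v2 = voxel_volume(np.vstack([pts, RNG.uniform(2, 3, size=(50, 3))]))
        assert v2 >= v1

    def test_subvoxel_translation_changes_at_most_a_shell(self):
        pts = self.cube_grid()
        base = voxel_volume(pts)
        shifted = voxel_volume(pts + np.array([0.03, 0.07, 0.04]))
        assert abs(shifted - base) / base <= 0.15

    def test_empty_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert voxel_volume(np.empty((0, 3))) == 0.0


class TestSurfaceArea:
    def test_heron_345_right_triangle(self):
        assert heron_area(3, 4, 5) == pytest.approx(6.0)

    def test_flat_grid_area_close_to_one(self):
        g = np.arange(0, 1.0001, 0.05)
        x, y = np.meshgrid(g, g)
        pts = np.column_stack([x.ravel(), y.ravel(), np.zeros(x.size)])
        area, mesh = bpa_surface_area(pts, 1.0, 0.2)
        assert area == pytest.approx(1.0, rel=0.10)
        # Heron sum agrees with the mesh library's area computation
        assert area == pytest.approx(mesh.area, rel=1e-9)

    def test_sphere_area_close_to_4pi(self):
        p = RNG.normal(size=(5000, 3))
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        area, _ = bpa_surface_area(p, 1.0, 0.2)
        assert area == pytest.approx(4 * np.pi, rel=0.10)

    def test_degenerate_input_zero_area(self):
        with pytest.warns(UserWarning):
            area, mesh = bpa_surface_area(np.zeros((2, 3)))
        assert area == 0.0 and len(mesh.faces) == 0


class TestScaleHomogeneity:
    """Traits in cm scale as k, k², k³ when the measurement grain scales too."""

    def test_homogeneity_of_all_four_traits(self):
        cloud, _ = generate_scene(SceneSpec(n_plants=1, seed=2, tilt_deg=0.0))
        pts = cloud.points[cloud.instance == 1]
        k = 2.0
        assert plant_height(pts, k) == pytest.approx(k * plant_height(pts, 1.0))
        assert canopy_width(pts, k) == pytest.approx(k * canopy_width(pts, 1.0))
        v1 = voxel_volume(pts, 1.0, voxel_side_cm=0.1)
        vk = voxel_volume(pts, k, voxel_side_cm=0.1 * k)
        assert vk == pytest.approx(k**3 * v1, rel=1e-9)
        a1, _ = bpa_surface_area(pts, 1.0, ball_radius_cm=0.2)
        ak, _ = bpa_surface_area(pts, k, ball_radius_cm=0.2 * k)
        assert ak == pytest.approx(k**2 * a1, rel=1e-6)


class TestPhenotypeScene:
    def test_ground_truth_labels_recover_manifest_heights(self):
        spec = SceneSpec(n_plants=3, seed=13, tilt_deg=12.0)
        cloud, records = generate_scene(spec)
        out, tr = phenotype_scene(
            cloud, config=PhenoConfig(compute_area=False, compute_volume=False))
        assert len(out) == 3
        for rec in out:
            gt = records[rec.plant_id - 1]
            assert rec.height_cm == pytest.approx(gt.height_cm, rel=0.02)
            assert rec.canopy_cm == pytest.approx(gt.canopy_cm, rel=0.05)
        assert tr.scale_k == pytest.approx(1.0, rel=0.02)

    def test_zero_plant_scene_empty_records(self):
        cloud, _ = generate_scene(SceneSpec(n_plants=0, seed=1))
        out, _ = phenotype_scene(
            cloud, config=PhenoConfig(compute_area=False, compute_volume=False))
        assert out == []

    def test_record_count_matches_instance_count(self):
        cloud, _ = generate_scene(SceneSpec(n_plants=4, seed=21))
        out, _ = phenotype_scene(
            cloud, config=PhenoConfig(compute_area=False, compute_volume=False))
        assert [r.plant_id for r in out] == [1, 2, 3, 4]
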