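"""Pose normalization: centering, planform orientation, bilateral symmetry."""

import numpy as np
import pytest
import trimesh

import morphogrid as mg
from morphogrid.mesh_io import MeshFormatError, face_geometry
from morphogrid.positioning import (
    FLIP_GROUP,
    PlanformAmbiguityWarning,
    _rotation_to_z,
)


def brute_force_silhouette_score(mesh, angle, stations=256):
    """Independent reference for the asymmetry score: per-station edge
    crossings computed with a plain Python loop over all mesh edges."""
    c, s = np.cos(angle), np.sin(angle)
    R = np.array([[c, -s], [s, c]])
    pts = mesh.vertices[:, :2] @ R.T
    edges = set()
    for f in mesh.faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            edges.add((min(a, b), max(a, b)))
    y_min, y_max = pts[:, 1].min(), pts[:, 1].max()
    dy = (y_max - y_min) / stations
    score = 0.0
    for j in range(stations):
        y = y_min + (j + 0.5) * dy
        xs = []
        for a, b in edges:
            y1, y2 = pts[a, 1], pts[b, 1]
            if (y1 - y) * (y2 - y) <= 0:
                if y1 == y2:
                    xs += [pts[a, 0], pts[b, 0]]
                else:
                    t = (y - y1) / (y2 - y1)
                    xs.append(pts[a, 0] + t * (pts[b, 0] - pts[a, 0]))
        if xs:
            score += abs(max(xs) + min(xs)) * dy
    return score


class TestCenterMesh:
    def test_already_centered(self, smooth_biface):
        centered, t0 = mg.center_mesh(smooth_biface)
        _, t1 = mg.center_mesh(centered)
        assert np.linalg.norm(t1) <= 1e-9 * smooth_biface.bbox_diagonal

    def test_shift_recovered(self, smooth_biface):
        centered, _ = mg.center_mesh(smooth_biface)
        shifted = centered.transformed(translation=[10.0, -5.0, 3.0])
        _, translation = mg.center_mesh(shifted)
        np.testing.assert_allclose(translation, [-10.0, 5.0, -3.0], atol=1e-9)

    def test_recentred_centroid_at_origin(self, noisy_biface, rng):
        R, t = mg.random_rigid_transform(rng)
        moved = noisy_biface.transformed(rotation=R, translation=t)
        centered, _ = mg.center_mesh(moved)
        centroid = face_geometry(centered)[2]
        assert np.linalg.norm(centroid) <= 1e-9 * moved.bbox_diagonal


class TestOrientPlanform:
    def test_thin_disc_mapped_to_xy_plane(self, rng):
        disc = trimesh.creation.cylinder(radius=10.0, height=0.05, sections=64)
        R, _ = mg.random_rigid_transform(rng)
        mesh = mg.TriangleMesh.from_trimesh(disc).transformed(rotation=R)
        oriented, _ = mg.orient_planform(mesh)
        normals, areas, _ = face_geometry(oriented)
        aligned_area = areas[np.abs(normals[:, 2]) >= 0.999].sum()
        assert aligned_area >= 0.90 * areas.sum()

    def test_planform_view_is_fixed_point(self, smooth_biface):
        centered, _ = mg.center_mesh(smooth_biface)
        _, rotation = mg.orient_planform(centered)
        # already in planform view: rotation is identity up to the
        # half-turn symmetry group
        err = min(
            np.abs(rotation - F).max() for F in FLIP_GROUP
        )
        assert err <= 1e-6

    def test_sphere_flags_ambiguity(self):
        sphere = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
        mesh = mg.TriangleMesh.from_trimesh(sphere)
        with pytest.warns(PlanformAmbiguityWarning):
            mg.orient_planform(mesh)

    def test_rotation_to_z_is_proper(self, rng):
        for _ in range(20):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            R = _rotation_to_z(v)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)
            target = R @ v if v[2] >= 0 else R @ -v
            np.testing.assert_allclose(target, [0, 0, 1], atol=1e-12)


class TestAsymmetryScore:
    def test_symmetric_outline_scores_zero(self, smooth_biface):
        area = smooth_biface.to_trimesh().area
        assert mg.asymmetry_score(smooth_biface, 0.0) <= 1e-6 * area

    def test_rotation_departs_from_zero(self, smooth_biface):
        assert mg.asymmetry_score(smooth_biface, np.deg2rad(10)) > 1.0

    def test_matches_brute_force_on_sheared_biface(self):
        mesh = mg.generate_biface(
            mg.BifaceParams(shear=0.15, relief_amp=1.0, resolution=8, seed=3)
        )
        for angle in (0.0, 0.3, 1.2):
            expected = brute_force_silhouette_score(mesh, angle)
            assert mg.asymmetry_score(mesh, angle) == pytest.approx(
                expected, rel=1e-9
            )

    def test_half_turn_periodicity(self, noisy_biface):
        for angle in (0.2, 0.9, 2.5):
            assert mg.asymmetry_score(noisy_biface, angle) == pytest.approx(
                mg.asymmetry_score(noisy_biface, angle + np.pi), rel=1e-9
            )


class TestOrientBilateral:
    def test_recovers_known_rotation(self, smooth_biface):
        theta = np.deg2rad(37.0)
        c, s = np.cos(theta), np.sin(theta)
        Rz = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        rotated = smooth_biface.transformed(rotation=Rz)
        _, rotation, _ = mg.orient_bilateral(rotated)
        recovered = np.rad2deg(np.arctan2(rotation[1, 0], rotation[0, 0]))
        assert min(abs((recovered + 37.0) % 180.0), abs((recovered + 37.0) % 180.0 - 180.0)) <= 0.1

    def test_optimal_mesh_stays_put(self, smooth_biface):
        _, rotation, _ = mg.orient_bilateral(smooth_biface)
        angle = np.rad2deg(abs(np.arctan2(rotation[1, 0], rotation[0, 0])))
        assert min(angle, 180.0 - angle) <= 0.1

    def test_length_axis_on_y(self, smooth_biface):
        oriented, _, _ = mg.orient_bilateral(smooth_biface)
        extent = oriented.vertices.max(axis=0) - oriented.vertices.min(axis=0)
        assert extent[1] == pytest.approx(120.0, rel=0.01)


class TestApplyReview:
    def test_flip_twice_is_identity(self, noisy_biface):
        twice = mg.apply_review(mg.apply_review(noisy_biface, flip_y=True), flip_y=True)
        np.testing.assert_array_equal(twice.vertices, noisy_biface.vertices)

    def test_four_quarter_turns_are_identity(self, noisy_biface):
        mesh = noisy_biface
        for _ in range(4):
            mesh = mg.apply_review(mesh, rotate_z_quarters=1)
        np.testing.assert_array_equal(mesh.vertices, noisy_biface.vertices)

    def test_flip_commutes_with_landmarking_up_to_index_mirror(self, smooth_biface):
        config = mg.GridConfig(4, 5)
        flipped_first = mg.fit_grid(
            mg.apply_review(smooth_biface, flip_y=True), config
        )
        landmarked_first = mg.fit_grid(smooth_biface, config)
        mirrored = mirror_landmark_indices(
            landmarked_first.coordinates, config
        ) @ np.diag([-1.0, 1.0, -1.0])
        np.testing.assert_allclose(
            flipped_first.coordinates, mirrored, atol=1e-6 * smooth_biface.bbox_diagonal
        )

    def test_bad_quarter_count_rejected(self, smooth_biface):
        with pytest.raises(ValueError):
            mg.apply_review(smooth_biface, rotate_z_quarters=4)


def mirror_landmark_indices(points: np.ndarray, config: mg.GridConfig) -> np.ndarray:
    """Landmark index permutation induced by the 180-degree Y flip:
    faces swap (upper <-> lower block) and stations reverse."""
    L, M = config.latitudes, config.per_latitude
    blocks = points.reshape(2, L, M, 3)
    return blocks[::-1, :, ::-1].reshape(-1, 3)


class TestFullProtocol:
    def test_rigid_invariance_small(self, noisy_biface, rng):
        canonical0, _ = mg.normalize_pose(noisy_biface, stations=128,
                                          coarse_step_deg=1.0)
        diag = noisy_biface.bbox_diagonal
        for _ in range(5):
            R, t = mg.random_rigid_transform(rng)
            moved = noisy_biface.transformed(rotation=R, translation=t)
            canonical, _ = mg.normalize_pose(moved, stations=128,
                                             coarse_step_deg=1.0)
            err = min(
                np.abs(canonical.vertices @ F.T - canonical0.vertices).max()
                for F in FLIP_GROUP
            )
            assert err <= 1e-3 * diag

    def test_positioning_is_rigid(self, noisy_biface, rng):
        canonical, pose = mg.normalize_pose(noisy_biface)
        idx = rng.choice(len(canonical.vertices), size=40, replace=False)
        before = np.linalg.norm(
            noisy_biface.vertices[idx, None] - noisy_biface.vertices[None, idx],
            axis=-1,
        )
        after = np.linalg.norm(
            canonical.vertices[idx, None] - canonical.vertices[None, idx], axis=-1
        )
        np.testing.assert_allclose(after, before, rtol=1e-9, atol=1e-9)

    def test_pose_result_rotation_proper(self, noisy_biface):
        _, pose = mg.normalize_pose(noisy_biface)
        np.testing.assert_allclose(
            pose.rotation @ pose.rotation.T, np.eye(3), atol=1e-9
        )
        assert np.linalg.det(pose.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_mesh_rejected(self):
        tiny = mg.TriangleMesh(np.zeros((3, 3)), [[0, 1, 2]])
        with pytest.raises(MeshFormatError):
            mg.normalize_pose(tiny)
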