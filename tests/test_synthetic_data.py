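"""Generator invariants: exact ground truth, rigidity, determinism."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import chi

import trimesh
from elbowaxis import synthetic_data as synth
from elbowaxis.axis_estimation import helical_axis_oracle

from conftest import direction_error_deg


class TestElbowParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"notch_radius": -1.0},
            {"notch_arc": 0.0},
            {"notch_arc": 360.0},
            {"mesh_resolution": 4.0},  # coarser than notch_radius / 4
            {"transcondylar_length": 0.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            synth.ElbowParams(**kwargs)


class TestDistalHumerus:
    def test_emits_exact_aspect_circles(self):
        params = synth.ElbowParams(medial_aspect_radius=10.0, transcondylar_length=40.0)
        _, truth = synth.make_distal_humerus(params)
        assert truth.medial_aspect.radius == 10.0
        sep = np.linalg.norm(truth.lateral_aspect.center - truth.medial_aspect.center)
        assert sep == pytest.approx(40.0, abs=1e-12)

    def test_mesh_watertight_outward(self, humerus):
        mesh, _ = humerus
        assert mesh.is_watertight
        assert mesh.is_winding_consistent
        assert mesh.volume > 0

    def test_too_coarse_resolution_rejected(self):
        # resolution passes the notch constraint but cannot resolve the disks
        params = synth.ElbowParams(
            notch_radius=40.0, medial_aspect_radius=1.0, lateral_aspect_radius=1.0,
            mesh_resolution=2.0,
        )
        with pytest.raises(ValueError, match="coarse"):
            synth.make_distal_humerus(params)


class TestProximalUlna:
    def test_notch_vertices_on_cylinder(self, ulna, params):
        mask = synth.notch_vertex_mask(ulna, tol=params.mesh_resolution)
        rel = ulna.mesh.vertices[mask] - ulna.notch_axis_point
        d = ulna.notch_axis_dir
        radial = np.linalg.norm(rel - np.outer(rel @ d, d), axis=1)
        assert mask.sum() > 100
        assert np.all(np.abs(radial - params.notch_radius) < params.mesh_resolution)

    def test_landmarks_on_notch_and_noncollinear(self, ulna, params):
        rel = ulna.landmarks - ulna.notch_axis_point
        d = ulna.notch_axis_dir
        radial = np.linalg.norm(rel - np.outer(rel @ d, d), axis=1)
        np.testing.assert_allclose(radial, params.notch_radius, atol=1e-9)
        area = 0.5 * np.linalg.norm(
            np.cross(ulna.landmarks[1] - ulna.landmarks[0], ulna.landmarks[2] - ulna.landmarks[0])
        )
        assert area > 1.0

    def test_watertight(self, ulna):
        assert ulna.mesh.is_watertight


class TestPoseSequence:
    def test_identity_trajectory_is_noop(self, ulna, humerus):
        _, humerus_truth = humerus
        traj = synth.AxisTrajectory(
            flexion_angles=np.array([0.0]),
            coronal_drift=lambda p: 0.0,
            horizontal_drift=lambda p: 0.0,
            axis_point_offset=lambda p: np.zeros(3),
        )
        meshes, landmarks, truth = synth.pose_sequence(ulna, traj, humerus_truth)
        np.testing.assert_array_equal(meshes[0].vertices, ulna.mesh.vertices)
        np.testing.assert_array_equal(landmarks[0], ulna.landmarks)
        assert truth.n_frames == 1

    def test_relative_rotation_recovered_by_registration_oracle(self, ulna, humerus):
        _, humerus_truth = humerus
        traj = synth.AxisTrajectory(
            flexion_angles=np.array([0.0, 30.0]),
            coronal_drift=lambda p: 0.0,
            horizontal_drift=lambda p: 0.0,
            axis_point_offset=lambda p: np.zeros(3),
        )
        meshes, _, truth = synth.pose_sequence(ulna, traj, humerus_truth)
        res = helical_axis_oracle(meshes[0], meshes[1])
        assert res.angle_deg == pytest.approx(30.0, abs=1e-9)
        assert direction_error_deg(res.axis.direction, truth.axis_dirs[0]) < 1e-7

    def test_drift_functions_recorded_exactly(self, ulna, humerus):
        _, humerus_truth = humerus
        rom = 90.0
        traj = synth.AxisTrajectory(
            flexion_angles=np.linspace(0, rom, 10),
            coronal_drift=lambda p: 0.0,
            horizontal_drift=lambda p: 45.0 * p / rom,
            axis_point_offset=lambda p: np.zeros(3),
        )
        _, _, truth = synth.pose_sequence(ulna, traj, humerus_truth)
        horiz = np.rad2deg(np.arctan2(truth.axis_dirs[:, 2], truth.axis_dirs[:, 0]))
        np.testing.assert_allclose(horiz, 45.0 * truth.flexion_deg / rom, atol=1e-9)

    def test_rigid_motion_preserves_edge_lengths(self, ulna, fixed_sequence):
        meshes, _, _ = fixed_sequence
        ref = np.sort(ulna.mesh.edges_unique_length)
        posed = np.sort(meshes[-1].edges_unique_length)
        np.testing.assert_allclose(posed, ref, atol=1e-9)

    def test_stored_axes_consistent_with_helical_between_frames(self, fixed_sequence):
        meshes, _, truth = fixed_sequence
        res = helical_axis_oracle(meshes[3], meshes[4])
        assert direction_error_deg(res.axis.direction, truth.axis_dirs[3]) < np.rad2deg(1e-6)

    def test_flexion_angles_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            synth.AxisTrajectory(
                flexion_angles=np.array([0.0, 10.0, 5.0]),
                coronal_drift=lambda p: 0.0,
                horizontal_drift=lambda p: 0.0,
                axis_point_offset=lambda p: np.zeros(3),
            )


class TestVertexNoise:
    def test_sigma_zero_is_identity(self, ulna):
        out = synth.add_vertex_noise(ulna.mesh, 0.0, seed=1)
        np.testing.assert_array_equal(out.vertices, ulna.mesh.vertices)

    def test_deterministic_per_seed(self, ulna):
        a = synth.add_vertex_noise(ulna.mesh, 0.3, seed=7)
        b = synth.add_vertex_noise(ulna.mesh, 0.3, seed=7)
        np.testing.assert_array_equal(a.vertices, b.vertices)
        c = synth.add_vertex_noise(ulna.mesh, 0.3, seed=8)
        assert not np.array_equal(a.vertices, c.vertices)

    def test_mean_displacement_matches_chi_distribution(self):
        # |N(0, sigma^2 I_3)| is chi(3)-distributed with mean sigma*sqrt(8/pi)
        sphere = trimesh.creation.icosphere(subdivisions=5)
        assert len(sphere.vertices) >= 10_000
        sigma = 0.2
        noisy = synth.add_vertex_noise(sphere, sigma, seed=3)
        disp = np.linalg.norm(noisy.vertices - sphere.vertices, axis=1)
        expected = chi(3, scale=sigma).mean()
        assert disp.mean() == pytest.approx(expected, rel=0.05)
        assert expected == pytest.approx(sigma * np.sqrt(8 / np.pi), rel=1e-12)


class TestWriteFixture:
    def test_round_trip(self, tmp_path, fixed_sequence, humerus):
        from elbowaxis import io

        meshes, landmarks, truth = fixed_sequence
        paths = synth.write_fixture(tmp_path, meshes[:3], _head(truth, 3), landmarks[:3])
        back = io.read_mesh(paths["frame_001"])
        np.testing.assert_allclose(back.vertices, meshes[1].vertices, atol=1e-4)
        lms = io.read_landmarks(paths["landmarks"])
        np.testing.assert_allclose(lms[2], landmarks[2], atol=1e-12)
        truth_back = io.read_ground_truth(paths["truth"])
        np.testing.assert_allclose(np.linalg.norm(truth_back.axis_dirs, axis=1), 1.0, atol=1e-12)

    def test_empty_mesh_list_rejected(self, tmp_path, fixed_sequence):
        _, _, truth = fixed_sequence
        with pytest.raises(ValueError, match="empty"):
            synth.write_fixture(tmp_path, [], truth)

    def test_fixture_files_byte_identical_per_seed(self, tmp_path):
        from elbowaxis.pipeline import make_fixture

        d1, d2 = tmp_path / "a", tmp_path / "b"
        make_fixture("noisy", d1, seed=5)
        make_fixture("noisy", d2, seed=5)
        for p1 in sorted(d1.iterdir()):
            assert p1.read_bytes() == (d2 / p1.name).read_bytes()


def _head(truth: synth.GroundTruth, n: int) -> synth.GroundTruth:
    return synth.GroundTruth(
        flexion_deg=truth.flexion_deg[:n],
        axis_points=truth.axis_points[:n],
        axis_dirs=truth.axis_dirs[:n],
        medial_aspect=truth.medial_aspect,
        lateral_aspect=truth.lateral_aspect,
        shaft_dir=truth.shaft_dir,
    )
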