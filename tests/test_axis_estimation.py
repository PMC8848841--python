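"""Axis construction: section curves, circle fits, line fits, recovery."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh
from hypothesis import given, strategies as st

from elbowaxis import synthetic_data as synth
from elbowaxis._geometry import GeometryError, Plane, apply_transform, make_transform
from elbowaxis.axis_estimation import (
    AxisEstimationError,
    EstimatorConfig,
    PlanarCurve,
    estimate_instantaneous_axis,
    fit_axis,
    fit_circle,
    helical_axis_oracle,
    offset_planes,
    plane_from_landmarks,
    section_curve,
)
from scipy.spatial.transform import Rotation

from conftest import direction_error_deg


class TestPlaneFromLandmarks:
    def test_axis_aligned_triangle(self):
        plane = plane_from_landmarks((0, 0, 0), (1, 0, 0), (0, 1, 0))
        assert abs(plane.normal @ np.array([0, 0, 1.0])) == pytest.approx(1.0)
        assert abs(plane.signed_distance(np.zeros(3))[0]) < 1e-12

    def test_collinear_rejected(self):
        with pytest.raises(GeometryError, match="collinear"):
            plane_from_landmarks((0, 0, 0), (1, 1, 1), (2, 2, 2))

    @given(st.integers(min_value=0, max_value=10_000))
    def test_random_triples_lie_on_plane(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-10, 10, (3, 3))
        area = 0.5 * np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0]))
        if area <= 1e-6:
            return
        plane = plane_from_landmarks(*pts)
        assert np.max(np.abs(plane.signed_distance(pts))) < 1e-9


class TestOffsetPlanes:
    def test_symmetric_offsets(self):
        base = Plane(point=np.zeros(3), normal=[0, 0, 1])
        planes = offset_planes(base, [0, 0, 1], spacing=1.0, count=11)
        zs = [p.point[2] for p in planes]
        np.testing.assert_allclose(zs, np.arange(-5, 6), atol=1e-12)

    @pytest.mark.parametrize("kwargs", [{"count": 1}, {"spacing": 0.0}])
    def test_degenerate_requests_rejected(self, kwargs):
        base = Plane(point=np.zeros(3), normal=[0, 0, 1])
        with pytest.raises(ValueError):
            offset_planes(base, [0, 0, 1], **{"spacing": 1.0, "count": 11, **kwargs})


class TestFitCircle:
    @pytest.mark.parametrize("arc", [2 * np.pi, np.pi])  # full circle and semicircle
    def test_exact_points_recovered(self, arc):
        theta = np.linspace(0, arc, 100, endpoint=False)
        pts = np.column_stack(
            [3 + 12 * np.cos(theta), 4 + 12 * np.sin(theta), np.zeros_like(theta)]
        )
        curve = PlanarCurve(points=pts, plane=Plane(point=np.zeros(3), normal=[0, 0, 1]))
        fit = fit_circle(curve)
        np.testing.assert_allclose(fit.center, [3, 4, 0], atol=1e-9)
        assert fit.radius == pytest.approx(12.0, abs=1e-9)
        assert fit.rms_residual < 1e-9

    def test_noisy_arc_matches_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        theta = np.linspace(0.3, 2.0, 20)
        xy = np.column_stack([3 + 12 * np.cos(theta), 4 + 12 * np.sin(theta)])
        xy = xy + rng.normal(0, 0.1, xy.shape)
        pts = np.column_stack([xy, np.zeros(20)])
        curve = PlanarCurve(points=pts, plane=Plane(point=np.zeros(3), normal=[0, 0, 1]))
        fit = fit_circle(curve)
        # independent oracle: dense grid search over center candidates,
        # radius profiled out as the mean distance
        gx = np.linspace(2.0, 4.0, 201)
        gy = np.linspace(3.0, 5.0, 201)
        best = (np.inf, 0.0, 0.0)
        for cx in gx:
            d = np.sqrt((xy[:, 0] - cx) ** 2 + (xy[:, 1] - gy[:, None]) ** 2)
            r = d.mean(axis=1)
            sse = ((d - r[:, None]) ** 2).sum(axis=1)
            i = int(np.argmin(sse))
            if sse[i] < best[0]:
                best = (sse[i], cx, gy[i])
        assert np.hypot(fit.center[0] - best[1], fit.center[1] - best[2]) < 0.15

    def test_short_arc_rejected(self):
        theta = np.linspace(0, np.deg2rad(40), 20)  # 40 deg < 60 deg guard
        pts = np.column_stack([12 * np.cos(theta), 12 * np.sin(theta), np.zeros(20)])
        curve = PlanarCurve(points=pts, plane=Plane(point=np.zeros(3), normal=[0, 0, 1]))
        with pytest.raises(AxisEstimationError, match="ill-conditioned"):
            fit_circle(curve)


class TestFitAxis:
    def test_exact_collinear_centers(self):
        d = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        centers = np.outer(np.arange(11) - 5, d)
        axis = fit_axis(centers)
        assert direction_error_deg(axis.direction, d) < 1e-9
        assert axis.rms_residual < 1e-12

    def test_noisy_centers_within_half_degree(self):
        rng = np.random.default_rng(0)
        d = np.array([1.0, 0.2, -0.1])
        d /= np.linalg.norm(d)
        t = np.linspace(-5, 5, 11)
        centers = np.outer(t, d) + rng.normal(0, 0.05, (11, 3))
        axis = fit_axis(centers)
        assert direction_error_deg(axis.direction, d) < 0.5

    def test_coincident_centers_rejected(self):
        with pytest.raises(AxisEstimationError, match="degenerate"):
            fit_axis(np.ones((5, 3)))

    def test_sign_follows_lateral_hint(self):
        centers = np.outer(np.arange(5), [-1.0, 0, 0])
        axis = fit_axis(centers, lateral_hint=np.array([1.0, 0, 0]))
        assert axis.direction[0] > 0


class TestSectionCurve:
    def test_perpendicular_cylinder_section_is_circle(self):
        cyl = trimesh.creation.cylinder(radius=10.0, height=30.0, sections=64)
        plane = Plane(point=np.array([0, 0, 2.0]), normal=[0, 0, 1])
        curve = section_curve(cyl, plane, near=np.array([10.0, 0, 2.0]))
        assert curve.closed
        radial = np.linalg.norm(curve.points[:, :2], axis=1)
        # chordal triangulation: points sit inside the true circle by up to
        # the sagitta r (1 - cos(pi/sections))
        sagitta = 10.0 * (1 - np.cos(np.pi / 64))
        assert np.all(radial <= 10.0 + 1e-9)
        assert np.all(radial >= 10.0 - sagitta - 1e-9)
        fit = fit_circle(curve)
        assert fit.radius == pytest.approx(10.0, abs=2 * sagitta)

    def test_missing_plane_rejected(self, ulna):
        plane = Plane(point=np.array([0, 0, 100.0]), normal=[0, 0, 1])
        with pytest.raises(AxisEstimationError, match="intersect"):
            section_curve(ulna.mesh, plane, near=np.zeros(3))

    def test_notch_arc_selected_not_far_cortex(self, ulna, params):
        plane = Plane(point=np.zeros(3), normal=[1.0, 0, 0])
        near = ulna.landmarks.mean(axis=0)
        curve = section_curve(ulna.mesh, plane, near)
        radial = np.linalg.norm(curve.points[:, 1:], axis=1)
        assert np.all(np.abs(radial - params.notch_radius) < params.mesh_resolution)


class TestEstimateInstantaneousAxis:
    def test_ideal_recovery(self, ulna, estimator_config):
        axis = estimate_instantaneous_axis(ulna.mesh, ulna.landmarks, estimator_config)
        assert direction_error_deg(axis.direction, ulna.notch_axis_dir) < 0.1
        assert axis.distance_to_point(ulna.notch_axis_point) < 0.1

    def test_axis_rides_with_the_bone(self, ulna, humerus, estimator_config):
        _, humerus_truth = humerus
        traj = synth.AxisTrajectory(
            flexion_angles=np.array([40.0]),
            coronal_drift=lambda p: 0.0,
            horizontal_drift=lambda p: 0.0,
            axis_point_offset=lambda p: np.zeros(3),
        )
        meshes, landmarks, truth = synth.pose_sequence(ulna, traj, humerus_truth)
        axis = estimate_instantaneous_axis(meshes[0], landmarks[0], estimator_config)
        assert direction_error_deg(axis.direction, truth.axis_dirs[0]) < 0.1
        assert axis.distance_to_point(truth.axis_points[0]) < 0.1

    def test_jittered_landmarks_stay_accurate(self, fixed_sequence, estimator_config):
        meshes, landmarks, truth = fixed_sequence
        for i in (0, 10, 20, 29):
            jittered = synth.jitter_landmarks(landmarks[i], 0.5, seed=100 + i)
            axis = estimate_instantaneous_axis(
                meshes[i], jittered, estimator_config, frame_index=i
            )
            assert direction_error_deg(axis.direction, truth.axis_dirs[i]) < 2.0

    def test_rigid_equivariance(self, ulna, estimator_config):
        rng = np.random.default_rng(5)
        R = Rotation.random(random_state=np.random.RandomState(5)).as_matrix()
        t = rng.uniform(-30, 30, 3)
        T = make_transform(R, t)
        mesh_t = ulna.mesh.copy()
        mesh_t.apply_transform(T)
        lms_t = apply_transform(T, ulna.landmarks)
        cfg = EstimatorConfig(lateral_hint=R @ np.array([1.0, 0, 0]))
        axis = estimate_instantaneous_axis(ulna.mesh, ulna.landmarks, estimator_config)
        axis_t = estimate_instantaneous_axis(mesh_t, lms_t, cfg)
        np.testing.assert_allclose(axis_t.direction, R @ axis.direction, atol=1e-6)
        expected_point = apply_transform(T, axis.point)
        assert axis_t.distance_to_point(expected_point) < 1e-6

    def test_offset_direction_symmetry(self, ulna, estimator_config):
        flipped = np.asarray(ulna.landmarks)[[0, 2, 1]]  # reverses the plane normal
        a = estimate_instantaneous_axis(ulna.mesh, ulna.landmarks, estimator_config)
        b = estimate_instantaneous_axis(ulna.mesh, flipped, estimator_config)
        # reversed resampling order perturbs the sampled points slightly;
        # the recovered line agrees far below the mesh resolution
        assert direction_error_deg(a.direction, b.direction) < 1e-3
        assert b.distance_to_point(a.point) < 1e-3

    def test_residuals_bounded_by_resolution(self, fixed_axes, params):
        for axis in fixed_axes:
            for fit in axis.circle_fits:
                assert fit.rms_residual <= params.mesh_resolution

    def test_landmarks_off_surface_rejected(self, ulna):
        cfg = EstimatorConfig(surface_tol=2 * ulna.params.mesh_resolution)
        bad = ulna.landmarks + np.array([0, 0, 10.0])
        with pytest.raises(AxisEstimationError, match="landmark"):
            estimate_instantaneous_axis(ulna.mesh, bad, cfg)


class TestHelicalAxisOracle:
    def test_exact_rotation_recovered(self, ulna):
        from elbowaxis._geometry import rigid_about_line

        T = rigid_about_line(np.array([1.0, 2.0, 3.0]), np.array([0, 1.0, 0]), 30.0)
        rotated = ulna.mesh.copy()
        rotated.apply_transform(T)
        res = helical_axis_oracle(ulna.mesh, rotated)
        assert res.reliable
        assert res.angle_deg == pytest.approx(30.0, abs=1e-9)
        assert direction_error_deg(res.axis.direction, np.array([0, 1.0, 0])) < np.rad2deg(1e-9)

    def test_identity_flagged_unreliable(self, ulna):
        res = helical_axis_oracle(ulna.mesh, ulna.mesh.copy())
        assert not res.reliable

    def test_noisy_correspondence(self, ulna):
        from elbowaxis._geometry import rigid_about_line

        T = rigid_about_line(np.zeros(3), np.array([1.0, 0, 0]), 30.0)
        rotated = ulna.mesh.copy()
        rotated.apply_transform(T)
        noisy = synth.add_vertex_noise(rotated, 0.1, seed=2)
        res = helical_axis_oracle(ulna.mesh, noisy)
        assert direction_error_deg(res.axis.direction, np.array([1.0, 0, 0])) < 0.5
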