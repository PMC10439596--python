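"""Geometric primitives: circle fits, axes, projections, signed angles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import least_squares

from femrot import (
    CrossSection,
    DegenerateAxisError,
    DegenerateFitError,
    DegenerateProjectionError,
    Line3,
    Plane3,
    anatomical_axis,
    angle_between_lines,
    fit_circle,
    mechanical_axis,
    project_direction,
    rotate_in_plane,
    signed_angle,
    transverse_plane,
)

XY_PLANE = Plane3(point=np.zeros(3), normal=np.array([0.0, 0.0, 1.0]))


def embed(xy_points, z=0.0):
    pts = np.asarray(xy_points, dtype=float)
    return np.column_stack([pts, np.full(len(pts), z)])


class TestFitCircle:
    @pytest.mark.parametrize(
        "points, center, radius",
        [
            ([(1, 0), (0, 1), (-1, 0), (0, -1)], (0, 0), 1.0),
            ([(0, 0), (2, 0), (1, 1), (1, -1)], (1, 0), 1.0),
        ],
    )
    def test_exact_on_hand_examples(self, points, center, radius):
        section = CrossSection(points=embed(points), section_plane=XY_PLANE)
        c, r = fit_circle(section)
        np.testing.assert_allclose(c[:2], center, atol=1e-12)
        np.testing.assert_allclose(c[2], 0.0, atol=1e-12)
        assert r == pytest.approx(radius, abs=1e-12)

    def test_exact_on_noise_free_circle(self, rng):
        t = rng.uniform(0, 2 * math.pi, 40)
        pts = embed(np.column_stack([10 + 15 * np.cos(t), -5 + 15 * np.sin(t)]))
        c, r = fit_circle(CrossSection(points=pts, section_plane=XY_PLANE))
        np.testing.assert_allclose(c, [10, -5, 0], atol=1e-9)
        assert r == pytest.approx(15.0, abs=1e-9)

    def test_matches_geometric_least_squares_under_noise(self, rng):
        """Kåsa center within 0.05 mm of an iterative geometric fit at 0.1 mm noise."""
        t = rng.uniform(0, 2 * math.pi, 50)
        x = 10 + 15 * np.cos(t) + rng.normal(0, 0.1, 50)
        y = -5 + 15 * np.sin(t) + rng.normal(0, 0.1, 50)
        c, r = fit_circle(CrossSection.from_points(embed(np.column_stack([x, y]))))

        def resid(p):
            return np.hypot(x - p[0], y - p[1]) - p[2]

        sol = least_squares(resid, [9.0, -4.0, 14.0]).x
        assert np.hypot(c[0] - sol[0], c[1] - sol[1]) < 0.05
        assert abs(r - sol[2]) < 0.05

    def test_collinear_points_raise(self):
        pts = embed([(0, 0), (1, 0), (2, 0), (3, 0)])
        with pytest.raises(DegenerateFitError):
            fit_circle(CrossSection(points=pts, section_plane=XY_PLANE))

    def test_out_of_plane_points_rejected(self):
        pts = embed([(1, 0), (0, 1), (-1, 0)])
        pts[0, 2] = 1.0
        with pytest.raises(DegenerateFitError):
            CrossSection(points=pts, section_plane=XY_PLANE)


class TestAxes:
    def test_anatomical_axis_orientation(self):
        line = anatomical_axis(canal_center=(0, 0, 300), notch_apex_center=(0, 0, 0))
        np.testing.assert_allclose(line.direction, [0, 0, 1], atol=1e-12)

    def test_anatomical_axis_same_line_under_swap(self):
        a = anatomical_axis((1, 2, 300), (0, 0, 0))
        b = anatomical_axis((0, 0, 0), (1, 2, 300))
        np.testing.assert_allclose(a.canonical_direction(), b.canonical_direction(), atol=1e-12)

    def test_coincident_centers_raise(self):
        with pytest.raises(DegenerateAxisError):
            anatomical_axis((1, 1, 1), (1, 1, 1))

    def test_mechanical_axis_identity_at_zero_valgus(self):
        anat = Line3(point=np.zeros(3), direction=[0, 0, 1])
        mech = mechanical_axis(anat, 0.0, "right", anterior=[0, 1, 0])
        np.testing.assert_allclose(mech.direction, anat.direction, atol=1e-12)

    def test_mechanical_axis_valgus_worked_example(self):
        """An anatomical axis tilted 7.9° in the coronal plane maps onto +Z."""
        a = math.radians(7.9)
        anat = Line3(point=np.zeros(3), direction=[math.sin(a), 0, math.cos(a)])
        mech = mechanical_axis(anat, 7.9, "right", anterior=[0, 1, 0])
        np.testing.assert_allclose(mech.direction, [0, 0, 1], atol=1e-12)
        assert angle_between_lines(mech.direction, anat.direction) == pytest.approx(7.9, abs=1e-9)

    @pytest.mark.parametrize("alpha", [1.0, 5.3, 7.9, 12.7, 20.0])
    @pytest.mark.parametrize("side", ["right", "left"])
    def test_mechanical_axis_angle_equals_alpha(self, alpha, side):
        anat = Line3(point=np.zeros(3), direction=[0.2, 0.3, 0.93])
        mech = mechanical_axis(anat, alpha, side, anterior=[0, 1, 0])
        assert angle_between_lines(mech.direction, anat.direction) == pytest.approx(alpha, abs=1e-9)

    def test_anterior_parallel_to_axis_raises(self):
        anat = Line3(point=np.zeros(3), direction=[0, 0, 1])
        with pytest.raises(DegenerateAxisError):
            mechanical_axis(anat, 7.9, "right", anterior=[0, 0, 1])


class TestPlaneAndProjection:
    def test_transverse_plane_contains_point(self):
        mech = Line3(point=np.zeros(3), direction=[0, 0, 1])
        plane = transverse_plane(mech, through=(5, 6, 7))
        assert plane.signed_distance((1, -2, 7)) == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(plane.normal, mech.direction)

    def test_projection_idempotent_and_unit(self):
        d = np.array([0.6, 0.8, 0.0])
        out = project_direction(d, XY_PLANE)
        np.testing.assert_allclose(out, d, atol=1e-12)
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)

    def test_projection_drops_normal_component(self):
        out = project_direction(np.array([1.0, 0.0, 1.0]) / math.sqrt(2), XY_PLANE)
        np.testing.assert_allclose(out, [1, 0, 0], atol=1e-12)

    @given(st.lists(st.floats(-1, 1), min_size=3, max_size=3))
    def test_projection_matches_gram_schmidt(self, comps):
        d = np.array(comps)
        n = XY_PLANE.normal
        gs = d - np.dot(d, n) * n
        if np.linalg.norm(gs) < 1e-6:
            return
        out = project_direction(d, XY_PLANE)
        np.testing.assert_allclose(out, gs / np.linalg.norm(gs), atol=1e-12)

    def test_normal_direction_raises(self):
        with pytest.raises(DegenerateProjectionError):
            project_direction(np.array([0.0, 0.0, 1.0]), XY_PLANE)


def _atan2_line_angle(a, b):
    """Independent oracle: atan2 angle with undirected-line normalization."""
    raw = math.degrees(math.atan2(a[0] * b[1] - a[1] * b[0], a[0] * b[0] + a[1] * b[1]))
    while raw > 90:
        raw -= 180
    while raw <= -90:
        raw += 180
    return raw


class TestSignedAngle:
    def test_zero_for_equal_directions(self):
        d = np.array([0.6, 0.8, 0.0])
        assert signed_angle(d, d, XY_PLANE, "right") == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("side", ["right", "left"])
    def test_external_rotation_is_positive(self, side):
        d = np.array([1.0, 0.0, 0.0])
        rot = rotate_in_plane(d, 3.0, XY_PLANE, "external", side)
        assert signed_angle(d, rot, XY_PLANE, side) == pytest.approx(3.0, abs=1e-12)
        rot_int = rotate_in_plane(d, 3.0, XY_PLANE, "internal", side)
        assert signed_angle(d, rot_int, XY_PLANE, side) == pytest.approx(-3.0, abs=1e-12)

    def test_grid_against_atan2_oracle(self):
        """Exhaustive rotation grid over (-180, 180], right femur."""
        base = np.array([1.0, 0.0, 0.0])
        for theta in np.arange(-179.5, 180.5, 0.5):
            t = math.radians(theta)
            d = np.array([math.cos(t), math.sin(t), 0.0])
            got = signed_angle(base, d, XY_PLANE, "right")
            want = _atan2_line_angle(base[:2], d[:2])
            assert got == pytest.approx(want, abs=1e-9), theta

    @given(st.floats(0.5, 89.5), st.floats(-180, 180))
    def test_antisymmetry(self, offset, start):
        t0 = math.radians(start)
        t1 = math.radians(start + offset)
        a = np.array([math.cos(t0), math.sin(t0), 0.0])
        b = np.array([math.cos(t1), math.sin(t1), 0.0])
        assert signed_angle(a, b, XY_PLANE, "right") == pytest.approx(
            -signed_angle(b, a, XY_PLANE, "right"), abs=1e-9
        )

    @given(st.floats(0.01, 90.0), st.floats(-180, 180))
    def test_rotate_then_measure_composition(self, theta, start):
        t0 = math.radians(start)
        d = np.array([math.cos(t0), math.sin(t0), 0.0])
        rot = rotate_in_plane(d, theta, XY_PLANE, "external", "right")
        assert signed_angle(d, rot, XY_PLANE, "right") == pytest.approx(theta, abs=1e-9)

    def test_result_range_is_half_open(self):
        d = np.array([1.0, 0.0, 0.0])
        perp = rotate_in_plane(d, 90.0, XY_PLANE, "external", "right")
        assert signed_angle(d, perp, XY_PLANE, "right") == pytest.approx(90.0, abs=1e-9)
        assert abs(np.dot(d, perp)) < 1e-12

    def test_zero_norm_raises(self):
        with pytest.raises(ValueError):
            signed_angle(np.zeros(3), np.array([1.0, 0, 0]), XY_PLANE, "right")


class TestRigidMotion:
    def test_all_ops_invariant_under_rigid_motion(self, rng):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", [33, -71, 12], degrees=True).as_matrix()
        t = np.array([14.0, -3.0, 8.0])
        circle_t = rng.uniform(0, 2 * math.pi, 30)
        pts = embed(np.column_stack([3 + 7 * np.cos(circle_t), 1 + 7 * np.sin(circle_t)]))
        c0, r0 = fit_circle(CrossSection.from_points(pts))
        c1, r1 = fit_circle(CrossSection.from_points(pts @ R.T + t))
        np.testing.assert_allclose(c1, R @ c0 + t, atol=1e-9)
        assert r1 == pytest.approx(r0, abs=1e-9)

        anat = Line3(point=np.zeros(3), direction=[0.1, 0.05, 0.99])
        anat_m = Line3(point=t, direction=R @ anat.direction)
        mech = mechanical_axis(anat, 6.5, "right", anterior=[0, 1, 0])
        mech_m = mechanical_axis(anat_m, 6.5, "right", anterior=R @ np.array([0, 1, 0.0]))
        np.testing.assert_allclose(mech_m.direction, R @ mech.direction, atol=1e-9)
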