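"""Differential-geometry kernels: frames, curvatures, geodesic residuals."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fibersurf as fs
from fibersurf.geometry import DomainError

from conftest import HALF, L, R, RHO


def cylinder_profile(r=1.0):
    return fs.ProfileCurve.from_callable(
        lambda z: r + 0.0 * z, -HALF, HALF, lambda z: 0.0 * z, lambda z: 0.0 * z
    )


def circle_curve(r, n=721):
    t = np.linspace(0.0, 2 * math.pi, n)
    pts = np.column_stack([r * np.cos(t), r * np.sin(t), np.zeros_like(t)])
    d1 = np.column_stack([-r * np.sin(t), r * np.cos(t), np.zeros_like(t)])
    d2 = np.column_stack([-r * np.cos(t), -r * np.sin(t), np.zeros_like(t)])
    return fs.curve_frame(pts, t=t, first_deriv=d1, second_deriv=d2)


class TestProfileCurve:
    def test_invariants_enforced(self):
        with pytest.raises(DomainError):
            fs.ProfileCurve([0.0, 0.0], [1.0, 1.0], [0.0, 0.0], [0.0, 0.0])
        with pytest.raises(DomainError):
            fs.ProfileCurve([0.0, 1.0], [1.0, -1.0], [0.0, 0.0], [0.0, 0.0])

    def test_derivatives_consistent_with_finite_differences(self, fixtures):
        for name, entry in fixtures.items():
            if name.startswith("stack"):
                continue  # kinked at joints: nodal derivatives only
            p = entry["profile"]
            z = np.linspace(p.z_min + 0.01, p.z_max - 0.01, 41)
            h = 1e-5
            fd1 = (p(z + h) - p(z - h)) / (2 * h)
            fd2 = (p(z + h) - 2 * p(z) + p(z - h)) / h**2
            assert np.allclose(p(z, 1), fd1, atol=1e-7), name
            assert np.allclose(p(z, 2), fd2, atol=1e-4), name

    def test_out_of_range_raises(self):
        p = cylinder_profile()
        with pytest.raises(DomainError):
            p(2 * HALF)


class TestSurfaceMap:
    @pytest.mark.parametrize(
        "theta,z,expected",
        [(0.0, 0.0, (1, 0, 0)), (math.pi / 2, 0.5, (0, 1, 0.5))],
    )
    def test_surface_point_on_cylinder(self, theta, z, expected):
        pt = fs.surface_point(theta, z, cylinder_profile())
        assert np.allclose(pt, expected, atol=1e-12)

    def test_surface_point_on_sphere_boundary_circle(self, fixtures):
        # the sphere's boundary circle: g(L/2) = R exactly
        pt = fs.surface_point(0.0, HALF, fixtures["sphere"]["profile"])
        assert np.allclose(pt, (R, 0.0, HALF), atol=1e-9)

    def test_cylinder_normal_is_radial(self):
        n = fs.surface_normal(0.7, 0.3, cylinder_profile())
        assert np.allclose(n, (math.cos(0.7), math.sin(0.7), 0.0), atol=1e-12)

    def test_sphere_normal_points_through_center(self, fixtures):
        p = fixtures["sphere"]["profile"]
        z = 0.4
        n = fs.surface_normal(0.0, z, p)
        assert np.allclose(n, (p(z) / RHO, 0.0, z / RHO), atol=1e-9)

    def test_catenoid_normal_orthogonal_to_meridian_tangent(self, fixtures):
        p = fixtures["catenoid"]["profile"]
        z = np.linspace(-0.6, 0.6, 31)
        n = fs.surface_normal(0.0, z, p)
        tangent = np.column_stack([p(z, 1), np.zeros_like(z), np.ones_like(z)])
        tangent /= np.linalg.norm(tangent, axis=1)[:, None]
        assert np.max(np.abs(np.sum(n * tangent, axis=1))) < 1e-12

    def test_frame_right_handed_and_orthonormal(self, fixtures):
        p = fixtures["hyperboloid"]["profile"]
        th = np.linspace(0, 2 * math.pi, 17)
        frame = fs.surface_frame(th, 0.3 * np.ones_like(th), p)
        for v in (frame.outward_normal, frame.meridian_dir, frame.circumferential_dir):
            assert np.allclose(np.linalg.norm(v, axis=-1), 1.0, atol=1e-12)
        cross = np.cross(frame.circumferential_dir, frame.meridian_dir)
        assert np.allclose(cross, frame.outward_normal, atol=1e-10)
        assert (
            np.max(np.abs(np.sum(frame.meridian_dir * frame.outward_normal, axis=-1)))
            < 1e-10
        )


class TestCurveFrame:
    @pytest.mark.parametrize("r", [0.1, 1.0, 10.0])
    def test_circle_curvature_and_center_pointing_normal(self, r):
        curve = circle_curve(r)
        assert np.max(np.abs(curve.curvature - 1.0 / r)) < 1e-10
        # principal normal points to the center
        expected = -curve.points / r
        expected[:, 2] = 0.0
        assert np.allclose(curve.principal_normal, expected, atol=1e-10)

    def test_helix_curvature_matches_waist_angle(self):
        # helix on the unit cylinder crossing the waist at angle mu from z
        mu = math.radians(35.0)
        t = np.linspace(0, 4 * math.pi, 1001)
        c = 1.0 / math.tan(mu)
        pts = np.column_stack([np.cos(t), np.sin(t), c * t])
        d1 = np.column_stack([-np.sin(t), np.cos(t), c * np.ones_like(t)])
        d2 = np.column_stack([-np.cos(t), -np.sin(t), np.zeros_like(t)])
        curve = fs.curve_frame(pts, t=t, first_deriv=d1, second_deriv=d2)
        assert np.max(np.abs(curve.curvature - math.sin(mu) ** 2)) < 1e-12

    def test_straight_line_flags_frame_undefined(self):
        t = np.linspace(0, 1, 50)
        pts = np.column_stack([0.3 + 0.2 * t, 0.1 * t, t])
        curve = fs.curve_frame(pts, t=t)
        assert np.all(curve.curvature < 1e-9)
        assert not curve.frame_defined.any()

    def test_spline_estimated_frame_close_to_analytic(self):
        curve = circle_curve(1.0, n=2001)
        est = fs.curve_frame(curve.points)
        assert np.max(np.abs(est.curvature[5:-5] - 1.0)) < 1e-5

    def test_frame_orthonormality(self, generic_solution):
        fib = generic_solution.solution.fiber_curve()
        assert np.allclose(np.linalg.norm(fib.tangent, axis=1), 1.0, atol=1e-12)
        ok = fib.frame_defined
        assert np.allclose(
            np.linalg.norm(fib.principal_normal[ok], axis=1), 1.0, atol=1e-12
        )
        dots = np.sum(fib.tangent[ok] * fib.principal_normal[ok], axis=1)
        assert np.max(np.abs(dots)) < 1e-10


class TestColinearity:
    def test_great_circle_is_geodesic(self, fixtures):
        p = fixtures["sphere"]["profile"]
        z = np.linspace(-0.6, 0.6, 201)
        g = p(z)
        pts = np.column_stack([g, np.zeros_like(z), z])  # meridian great circle
        d1 = np.column_stack([p(z, 1), np.zeros_like(z), np.ones_like(z)])
        d2 = np.column_stack([p(z, 2), np.zeros_like(z), np.zeros_like(z)])
        curve = fs.curve_frame(pts, t=z, first_deriv=d1, second_deriv=d2)
        assert np.max(fs.colinearity_residual(curve, p)) < 1e-10

    def test_meridian_of_any_surface_is_geodesic(self, fixtures):
        p = fixtures["catenoid"]["profile"]
        z = np.linspace(-0.5, 0.5, 101)
        pts = np.column_stack([p(z), np.zeros_like(z), z])
        d1 = np.column_stack([p(z, 1), np.zeros_like(z), np.ones_like(z)])
        d2 = np.column_stack([p(z, 2), np.zeros_like(z), np.zeros_like(z)])
        curve = fs.curve_frame(pts, t=z, first_deriv=d1, second_deriv=d2)
        assert np.max(fs.colinearity_residual(curve, p)) < 1e-10

    def test_latitude_circle_is_not_geodesic(self, fixtures):
        # non-equatorial parallel on the sphere: |e_p x e_n| = |z|/rho
        p = fixtures["sphere"]["profile"]
        z0 = 0.5
        r = float(p(z0))
        t = np.linspace(0, 2 * math.pi, 181)
        pts = np.column_stack([r * np.cos(t), r * np.sin(t), z0 * np.ones_like(t)])
        d1 = np.column_stack([-r * np.sin(t), r * np.cos(t), np.zeros_like(t)])
        d2 = np.column_stack([-r * np.cos(t), -r * np.sin(t), np.zeros_like(t)])
        curve = fs.curve_frame(pts, t=t, first_deriv=d1, second_deriv=d2)
        res = fs.colinearity_residual(curve, p)
        assert np.allclose(res, z0 / RHO, atol=1e-9)
        assert np.min(res) > 0.1

    def test_off_surface_curve_rejected(self, fixtures):
        p = fixtures["sphere"]["profile"]
        curve = circle_curve(0.5)
        with pytest.raises(DomainError):
            fs.colinearity_residual(curve, p)


class TestMeanCurvature:
    def test_cylinder(self):
        z = np.linspace(-0.5, 0.5, 11)
        assert np.allclose(fs.mean_curvature(cylinder_profile(), z), 0.5, atol=1e-12)

    def test_sphere_constant(self, fixtures):
        z = np.linspace(-0.6, 0.6, 101)
        H = fs.mean_curvature(fixtures["sphere"]["profile"], z)
        assert np.max(np.abs(H - 1.0 / RHO)) < 1e-8

    def test_catenoid_minimal(self, fixtures):
        z = np.linspace(-0.62, 0.62, 101)
        H = fs.mean_curvature(fixtures["catenoid"]["profile"], z)
        assert np.max(np.abs(H)) < 1e-8


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    theta=st.floats(0, 2 * math.pi),
    z=st.floats(-0.6, 0.6),
)
def test_normal_unit_and_orthogonal_everywhere(theta, z):
    """Surface normal has unit length and kills both coordinate tangents."""
    p = fs.sphere_segment(R, L)[0]
    n = fs.surface_normal(theta, z, p)
    assert abs(np.linalg.norm(n) - 1.0) < 1e-12
    frame = fs.surface_frame(theta, z, p)
    assert abs(float(np.sum(n * frame.meridian_dir))) < 1e-10
    assert abs(float(np.sum(n * frame.circumferential_dir))) < 1e-10
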