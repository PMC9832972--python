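"""Governing ODE systems: fixed points, oracles, conservation laws, symmetry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fibersurf as fs
from fibersurf.equilibrium import (
    EquilibriumParams,
    IntegrationFailure,
    MeridianLimit,
    integrate_fiber_cartesian,
    integrate_half_profile,
    rhs_cylindrical,
)
from fibersurf.geometry import DomainError, colinearity_residual

from conftest import HALF, L, R, RHO


class TestIntegrationConstant:
    @pytest.mark.parametrize(
        "g0,mu0,expected",
        [
            (1.0, 89.999999, 1.0),  # sin -> 1 limit
            (0.5, 30.0, 16.0),
            (RHO, 58.0, 1.0 / (RHO**2 * math.sin(math.radians(58)) ** 2)),
        ],
    )
    def test_values(self, g0, mu0, expected):
        assert fs.K_from_boundary(g0, mu0) == pytest.approx(expected, rel=1e-9)

    def test_single_sphere_point_K_g0_squared(self):
        # at the sphere landmark K g0^2 = 1/sin^2(58 deg) ~ 1.390
        K = fs.K_from_boundary(RHO, 58.0)
        assert K * RHO**2 == pytest.approx(1.0 / math.sin(math.radians(58)) ** 2, rel=1e-12)
        assert K * RHO**2 == pytest.approx(1.390, abs=5e-4)

    def test_meridian_limit_and_domain(self):
        with pytest.raises(MeridianLimit):
            fs.K_from_boundary(1.0, 0.0)
        with pytest.raises(DomainError):
            fs.K_from_boundary(1.0, 90.0)


class TestRHS:
    def test_cylinder_fixed_point(self):
        # g=1, kappa_T = sin^2(mu0): 1 - K kappa_T g^3 = 0 so g'' = 0
        mu0 = 20.0
        p = EquilibriumParams(g0=1.0, mu0=mu0, kappa_T=math.sin(math.radians(mu0)) ** 2)
        gpp, thp = rhs_cylindrical((1.0, 0.0, 0.0), p)
        assert abs(gpp) < 1e-14
        assert thp == pytest.approx(math.tan(math.radians(mu0)), rel=1e-12)

    @pytest.mark.parametrize("mu0", [15.0, 35.0, 60.0])
    def test_neck_winding_rate(self, mu0):
        # theta'(0) = tan(mu0)/g0 for every solution family
        g0 = 0.7
        p = EquilibriumParams(g0=g0, mu0=mu0, kappa_T=-0.3)
        _, thp = rhs_cylindrical((g0, 0.0, 0.0), p)
        assert thp == pytest.approx(math.tan(math.radians(mu0)) / g0, rel=1e-12)

    def test_hyperboloid_zero_curvature_residual(self):
        # closed form g^2 = g0^2 + m z^2 with ruling angle arctan(sqrt(m))
        g0 = 0.8
        m = (R**2 - g0**2) / HALF**2
        mu0 = math.degrees(math.atan(math.sqrt(m)))
        p = EquilibriumParams(g0=g0, mu0=mu0, kappa_T=0.0)
        for z in np.linspace(0.01, 0.6, 25):
            g = math.sqrt(g0**2 + m * z * z)
            gp = m * z / g
            gpp_exact = m * g0**2 / g**3
            gpp, _ = rhs_cylindrical((g, gp, 0.0), p)
            assert abs(gpp - gpp_exact) < 1e-9

    def test_singular_set_raises(self):
        p = EquilibriumParams(g0=1.0, mu0=30.0, kappa_T=0.0)
        with pytest.raises(DomainError):
            rhs_cylindrical((0.4, 0.0, 0.0), p)  # K g^2 < 1


class TestHalfProfile:
    def test_sphere_reaches_boundary(self):
        p = EquilibriumParams(g0=RHO, mu0=30.0, kappa_T=1.0 / RHO)
        sol = integrate_half_profile(p)
        assert sol.boundary_radius == pytest.approx(1.0, abs=1e-6)
        assert sol.H_neck == pytest.approx(1.0 / RHO, abs=1e-10)

    @pytest.mark.parametrize("g0", [0.4, 0.6, 0.8])
    def test_zero_curvature_limit_is_hyperboloid(self, g0):
        m = (R**2 - g0**2) / HALF**2
        mu0 = math.degrees(math.atan(math.sqrt(m)))
        p = EquilibriumParams(g0=g0, mu0=mu0, kappa_T=0.0)
        sol = integrate_half_profile(p)
        z = sol.z
        assert np.max(np.abs(sol.g - np.sqrt(g0**2 + m * z**2))) < 1e-8

    def test_cylinder_everywhere(self):
        mu0 = 20.0
        p = EquilibriumParams(g0=1.0, mu0=mu0, kappa_T=math.sin(math.radians(mu0)) ** 2)
        sol = integrate_half_profile(p)
        assert np.max(np.abs(sol.g - 1.0)) < 1e-10

    def test_symmetry_of_mirrored_output(self, generic_solution):
        sol = generic_solution.solution
        assert np.allclose(sol.g, sol.g[::-1], atol=0)
        assert np.allclose(sol.theta, -sol.theta[::-1], atol=0)

    def test_mirroring_matches_direct_integration(self):
        # integrating backward from z=0 must agree with the mirrored arrays
        from scipy.integrate import solve_ivp

        p = EquilibriumParams(g0=0.7, mu0=40.0, kappa_T=-0.4)
        sol = integrate_half_profile(p)
        K = p.K

        def rhs(z, y):
            g, gp, th = y
            u = 1 + gp * gp
            v = K * g * g - 1
            return [gp, u / (g * v) * (1 - K * p.kappa_T * g**3 * math.sqrt(u)),
                    math.sqrt(u / v) / g]

        neg = sol.z[sol.z <= 0][::-1]
        back = solve_ivp(rhs, (0, -HALF), [p.g0, 0, 0], t_eval=neg,
                         rtol=1e-12, atol=1e-14, method="DOP853")
        assert np.max(np.abs(back.y[0] - sol.profile(neg))) < 1e-8
        assert np.max(np.abs(back.y[2] - np.interp(neg, sol.z, sol.theta))) < 1e-8

    def test_clairaut_alpha_matches_geometric_angle(self, generic_solution):
        sol = generic_solution.solution
        fib = sol.fiber_curve()
        x, y, z = fib.points.T
        theta = np.arctan2(y, x)
        frame = fs.surface_frame(theta, z, sol.profile)
        sin_alpha_geom = np.sum(fib.tangent * frame.circumferential_dir, axis=1)
        assert np.max(np.abs(np.sin(sol.alpha) - sin_alpha_geom)) < 1e-8

    def test_integration_failure_reported_with_mode_and_position(self):
        # strong inward curvature drives g onto the singular set K g^2 = 1
        p = EquilibriumParams(g0=0.05, mu0=35.0, kappa_T=20.0)
        with pytest.raises(IntegrationFailure) as err:
            integrate_half_profile(p)
        assert err.value.z_fail < HALF
        assert err.value.mode in {"singular", "pinch", "blowup"}

    def test_meridian_pinch_off(self):
        # mu0 = 0 with a tight arc: the meridian closes onto the axis,
        # turning vertical (|g'| -> inf) as it reaches it
        p = EquilibriumParams(g0=0.05, mu0=0.0, kappa_T=20.0)
        with pytest.raises(IntegrationFailure) as err:
            integrate_half_profile(p)
        assert err.value.mode in {"pinch", "blowup"}
        assert err.value.z_fail == pytest.approx(0.05, abs=0.01)
        assert err.value.g_fail < 0.01


class TestCartesianOracle:
    def test_zero_curvature_initial_tangent_gives_straight_line(self):
        p = EquilibriumParams(g0=0.8, mu0=43.83086067211427, kappa_T=0.0)
        curve = integrate_fiber_cartesian(p)
        # zero acceleration: the fiber is a straight ruling of the hyperboloid
        chords = curve.points[-1] - curve.points[0]
        t = (curve.param - curve.param[0]) / (curve.param[-1] - curve.param[0])
        line = curve.points[0] + t[:, None] * chords
        assert np.max(np.linalg.norm(curve.points - line, axis=1)) < 1e-9
        assert np.all(curve.curvature < 1e-9)

    def test_sphere_fiber_stays_on_sphere(self):
        p = EquilibriumParams(g0=RHO, mu0=30.0, kappa_T=1.0 / RHO)
        curve = integrate_fiber_cartesian(p)
        radii = np.linalg.norm(curve.points, axis=1)
        assert np.max(np.abs(radii - RHO)) < 1e-8

    def test_constant_curvature_along_fiber(self):
        p = EquilibriumParams(g0=0.65, mu0=38.0, kappa_T=-0.45)
        curve = integrate_fiber_cartesian(p)
        assert np.max(np.abs(curve.curvature - 0.45)) < 1e-6


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    g0=st.floats(0.5, 1.3),
    mu0=st.floats(15.0, 60.0),
    kappa_T=st.floats(-1.0, 1.0),
)
def test_cylindrical_and_cartesian_formulations_agree(g0, mu0, kappa_T):
    """Dual-route check: both ODE systems trace the same 3-D fiber to 1e-6."""
    p = EquilibriumParams(g0=g0, mu0=mu0, kappa_T=kappa_T)
    try:
        sol = integrate_half_profile(p)
    except IntegrationFailure:
        return  # parameter set leaves the solvable region: nothing to compare
    half_idx = sol.z >= 0
    cart = integrate_fiber_cartesian(p, z_eval=sol.z[half_idx])
    fib = sol.fiber_curve()
    dist = np.linalg.norm(fib.points[half_idx] - cart.points, axis=1)
    assert np.max(dist) < 1e-6


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    g0=st.floats(0.45, 1.25),
    mu0=st.floats(10.0, 65.0),
    kappa_T=st.floats(-1.5, 1.2),
)
def test_conservation_laws_along_every_solution(g0, mu0, kappa_T):
    """Clairaut first integral and geodesic colinearity hold to 1e-8."""
    p = EquilibriumParams(g0=g0, mu0=mu0, kappa_T=kappa_T)
    try:
        sol = integrate_half_profile(p)
    except IntegrationFailure:
        return
    assert np.max(np.abs(sol.clairaut_residual())) < 1e-8
    fib = sol.fiber_curve()
    assert np.max(colinearity_residual(fib, sol.profile)) < 1e-8
    assert np.max(np.abs(fib.curvature - abs(kappa_T))) < 1e-6


class TestFiberFamily:
    def test_single_fiber_is_base(self, generic_solution):
        fam = fs.fiber_family(generic_solution.solution, 1)
        assert np.allclose(fam[0].points, generic_solution.solution.fiber_curve().points)

    def test_family_members_congruent_under_rotation(self, sphere_solution):
        fam = fs.fiber_family(sphere_solution.solution, 4)
        base = fam[0]
        for k, member in enumerate(fam):
            ang = 2 * math.pi * k / 4
            rot = np.array(
                [[math.cos(ang), -math.sin(ang), 0],
                 [math.sin(ang), math.cos(ang), 0],
                 [0, 0, 1]]
            )
            assert np.max(np.abs(member.points - base.points @ rot.T)) < 1e-12

    def test_every_member_is_geodesic(self, generic_solution):
        sol = generic_solution.solution
        for member in fs.fiber_family(sol, 5):
            assert np.max(colinearity_residual(member, sol.profile)) < 1e-8
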