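"""Closed-form and limit-case surfaces: oracles for the fiber-equilibrium ODEs.

Cylinder, one-sheet hyperboloid, spherical segments (single and stacked),
torus segments, catenoid, and the constant-mean-curvature (Delaunay)
boundary-value family spanning two coaxial circles of radius R at
z = +-L/2.  Each closed form substitutes exactly into the governing
equations with its known (kappa_T, mu0), which makes this module the central
oracle suite for the numerical solvers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .geometry import DomainError, ProfileCurve, mean_curvature

__all__ = [
    "DelaunaySolution",
    "hyperboloid",
    "sphere_segment",
    "stacked_spheres",
    "torus_segment",
    "catenoid_neck",
    "catenoid_profile",
    "delaunay_solve",
]


# --------------------------------------------------------------------------- #
# ruled / spherical / toroidal closed forms
# --------------------------------------------------------------------------- #


def hyperboloid(g0: float, R: float = 1.0, L: float = 1.25, n: int = 801):
    """One-sheet hyperboloid through the boundary circles: g^2 = g0^2 + m z^2.

    The straight rulings are the zero-curvature fibers; the ruling crosses
    the waist at angle ``mu0 = arctan(sqrt(m))`` from the meridian, with
    ``m = (R^2 - g0^2) / (L/2)^2``.

    Returns ``(profile, mu0_degrees)``.
    """
    if not 0 < g0 < R:
        raise DomainError("hyperboloid requires 0 < g0 < R")
    half = L / 2.0
    m = (R * R - g0 * g0) / (half * half)

    def g(z):
        return np.sqrt(g0 * g0 + m * z * z)

    def dg(z):
        return m * z / g(z)

    def d2g(z):
        return m * g0 * g0 / g(z) ** 3

    profile = ProfileCurve.from_callable(g, -half, half, dg, d2g, n=n)
    return profile, math.degrees(math.atan(math.sqrt(m)))


def hyperboloid_neck(mu0: float, R: float = 1.0, L: float = 1.25) -> float:
    """Neck radius of the hyperboloid whose rulings cross the waist at mu0 deg.

    ``g0 = sqrt(R^2 - tan^2(mu0) (L/2)^2)`` — the zero-pressure neck of the
    fiber model at fibril angle mu0.
    """
    half = L / 2.0
    arg = R * R - math.tan(math.radians(mu0)) ** 2 * half * half
    if arg <= 0:
        raise DomainError("no hyperboloid through the boundary at this angle")
    return math.sqrt(arg)


def sphere_segment(R: float = 1.0, L: float = 1.25, n: int = 801):
    """The single spherical segment through both boundary circles.

    Sphere radius ``rho = sqrt(R^2 + (L/2)^2)``; its great-circle fibers have
    normal curvature ``kappa_T = 1/rho``.  A great circle crossing the
    equator at angle mu0 reaches height ``rho cos(mu0)``; it stays within
    |z| <= L/2 only for ``mu0 <= arccos((L/2)/rho)`` — the landmark maximal
    fibril angle (58 degrees for R=1, L=1.25).

    Returns ``(profile, rho, kappa_T, mu_max_degrees)``.
    """
    if R <= 0 or L <= 0:
        raise DomainError("R and L must be positive")
    half = L / 2.0
    rho = math.hypot(R, half)

    def g(z):
        return np.sqrt(rho * rho - z * z)

    def dg(z):
        return -z / g(z)

    def d2g(z):
        return -rho * rho / g(z) ** 3

    profile = ProfileCurve.from_callable(g, -half, half, dg, d2g, n=n)
    mu_max = math.degrees(math.acos(half / rho))
    return profile, rho, 1.0 / rho, mu_max


def stacked_spheres(n_segments: int, R: float = 1.0, L: float = 1.25, g0: float | None = None, n: int = 801):
    """Stacks of congruent spherical segments spanning the boundary circles.

    These are the limit cases toward which solutions tend at positive
    kappa_T; the meridian is continuous but not differentiable at the joints.

    * ``n_segments=2``: two congruent segments meeting at z = 0.  The family
      is parameterized by the joint (neck) radius ``g0``; each sphere passes
      through ``(g0, 0)`` and ``(R, L/2)``, giving
      ``z_c = ((L/2)^2 + R^2 - g0^2) / L`` and ``rho = hypot(g0, z_c)``.
    * ``n_segments=3``: central segment symmetric about z = 0 (so its sphere
      is centered on the equatorial plane and ``g0 = rho``), outer segments
      congruent to it; the joint height follows from the outer boundary,
      leaving the one-parameter family ``kappa_T = 1/g0`` for ``g0 >= R``.

    Returns ``(profile, g0, kappa_T)``.
    """
    half = L / 2.0
    if n_segments == 1:
        profile, rho, kT, _ = sphere_segment(R, L, n=n)
        return profile, rho, kT
    if n_segments == 2:
        if g0 is None:
            g0 = 0.75 * R
        zc = (half * half + R * R - g0 * g0) / (2.0 * half)
        rho = math.hypot(g0, zc)

        def g(z):
            za = np.abs(z)
            return np.sqrt(np.maximum(rho * rho - (za - zc) ** 2, 1e-300))

        zs = np.linspace(-half, half, n if n % 2 == 1 else n + 1)
        gz = g(zs)
        gp = np.gradient(gz, zs)  # kinked at the joint; nodal values only
        gpp = np.gradient(gp, zs)
        return ProfileCurve(zs, gz, gp, gpp), float(g0), 1.0 / rho
    if n_segments == 3:
        if g0 is None:
            g0 = 1.05 * R
        rho = g0
        if rho < R:
            raise DomainError("3-stack requires g0 >= R")
        j = 0.5 * (half - math.sqrt(rho * rho - R * R))
        if j <= 0:
            raise DomainError("central segment vanishes: g0 too large for this L")

        def g(z):
            za = np.abs(np.asarray(z, float))
            inner = np.sqrt(np.maximum(rho * rho - za**2, 1e-300))
            outer = np.sqrt(np.maximum(rho * rho - (za - 2 * j) ** 2, 1e-300))
            return np.where(za <= j, inner, outer)

        zs = np.linspace(-half, half, n if n % 2 == 1 else n + 1)
        gz = g(zs)
        gp = np.gradient(gz, zs)
        gpp = np.gradient(gp, zs)
        return ProfileCurve(zs, gz, gp, gpp), float(g0), 1.0 / rho
    raise DomainError("stacked_spheres supports n_segments in {1, 2, 3}")


def torus_segment(g0: float, R: float = 1.0, L: float = 1.25, n: int = 801):
    """Barrel-shaped torus segment: the mu0 = 0 (meridian-fiber) limit.

    With fibers along meridians, constant normal curvature makes the
    meridian a circular arc.  The arc passes through ``(R, +-L/2)`` with apex
    ``(g0, 0)``; for the upper branch ``g0 > R`` its radius is
    ``r_a = (a^2 + (L/2)^2) / (2a)`` with ``a = g0 - R``, and
    ``kappa_T = +1/r_a`` (the fibers bend toward the interior).

    Returns ``(profile, kappa_T)``.
    """
    if g0 <= R:
        raise DomainError("torus segment (upper branch) requires g0 > R")
    half = L / 2.0
    a = g0 - R
    r_a = (a * a + half * half) / (2.0 * a)
    gc = g0 - r_a  # arc center on the g-axis

    if r_a < half:
        raise DomainError("no circular arc through the boundary circles")

    def g(z):
        return gc + np.sqrt(r_a * r_a - z * z)

    def dg(z):
        return -z / np.sqrt(r_a * r_a - z * z)

    def d2g(z):
        return -r_a * r_a / (r_a * r_a - z * z) ** 1.5

    profile = ProfileCurve.from_callable(g, -half, half, dg, d2g, n=n)
    return profile, 1.0 / r_a


# --------------------------------------------------------------------------- #
# catenoid and the Delaunay constant-mean-curvature family
# --------------------------------------------------------------------------- #


def catenoid_neck(R: float = 1.0, L: float = 1.25):
    """Neck radii c of catenoids through the boundary: c cosh((L/2)/c) = R.

    The catenary equation has two roots; the larger is the stable branch.
    Returns ``(c_primary, (c_small, c_large))``.  Raises if L is too large
    relative to R for any catenoid to span the gap.
    """
    half = L / 2.0

    # substitute t = (L/2)/c to keep cosh in range for the small-c branch
    def h(t):
        return (half / t) * math.cosh(t) - R

    # h has a single minimum at cosh(t) = t sinh(t); roots bracket it
    t_star = brentq(lambda t: math.cosh(t) - t * math.sinh(t), 1e-8, 50.0)
    if h(t_star) > 0:
        raise DomainError("no catenoid spans this boundary (L too large)")
    t_large = brentq(h, t_star, 700.0, xtol=1e-15)
    t_small = brentq(h, 1e-12, t_star, xtol=1e-15)
    c_small, c_large = half / t_large, half / t_small
    return c_large, (c_small, c_large)


def catenoid_profile(c: float, L: float = 1.25, n: int = 801) -> ProfileCurve:
    """Catenoid meridian ``g = c cosh(z/c)`` on |z| <= L/2."""
    half = L / 2.0
    return ProfileCurve.from_callable(
        lambda z: c * np.cosh(z / c),
        -half,
        half,
        lambda z: np.sinh(z / c),
        lambda z: np.cosh(z / c) / c,
        n=n,
    )


@dataclass(frozen=True)
class DelaunaySolution:
    """A constant-mean-curvature meridian through the boundary circles.

    ``H`` is the constant mean curvature and ``B = g0 - H g0^2`` the first
    integral ``g / sqrt(1 + g'^2) - H g^2 = B``.  ``family`` classifies the
    Delaunay type.
    """

    profile: ProfileCurve
    H: float
    B: float
    family: str
    g0: float

    def first_integral_residual(self) -> np.ndarray:
        g = self.profile.g
        gp = self.profile.g_prime
        return g / np.sqrt(1.0 + gp * gp) - self.H * g * g - self.B


def _classify(H: float, g0: float, R: float, L: float) -> str:
    if abs(H) < 1e-9:
        return "catenoid"
    rho = math.hypot(R, L / 2.0)
    if abs(H - 1.0 / rho) < 1e-9 and abs(g0 - rho) < 1e-6:
        return "sphere"
    if abs(H - 0.5 / g0) < 1e-9:
        return "cylinder"
    return "unduloid" if H > 0 else "nodoid"


def _delaunay_g_at_boundary(H: float, g0: float, half: float):
    """Integrate the CMC meridian (arc length) from the neck; g at z = half.

    Arc-length state (g, z, phi) with dg/ds = sin(phi), dz/ds = cos(phi),
    dphi/ds = cos(phi)/g - 2H handles vertical tangents (nodoid branches)
    without reparameterization.
    """

    def rhs(s, y):
        g, z, phi = y
        return [math.sin(phi), math.cos(phi), math.cos(phi) / g - 2.0 * H]

    def ev_boundary(s, y):
        return y[1] - half

    ev_boundary.terminal = True
    ev_boundary.direction = 1

    def ev_pinch(s, y):
        return y[0] - 1e-9

    ev_pinch.terminal = True
    ev_pinch.direction = -1

    def ev_backward(s, y):
        return y[1] + 0.25 * half  # meridian folded far back below the neck

    ev_backward.terminal = True
    ev_backward.direction = -1

    s_max = 40.0 * half + 10.0 * g0
    sol = solve_ivp(
        rhs,
        (0.0, s_max),
        [g0, 0.0, 0.0],
        method="DOP853",
        rtol=1e-11,
        atol=1e-13,
        dense_output=True,
        events=[ev_boundary, ev_pinch, ev_backward],
    )
    if sol.t_events[0].size:
        g_b = sol.sol(sol.t_events[0][0])[0]
        return float(g_b), sol
    return None, sol


def delaunay_solve(
    g0: float,
    R: float = 1.0,
    L: float = 1.25,
    H_bracket: tuple[float, float] = (-8.0, 8.0),
    n_scan: int = 161,
    n: int = 801,
) -> DelaunaySolution:
    """Constant-mean-curvature surface with neck g0 meeting g(L/2) = R.

    Shoots on H using the arc-length meridian equations (robust through
    vertical tangents); the root with smallest |H| is returned.  The profile
    is resampled as a z-graph, with derivatives recovered from the first
    integral ``g / sqrt(1+g'^2) - H g^2 = B`` (``B = g0 - H g0^2``) rather
    than finite differences.
    """
    if g0 <= 0:
        raise DomainError("g0 must be positive")
    half = L / 2.0

    def resid(H):
        g_b, _ = _delaunay_g_at_boundary(H, g0, half)
        if g_b is None:
            return -R - 1.0  # pinched or folded away: undershoot
        return g_b - R

    Hs = np.linspace(H_bracket[0], H_bracket[1], n_scan)
    vals = np.array([resid(H) for H in Hs])
    roots = []
    for i in range(n_scan - 1):
        if vals[i] == 0.0:
            roots.append(float(Hs[i]))
        elif np.sign(vals[i]) * np.sign(vals[i + 1]) < 0:
            try:
                roots.append(float(brentq(resid, Hs[i], Hs[i + 1], xtol=1e-13)))
            except ValueError:
                continue
    roots = [r for r in roots if abs(resid(r)) < 1e-8]
    if not roots:
        raise DomainError(f"no constant-H surface with neck {g0} meets the boundary")
    H = min(roots, key=abs)
    B = g0 - H * g0 * g0

    _, sol = _delaunay_g_at_boundary(H, g0, half)
    s_end = sol.t_events[0][0]
    s_dense = np.linspace(0.0, s_end, 4 * n)
    g_s, z_s, phi_s = sol.sol(s_dense)
    # z must be monotone to express the meridian as a graph g(z)
    if np.any(np.diff(z_s) <= 0):
        keep = np.concatenate([[True], np.diff(z_s) > 1e-14])
        g_s, z_s, phi_s = g_s[keep], z_s[keep], phi_s[keep]
    z_grid = np.linspace(0.0, half, (n + 1) // 2)
    from scipy.interpolate import CubicHermiteSpline

    with np.errstate(divide="ignore"):
        dg_dz = np.tan(np.clip(phi_s, -np.pi / 2 + 1e-8, np.pi / 2 - 1e-8))
    g_half = CubicHermiteSpline(z_s, g_s, dg_dz)(z_grid)
    g_half[0] = g0
    # derivatives from the first integral: g' = +-sqrt((g/(B + H g^2))^2 - 1),
    # signed by the local monotonicity of the resampled meridian
    q = g_half / (B + H * g_half * g_half)
    sgn = np.sign(np.gradient(g_half, z_grid))
    gp_half = sgn * np.sqrt(np.maximum(q * q - 1.0, 0.0))
    gp_half[0] = 0.0
    gpp_half = (1.0 + gp_half**2) / g_half - 2.0 * H * (1.0 + gp_half**2) ** 1.5
    z_full = np.concatenate([-z_grid[:0:-1], z_grid])
    g_full = np.concatenate([g_half[:0:-1], g_half])
    gp_full = np.concatenate([-gp_half[:0:-1], gp_half])
    gpp_full = np.concatenate([gpp_half[:0:-1], gpp_half])
    profile = ProfileCurve(z_full, g_full, gp_full, gpp_full)
    return DelaunaySolution(
        profile=profile, H=H, B=B, family=_classify(H, g0, R, L), g0=g0
    )
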