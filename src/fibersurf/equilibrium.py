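"""Governing ODEs for fiber-stabilized surfaces of revolution.

A contractile fiber bound to the surface of an inviscid body must, in
mechanical equilibrium, follow a geodesic of the surface (its principal
normal colinear with the surface normal) with constant normal curvature
``kappa_T`` so that the pressure it supports is uniform.  For a surface of
revolution with meridian ``g(z)`` and fiber winding ``theta(z)`` this yields
the cylindrical system

    g''     = (1 + g'^2) / (g (K g^2 - 1)) * (1 - K kappa_T g^3 sqrt(1 + g'^2)),
    theta'  = (1/g) sqrt((1 + g'^2) / (K g^2 - 1)),

where ``K = 1/(g0^2 sin^2 mu0)`` is fixed by the neck radius ``g0`` and the
fibril angle ``mu0`` between fiber and meridian at the neck.  ``theta'`` is
the classical geodesic equation on a surface of revolution; the first
equation enforces constant normal curvature.  Clairaut's relation
``g sin(alpha) = g0 sin(mu0)`` is an exact first integral.

An equivalent second-order Cartesian system in ``x(z), y(z)`` is implemented
independently and used as a cross-validation oracle.  Both systems are
integrated with the printed right-hand sides; the package-wide signed
curvature convention (spheres and barrels at ``kappa_T > 0``) requires the
Cartesian form to be driven with ``-kappa_T``, which is applied internally.

The meridian-fiber limit ``mu0 = 0`` (``K -> inf``) degenerates to
``theta' = 0`` and ``g'' = -kappa_T (1 + g'^2)^{3/2}``: the fiber is a planar
meridian arc of constant curvature (a torus segment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .geometry import DomainError, ProfileCurve, SpaceCurve, _frenet

__all__ = [
    "EquilibriumParams",
    "FiberSolution",
    "IntegrationFailure",
    "MeridianLimit",
    "K_from_boundary",
    "rhs_cylindrical",
    "integrate_half_profile",
    "integrate_fiber_cartesian",
    "fiber_family",
]

#: printed Cartesian system's kappa relative to the package-wide convention
_CARTESIAN_SIGN = -1.0

_GP_CAP = 1.0e4  # |g'| beyond this the meridian is effectively vertical
_SINGULAR_MARGIN = 1e-12


class MeridianLimit(DomainError):
    """mu0 = 0: fibers are meridians; K is infinite and handled analytically."""


class IntegrationFailure(RuntimeError):
    """Integration stopped before z = L/2.

    Attributes
    ----------
    z_fail : float
        Axial coordinate where integration stopped.
    mode : str
        ``"singular"`` (K g^2 -> 1: fiber tangent to a parallel circle),
        ``"pinch"`` (g -> 0) or ``"blowup"`` (|g'| -> inf, vertical meridian).
    g_fail, g_prime_fail : float
        State at the failure point.
    """

    def __init__(self, z_fail: float, mode: str, g_fail: float, g_prime_fail: float):
        super().__init__(f"integration failed at z={z_fail:.6g} ({mode})")
        self.z_fail = z_fail
        self.mode = mode
        self.g_fail = g_fail
        self.g_prime_fail = g_prime_fail


def K_from_boundary(g0: float, mu0: float) -> float:
    """Integration constant ``K = 1/(g0^2 sin^2 mu0)``; ``mu0`` in degrees."""
    if g0 <= 0:
        raise DomainError("g0 must be positive")
    if mu0 == 0:
        raise MeridianLimit(
            "mu0 = 0 gives infinite K (meridian fibers); use the torus limit"
        )
    if not 0 < mu0 < 90:
        raise DomainError("mu0 must lie in [0, 90) degrees")
    s = math.sin(math.radians(mu0))
    return 1.0 / (g0 * s) ** 2


@dataclass(frozen=True)
class EquilibriumParams:
    """Parameters of one fiber-equilibrium boundary-value problem.

    Angles are in degrees on the interface (stored as given); lengths in
    units of the boundary radius.  ``chirality=+1`` winds right-handed
    (``theta`` increasing with z), ``-1`` gives the mirror solution.
    """

    g0: float
    mu0: float
    kappa_T: float
    L: float = 1.25
    R: float = 1.0
    theta0: float = 0.0
    chirality: int = 1

    def __post_init__(self):
        if self.g0 <= 0:
            raise DomainError("g0 must be positive")
        if not 0 <= self.mu0 < 90:
            raise DomainError("mu0 must lie in [0, 90) degrees")
        if self.L <= 0 or self.R <= 0:
            raise DomainError("L and R must be positive")
        if self.chirality not in (-1, 1):
            raise DomainError("chirality must be +1 or -1")

    @property
    def K(self) -> float:
        """Integration constant; ``inf`` in the meridian-fiber limit."""
        if self.mu0 == 0:
            return math.inf
        return K_from_boundary(self.g0, self.mu0)

    @property
    def clairaut_constant(self) -> float:
        """``g0 sin(mu0) = 1/sqrt(K)`` — conserved value of ``g sin(alpha)``."""
        return self.g0 * math.sin(math.radians(self.mu0))


def rhs_cylindrical(state, params: EquilibriumParams):
    """Right-hand side ``(g'', theta')`` of the cylindrical system.

    ``state`` is ``(g, g_prime, theta)``.  Raises on the singular set
    ``K g^2 <= 1`` (fiber tangent to a parallel circle).
    """
    g, gp, _ = state
    K = params.K
    u = 1.0 + gp * gp
    if math.isinf(K):  # meridian fibers: planar arc of constant curvature
        return -params.kappa_T * u ** 1.5, 0.0
    v = K * g * g - 1.0
    if v <= 0:
        raise DomainError(f"singular set K g^2 <= 1 reached (g={g:.6g})")
    gpp = u / (g * v) * (1.0 - K * params.kappa_T * g**3 * math.sqrt(u))
    thp = math.sqrt(u / v) / g
    return gpp, thp


def _theta_double_prime(g, gp, gpp, thp, K):
    """d(theta')/dz from the closed form of theta' (zero in the mu0=0 limit)."""
    if math.isinf(K):
        return np.zeros_like(g)
    u = 1.0 + gp * gp
    v = K * g * g - 1.0
    return thp * gp * (gpp / u - K * g / v - 1.0 / g)


def _integrate_raw(params: EquilibriumParams, rtol: float, atol: float):
    """Integrate the half interval [0, L/2]; return the solve_ivp result.

    Terminal events mark the failure modes; the caller decides whether a
    stopped run is an error or data for existence mapping.
    """
    K = params.K
    kT = params.kappa_T
    half = params.L / 2.0

    def rhs(z, y):
        # clamp wild trial-stage states: terminal events stop the
        # integration long before these caps matter for accepted steps
        g = min(max(float(y[0]), 1e-12), 1e6)
        gp = min(max(float(y[1]), -1e6), 1e6)
        u = 1.0 + gp * gp
        if math.isinf(K):
            return [gp, -kT * u**1.5, 0.0]
        v = K * g * g - 1.0
        if v <= _SINGULAR_MARGIN:
            v = _SINGULAR_MARGIN
        gpp = u / (g * v) * (1.0 - K * kT * g**3 * math.sqrt(u))
        thp = math.sqrt(u / v) / g
        return [gp, gpp, thp]

    events = []

    def ev_pinch(z, y):
        return y[0] - 1e-9

    ev_pinch.terminal = True
    ev_pinch.direction = -1
    events.append(ev_pinch)

    def ev_blowup(z, y):
        return y[1] * y[1] - _GP_CAP**2

    ev_blowup.terminal = True
    ev_blowup.direction = 1
    events.append(ev_blowup)

    if not math.isinf(K):

        def ev_singular(z, y):
            return K * y[0] * y[0] - 1.0 - 1e-10

        ev_singular.terminal = True
        ev_singular.direction = -1
        events.append(ev_singular)

    return solve_ivp(
        rhs,
        (0.0, half),
        [params.g0, 0.0, 0.0],
        method="DOP853",
        rtol=rtol,
        atol=atol,
        dense_output=True,
        events=events,
        max_step=half / 8,
    )


def _failure_from(sol, params: EquilibriumParams) -> IntegrationFailure:
    z_f = sol.t[-1]
    g_f, gp_f = sol.y[0][-1], sol.y[1][-1]
    if sol.t_events[0].size:
        mode = "pinch"
    elif sol.t_events[1].size:
        mode = "blowup"
    else:
        mode = "singular"
    return IntegrationFailure(z_f, mode, g_f, gp_f)


@dataclass(frozen=True)
class FiberSolution:
    """A solved fiber equilibrium on ``z`` in ``[-L/2, L/2]``.

    The profile is mirrored from the half interval using the exact symmetry
    ``g(-z) = g(z)``, ``theta(-z) = -theta(z)`` of the governing equations,
    so the output is symmetric to machine precision.  ``alpha`` is the local
    angle between fiber and meridian (radians), given exactly by Clairaut's
    relation ``sin(alpha) = g0 sin(mu0) / g``.
    """

    params: EquilibriumParams
    profile: ProfileCurve
    theta: np.ndarray
    theta_prime: np.ndarray
    theta_double_prime: np.ndarray
    kappa_T: float
    H_neck: float

    @property
    def z(self) -> np.ndarray:
        return self.profile.z_grid

    @property
    def g(self) -> np.ndarray:
        return self.profile.g

    @property
    def alpha(self) -> np.ndarray:
        arg = self.params.clairaut_constant / self.profile.g
        return np.arcsin(np.clip(arg, -1.0, 1.0))

    @property
    def pressure_sign(self) -> int:
        """Sign of the pressure the fibers induce (Eq. of state p ~ kappa_T)."""
        return int(np.sign(self.kappa_T))

    @property
    def boundary_radius(self) -> float:
        return float(self.profile.g[-1])

    def clairaut_residual(self) -> np.ndarray:
        """``g sin(alpha) - g0 sin(mu0)`` on the grid (zero in exact arithmetic)."""
        return self.profile.g * np.sin(self.alpha) - self.params.clairaut_constant

    def fiber_curve(self, theta_start: float = 0.0, chirality: int | None = None) -> SpaceCurve:
        """Reconstruct the 3-D fiber path with analytic z-derivatives.

        The returned frame is exact up to integration tolerance, so the
        pointwise Frenet curvature can be compared against ``kappa_T`` at
        the 1e-6 level and the colinearity residual at 1e-8.
        """
        sigma = self.params.chirality if chirality is None else chirality
        g = self.profile.g
        gp = self.profile.g_prime
        gpp = self.profile.g_double_prime
        th = sigma * self.theta + theta_start
        thp = sigma * self.theta_prime
        thpp = sigma * self.theta_double_prime
        ct, st = np.cos(th), np.sin(th)
        x = g * ct
        y = g * st
        xp = gp * ct - g * thp * st
        yp = gp * st + g * thp * ct
        xpp = gpp * ct - 2 * gp * thp * st - g * thp**2 * ct - g * thpp * st
        ypp = gpp * st + 2 * gp * thp * ct - g * thp**2 * st + g * thpp * ct
        z = self.z
        pts = np.stack([x, y, z], axis=-1)
        d1 = np.stack([xp, yp, np.ones_like(z)], axis=-1)
        d2 = np.stack([xpp, ypp, np.zeros_like(z)], axis=-1)
        return _frenet(pts, d1, d2, z)


def integrate_half_profile(
    params: EquilibriumParams,
    n_grid: int = 201,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> FiberSolution:
    """Integrate from the neck to z = L/2 and mirror to the full interval.

    Initial conditions ``g(0) = g0``, ``g'(0) = 0``, ``theta(0) = 0``.  The
    outer boundary value ``g(L/2)`` is *not* constrained here; the shooting
    solver adjusts ``kappa_T`` against it.  Raises :class:`IntegrationFailure`
    if the solution hits the singular set, pinches off, or turns vertical
    before reaching z = L/2.
    """
    sol = _integrate_raw(params, rtol, atol)
    half = params.L / 2.0
    if sol.status != 0 or sol.t[-1] < half * (1 - 1e-12):
        raise _failure_from(sol, params)

    z_half = np.linspace(0.0, half, n_grid)
    g_h, gp_h, th_h = sol.sol(z_half)
    g_h[0], gp_h[0], th_h[0] = params.g0, 0.0, 0.0

    K = params.K
    kT = params.kappa_T
    u = 1.0 + gp_h**2
    if math.isinf(K):
        gpp_h = -kT * u**1.5
        thp_h = np.zeros_like(g_h)
    else:
        v = K * g_h**2 - 1.0
        gpp_h = u / (g_h * v) * (1.0 - K * kT * g_h**3 * np.sqrt(u))
        thp_h = np.sqrt(u / v) / g_h
    thpp_h = _theta_double_prime(g_h, gp_h, gpp_h, thp_h, K)

    # mirror: g even, theta odd
    z = np.concatenate([-z_half[:0:-1], z_half])
    g = np.concatenate([g_h[:0:-1], g_h])
    gp = np.concatenate([-gp_h[:0:-1], gp_h])
    gpp = np.concatenate([gpp_h[:0:-1], gpp_h])
    th = np.concatenate([-th_h[:0:-1], th_h])
    thp = np.concatenate([thp_h[:0:-1], thp_h])
    thpp = np.concatenate([-thpp_h[:0:-1], thpp_h])

    profile = ProfileCurve(z, g, gp, gpp)
    H_neck = 0.5 * (1.0 / params.g0 - gpp_h[0])
    return FiberSolution(
        params=params,
        profile=profile,
        theta=th,
        theta_prime=thp,
        theta_double_prime=thpp,
        kappa_T=kT,
        H_neck=H_neck,
    )


def integrate_fiber_cartesian(
    params: EquilibriumParams,
    initial=None,
    z_eval=None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> SpaceCurve:
    """Integrate the independent Cartesian second-order system for the fiber.

    ``initial`` is ``(x, x', y, y')`` at z = 0; the default starts on the neck
    circle at ``(g0, 0)`` with tangent at angle ``mu0`` to the z-direction,
    matching the cylindrical initial conditions.  The resulting curve must
    coincide pointwise with :meth:`FiberSolution.fiber_curve` at equal
    ``kappa_T`` — this is the package's dual-route consistency oracle.
    """
    if initial is None:
        thp0 = math.tan(math.radians(params.mu0)) / params.g0 * params.chirality
        initial = (params.g0, 0.0, 0.0, params.g0 * thp0)
    kc = _CARTESIAN_SIGN * params.kappa_T
    half = params.L / 2.0

    def rhs(z, s):
        clip = lambda w: min(max(float(w), -1e6), 1e6)
        x, xp, y, yp = (clip(w) for w in s)
        D2 = x * x * (1 + xp * xp) + 2 * x * y * xp * yp + y * y * (1 + yp * yp)
        D = math.sqrt(max(D2, 1e-300))
        A = 1 + xp * xp + yp * yp
        xpp = kc * (x * (1 + xp * xp) + y * xp * yp) * A / D
        ypp = kc * A * (x * xp * yp + y * (1 + yp * yp)) / D
        return [xp, xpp, yp, ypp]

    def ev_pinch(z, s):
        return s[0] ** 2 + s[2] ** 2 - 1e-18

    ev_pinch.terminal = True
    ev_pinch.direction = -1

    def ev_blowup(z, s):
        return s[1] ** 2 + s[3] ** 2 - _GP_CAP**2

    ev_blowup.terminal = True
    ev_blowup.direction = 1

    sol = solve_ivp(
        rhs,
        (0.0, half),
        list(initial),
        method="DOP853",
        rtol=rtol,
        atol=atol,
        dense_output=True,
        events=[ev_pinch, ev_blowup],
        max_step=half / 8,
    )
    if sol.status != 0:
        mode = "pinch" if sol.t_events[0].size else "blowup"
        x_f, y_f = sol.y[0][-1], sol.y[2][-1]
        raise IntegrationFailure(sol.t[-1], mode, math.hypot(x_f, y_f), math.nan)
    if z_eval is None:
        z_eval = np.linspace(0.0, half, 201)
    z_eval = np.asarray(z_eval, float)
    x, xp, y, yp = sol.sol(z_eval)
    d = np.array([rhs(zi, si) for zi, si in zip(z_eval, np.stack([x, xp, y, yp]).T)])
    pts = np.stack([x, y, z_eval], axis=-1)
    d1 = np.stack([xp, yp, np.ones_like(z_eval)], axis=-1)
    d2 = np.stack([d[:, 1], d[:, 3], np.zeros_like(z_eval)], axis=-1)
    return _frenet(pts, d1, d2, z_eval)


def fiber_family(solution: FiberSolution, n_fibers: int) -> list[SpaceCurve]:
    """The ``n_fibers`` congruent fibers rotated by ``2 pi k / n_fibers``.

    Geodesics on a surface of revolution at fixed Clairaut constant form a
    one-parameter family under rotation; every member is congruent to the
    base fiber.
    """
    if n_fibers < 1:
        raise DomainError("n_fibers must be >= 1")
    return [
        solution.fiber_curve(theta_start=2.0 * math.pi * k / n_fibers)
        for k in range(n_fibers)
    ]
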