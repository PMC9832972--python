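"""Boundary-value shooting: enforce g(L/2) = R on the fiber-equilibrium ODEs.

Following the numerical procedure of the model, the neck data ``(g0, mu0)``
are fixed and the constant fiber curvature ``kappa_T`` is adjusted until the
integrated meridian meets the boundary circle, ``g(L/2) = R``.  The residual
is ``g(L/2) - R`` where integration succeeds; where the integration fails
before z = L/2 (singular set, pinch-off, vertical meridian) a signed
distance-to-failure penalty keeps the residual usable for bracketing, so
brackets spanning failure regions still resolve.

A scan over the kappa_T bracket locates every sign change; all roots are
polished by Brent iteration and reported, the smallest ``|kappa_T|`` flagged
primary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .equilibrium import (
    EquilibriumParams,
    FiberSolution,
    IntegrationFailure,
    _integrate_raw,
    integrate_half_profile,
)
from .geometry import DomainError

__all__ = ["ShootingResult", "solve_kappa", "solve_mu0", "existence_limits"]

_PENALTY_SLOPE = 50.0
_RTOL_SCAN, _ATOL_SCAN = 1e-7, 1e-9
_RTOL_TIGHT, _ATOL_TIGHT = 1e-10, 1e-12
_RESIDUAL_TOL = 1e-8


def _boundary_residual(g0, mu0, kappa, R, L, rtol, atol):
    """Signed boundary residual; penalized when integration stops early."""
    params = EquilibriumParams(g0=g0, mu0=mu0, kappa_T=kappa, L=L, R=R)
    sol = _integrate_raw(params, rtol, atol)
    half = L / 2.0
    if sol.status == 0 and sol.t[-1] >= half * (1 - 1e-12):
        return sol.y[0][-1] - R, True
    z_f, g_f, gp_f = sol.t[-1], sol.y[0][-1], sol.y[1][-1]
    blowup_out = sol.t_events[1].size > 0 and gp_f > 0
    sgn = 1.0 if blowup_out else -1.0
    return (g_f - R) + sgn * (half - z_f) * _PENALTY_SLOPE, False


@dataclass(frozen=True)
class ShootingResult:
    """Outcome of a shooting solve.

    ``status`` is ``"converged"``, ``"no-sign-change"`` (the scan found no
    bracketable root — absence of solutions is data for the existence limits)
    or ``"integration-failed"`` (no scan point integrated to L/2).  When
    converged, ``solution`` is the primary root's :class:`FiberSolution`
    and ``roots`` lists every root found in the bracket.
    """

    status: str
    kappa_T: float = math.nan
    residual: float = math.nan
    bracket: tuple[float, float] = (math.nan, math.nan)
    solution: FiberSolution | None = None
    roots: tuple[float, ...] = field(default_factory=tuple)

    @property
    def converged(self) -> bool:
        return self.status == "converged"


def solve_kappa(
    g0: float,
    mu0: float,
    R: float = 1.0,
    L: float = 1.25,
    bracket: tuple[float, float] = (-20.0, 20.0),
    n_scan: int = 97,
    n_grid: int = 201,
) -> ShootingResult:
    """Find kappa_T such that the meridian meets the boundary, g(L/2) = R.

    Scans ``n_scan`` points of ``bracket`` for sign changes of the boundary
    residual, polishes each bracket by Brent iteration (kappa tolerance
    1e-12), and verifies every candidate by a tight re-integration; roots
    whose final residual exceeds 1e-8 (sign changes caused by penalty jumps)
    are discarded.
    """
    if not 0 <= mu0 < 90:
        raise DomainError("mu0 must lie in [0, 90) degrees")
    if g0 <= 0:
        raise DomainError("g0 must be positive")

    kappas = np.linspace(bracket[0], bracket[1], n_scan)
    res = np.empty(n_scan)
    ok = np.zeros(n_scan, dtype=bool)
    for i, k in enumerate(kappas):
        res[i], ok[i] = _boundary_residual(g0, mu0, k, R, L, _RTOL_SCAN, _ATOL_SCAN)

    if not ok.any():
        return ShootingResult(status="integration-failed", bracket=bracket)

    def f(kappa):
        return _boundary_residual(g0, mu0, kappa, R, L, _RTOL_TIGHT, _ATOL_TIGHT)[0]

    roots: list[float] = []
    for i in range(n_scan - 1):
        if res[i] == 0.0 and ok[i]:
            roots.append(float(kappas[i]))
            continue
        if np.sign(res[i]) * np.sign(res[i + 1]) < 0:
            try:
                root = brentq(f, kappas[i], kappas[i + 1], xtol=1e-12, rtol=8.9e-16)
            except ValueError:
                continue  # coarse/tight sign disagreement at a penalty jump
            r_val, success = _boundary_residual(
                g0, mu0, root, R, L, _RTOL_TIGHT, _ATOL_TIGHT
            )
            if success and abs(r_val) < _RESIDUAL_TOL:
                roots.append(float(root))

    roots = sorted(set(round(r, 12) for r in roots), key=abs)
    if not roots:
        return ShootingResult(status="no-sign-change", bracket=bracket)

    primary = roots[0]
    params = EquilibriumParams(g0=g0, mu0=mu0, kappa_T=primary, L=L, R=R)
    solution = integrate_half_profile(params, n_grid=n_grid, rtol=_RTOL_TIGHT, atol=_ATOL_TIGHT)
    return ShootingResult(
        status="converged",
        kappa_T=primary,
        residual=solution.boundary_radius - R,
        bracket=bracket,
        solution=solution,
        roots=tuple(roots),
    )


def solve_mu0(
    g0: float,
    kappa_T: float,
    R: float = 1.0,
    L: float = 1.25,
    n_scan: int = 91,
    n_grid: int = 201,
) -> ShootingResult:
    """Inverse query: root-find the neck fibril angle mu0 at fixed kappa_T.

    Round-trips with :func:`solve_kappa` to 1e-6.  The reported ``kappa_T``
    field carries the requested curvature; the found angle is in
    ``solution.params.mu0`` (degrees).
    """
    if g0 <= 0:
        raise DomainError("g0 must be positive")
    mus = np.linspace(0.0, 89.5, n_scan)
    res = np.empty(n_scan)
    ok = np.zeros(n_scan, dtype=bool)
    for i, m in enumerate(mus):
        res[i], ok[i] = _boundary_residual(g0, m, kappa_T, R, L, _RTOL_SCAN, _ATOL_SCAN)
    if not ok.any():
        return ShootingResult(status="integration-failed", bracket=(0.0, 89.5))

    def f(mu):
        return _boundary_residual(g0, mu, kappa_T, R, L, _RTOL_TIGHT, _ATOL_TIGHT)[0]

    roots = []
    for i in range(n_scan - 1):
        if res[i] == 0.0 and ok[i]:
            roots.append(float(mus[i]))
            continue
        if np.sign(res[i]) * np.sign(res[i + 1]) < 0:
            try:
                root = brentq(f, mus[i], mus[i + 1], xtol=1e-12, rtol=8.9e-16)
            except ValueError:
                continue
            r_val, success = _boundary_residual(
                g0, root, kappa_T, R, L, _RTOL_TIGHT, _ATOL_TIGHT
            )
            if success and abs(r_val) < _RESIDUAL_TOL:
                roots.append(float(root))
    if not roots:
        return ShootingResult(status="no-sign-change", bracket=(0.0, 89.5))
    primary = min(roots)
    params = EquilibriumParams(g0=g0, mu0=primary, kappa_T=kappa_T, L=L, R=R)
    solution = integrate_half_profile(params, n_grid=n_grid, rtol=_RTOL_TIGHT, atol=_ATOL_TIGHT)
    return ShootingResult(
        status="converged",
        kappa_T=kappa_T,
        residual=solution.boundary_radius - R,
        bracket=(0.0, 89.5),
        solution=solution,
        roots=tuple(sorted(roots)),
    )


def existence_limits(
    mu0: float,
    g0_range: tuple[float, float],
    R: float = 1.0,
    L: float = 1.25,
    n_g0: int = 25,
    bracket: tuple[float, float] = (-20.0, 20.0),
    n_scan: int = 49,
    g0_resolution: float = 1e-4,
):
    """Map the solvable band of neck radii at fixed mu0.

    Scans ``n_g0`` neck radii in ``g0_range``; for each, records whether any
    kappa_T in ``bracket`` meets the boundary condition and the interval of
    roots found.  The outer limits (the boundaries beyond which no solution
    exists) are then located by bisection on g0 to ``g0_resolution``.

    Returns
    -------
    dict with keys ``records`` (list of per-g0 dicts with ``g0``,
    ``converged``, ``kappa_interval``) and ``limits`` (list of refined
    boundary g0 values, one per convergence flip along the grid).
    """

    def probe(g0):
        r = solve_kappa(g0, mu0, R=R, L=L, bracket=bracket, n_scan=n_scan, n_grid=41)
        if r.converged:
            return True, (min(r.roots), max(r.roots))
        return False, None

    g0s = np.linspace(g0_range[0], g0_range[1], n_g0)
    records = []
    flags = []
    for g0 in g0s:
        conv, interval = probe(float(g0))
        flags.append(conv)
        records.append({"g0": float(g0), "converged": conv, "kappa_interval": interval})

    limits = []
    for i in range(len(g0s) - 1):
        if flags[i] != flags[i + 1]:
            lo, hi = float(g0s[i]), float(g0s[i + 1])
            f_lo = flags[i]
            while hi - lo > g0_resolution:
                mid = 0.5 * (lo + hi)
                if probe(mid)[0] == f_lo:
                    lo = mid
                else:
                    hi = mid
            limits.append(0.5 * (lo + hi))
    return {"records": records, "limits": limits}
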