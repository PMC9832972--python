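"""Differential geometry of surfaces of revolution and curves lying on them.

A surface of revolution is described by its meridian profile ``g(z)`` — the
distance from the symmetry axis as a function of the axial coordinate — via

    X(theta, z) = (g(z) cos(theta), g(z) sin(theta), z).

Primes denote derivatives with respect to ``z`` throughout (the meridian is a
graph over the axis, not an arc-length parameterization).  All lengths are
dimensionless, measured in units of the boundary radius R unless stated
otherwise.

Sign conventions
----------------
* The outward surface normal ``e_n`` points away from the symmetry axis.
* The mean curvature is ``H = (kappa_m + kappa_c)/2`` with the meridian
  curvature ``kappa_m = -g''/(1+g'^2)^{3/2}`` and the circumferential
  curvature ``kappa_c = 1/(g sqrt(1+g'^2))``, so a sphere of radius rho has
  ``H = +1/rho`` everywhere and a catenoid has ``H = 0``.
* The signed normal curvature of a curve on the surface is
  ``kappa_signed = -kappa * (e_p . e_n)`` where ``e_p`` is the principal
  normal: positive when the curve bends toward the interior of the body, so
  great circles on a sphere have ``+1/rho``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicHermiteSpline, CubicSpline

__all__ = [
    "ProfileCurve",
    "SpaceCurve",
    "SurfaceFrame",
    "surface_point",
    "surface_normal",
    "surface_frame",
    "curve_frame",
    "colinearity_residual",
    "principal_curvatures",
    "mean_curvature",
]


class DomainError(ValueError):
    """Input outside the mathematical domain of an operation."""


# --------------------------------------------------------------------------- #
# profile curves
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class ProfileCurve:
    """Meridian ``g(z)`` of a surface of revolution sampled on a z-grid.

    Parameters
    ----------
    z_grid : ndarray
        Strictly increasing axial coordinates.
    g, g_prime, g_double_prime : ndarray
        Meridian radius and its first two z-derivatives at each node.
        ``g`` must be positive everywhere.

    Evaluation between nodes uses a C1 cubic Hermite interpolant built from
    ``(g, g')``; the second derivative is interpolated separately from the
    ``g''`` samples so that analytically supplied curvatures are honored at
    the nodes.
    """

    z_grid: np.ndarray
    g: np.ndarray
    g_prime: np.ndarray
    g_double_prime: np.ndarray
    _spline: CubicHermiteSpline = field(init=False, repr=False, compare=False)
    _d2_spline: CubicSpline = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        z = np.asarray(self.z_grid, dtype=float)
        g = np.asarray(self.g, dtype=float)
        gp = np.asarray(self.g_prime, dtype=float)
        gpp = np.asarray(self.g_double_prime, dtype=float)
        if z.ndim != 1 or len(z) < 2:
            raise DomainError("z_grid must be a 1-D array with >= 2 nodes")
        if np.any(np.diff(z) <= 0):
            raise DomainError("z_grid must be strictly increasing")
        if np.any(g <= 0):
            raise DomainError("meridian radius g must be positive everywhere")
        object.__setattr__(self, "z_grid", z)
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "g_prime", gp)
        object.__setattr__(self, "g_double_prime", gpp)
        object.__setattr__(self, "_spline", CubicHermiteSpline(z, g, gp))
        object.__setattr__(self, "_d2_spline", CubicSpline(z, gpp))

    @classmethod
    def from_callable(
        cls,
        g,
        z_min: float,
        z_max: float,
        dg=None,
        d2g=None,
        n: int = 801,
    ) -> "ProfileCurve":
        """Sample an analytic meridian on a uniform grid.

        Missing derivatives are obtained by high-order central differences
        with step scaled to the grid.
        """
        z = np.linspace(z_min, z_max, n)
        gz = np.asarray(g(z), dtype=float) * np.ones_like(z)
        h = (z_max - z_min) / (8 * (n - 1))
        if dg is None:
            dgz = (8 * (g(z + h) - g(z - h)) - (g(z + 2 * h) - g(z - 2 * h))) / (12 * h)
        else:
            dgz = np.asarray(dg(z), dtype=float) * np.ones_like(z)
        if d2g is None:
            d2gz = (
                16 * (g(z + h) + g(z - h))
                - (g(z + 2 * h) + g(z - 2 * h))
                - 30 * gz
            ) / (12 * h * h)
        else:
            d2gz = np.asarray(d2g(z), dtype=float) * np.ones_like(z)
        return cls(z, gz, dgz, d2gz)

    @classmethod
    def from_samples(cls, z, g) -> "ProfileCurve":
        """Build a profile from raw ``(z, g)`` samples via cubic spline."""
        sp = CubicSpline(np.asarray(z, float), np.asarray(g, float))
        z = np.asarray(z, float)
        return cls(z, sp(z), sp(z, 1), sp(z, 2))

    @property
    def z_min(self) -> float:
        return float(self.z_grid[0])

    @property
    def z_max(self) -> float:
        return float(self.z_grid[-1])

    def _check_range(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        eps = 1e-12 * max(1.0, self.z_max - self.z_min)
        if np.any(z < self.z_min - eps) or np.any(z > self.z_max + eps):
            raise DomainError(
                f"z outside profile range [{self.z_min}, {self.z_max}]"
            )
        return np.clip(z, self.z_min, self.z_max)

    def __call__(self, z, nu: int = 0):
        """Evaluate ``g`` (``nu=0``), ``g'`` (``nu=1``) or ``g''`` (``nu=2``)."""
        z = self._check_range(z)
        if nu == 0:
            return self._spline(z)
        if nu == 1:
            return self._spline(z, 1)
        if nu == 2:
            return self._d2_spline(z)
        raise DomainError("nu must be 0, 1 or 2")


# --------------------------------------------------------------------------- #
# surface maps and frames
# --------------------------------------------------------------------------- #


def surface_point(theta, z, profile: ProfileCurve) -> np.ndarray:
    """Map surface coordinates ``(theta, z)`` to 3-D points.

    Returns an array of shape ``(..., 3)`` with entries
    ``(g(z) cos(theta), g(z) sin(theta), z)``.
    """
    theta = np.asarray(theta, dtype=float)
    z = np.asarray(z, dtype=float)
    g = profile(z)
    return np.stack(
        [g * np.cos(theta), g * np.sin(theta), np.broadcast_to(z, g.shape).copy()],
        axis=-1,
    )


def surface_normal(theta, z, profile: ProfileCurve) -> np.ndarray:
    """Outward unit normal of the surface of revolution at ``(theta, z)``.

    ``e_n = (cos(theta), sin(theta), -g'(z)) / sqrt(1 + g'(z)^2)`` — the
    normal points away from the symmetry axis.
    """
    theta = np.asarray(theta, dtype=float)
    z = np.asarray(z, dtype=float)
    gp = profile(z, 1)
    denom = np.sqrt(1.0 + gp**2)
    theta, gp, denom = np.broadcast_arrays(theta, gp, denom)
    return np.stack(
        [np.cos(theta) / denom, np.sin(theta) / denom, -gp / denom], axis=-1
    )


@dataclass(frozen=True)
class SurfaceFrame:
    """Orthonormal surface frame along a set of surface points.

    ``circumferential_dir`` (e_1) and ``meridian_dir`` (e_2) are the principal
    curvature lines; ``outward_normal = e_1 x e_2`` completes the right-handed
    triad.  ``principal_curvatures`` holds ``(kappa_circ, kappa_meridian)`` in
    the same order.
    """

    outward_normal: np.ndarray
    meridian_dir: np.ndarray
    circumferential_dir: np.ndarray
    principal_curvatures: np.ndarray


def surface_frame(theta, z, profile: ProfileCurve) -> SurfaceFrame:
    """Principal-direction frame of the surface of revolution at ``(theta, z)``."""
    theta = np.asarray(theta, dtype=float)
    z = np.asarray(z, dtype=float)
    g = profile(z)
    gp = profile(z, 1)
    gpp = profile(z, 2)
    theta, g, gp, gpp = np.broadcast_arrays(theta, g, gp, gpp)
    s = np.sqrt(1.0 + gp**2)
    ct, st = np.cos(theta), np.sin(theta)
    meridian = np.stack([gp * ct / s, gp * st / s, 1.0 / s], axis=-1)
    circ = np.stack([-st, ct, np.zeros_like(ct)], axis=-1)
    normal = np.cross(circ, meridian)
    kappa_c = 1.0 / (g * s)
    kappa_m = -gpp / s**3
    return SurfaceFrame(
        outward_normal=normal,
        meridian_dir=meridian,
        circumferential_dir=circ,
        principal_curvatures=np.stack([kappa_c, kappa_m], axis=-1),
    )


def principal_curvatures(profile: ProfileCurve, z):
    """``(kappa_meridian, kappa_circumferential)`` of the surface at ``z``."""
    z = np.asarray(z, dtype=float)
    g, gp, gpp = profile(z), profile(z, 1), profile(z, 2)
    s = np.sqrt(1.0 + gp**2)
    return -gpp / s**3, 1.0 / (g * s)


def mean_curvature(profile: ProfileCurve, z):
    """Mean curvature ``H`` of the surface of revolution at ``z``.

    At a neck (``g' = 0``) this reduces to ``H = (1/g - g'')/2``.  A sphere of
    radius rho gives ``H = +1/rho`` at every z; a catenoid gives ``H = 0``.
    """
    km, kc = principal_curvatures(profile, z)
    return 0.5 * (km + kc)


# --------------------------------------------------------------------------- #
# space curves
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class SpaceCurve:
    """A 3-D curve with its tangent/principal-normal frame and curvature.

    ``frame_defined`` flags points where the curvature is large enough for
    the principal normal to be meaningful; on straight segments the curvature
    is reported as zero and the frame is flagged undefined rather than filled
    with noise.
    """

    points: np.ndarray
    tangent: np.ndarray
    principal_normal: np.ndarray
    curvature: np.ndarray
    frame_defined: np.ndarray
    param: np.ndarray

    def __len__(self) -> int:
        return len(self.points)


_STRAIGHT_TOL = 1e-10


def _frenet(points, d1, d2, t) -> SpaceCurve:
    speed = np.linalg.norm(d1, axis=-1)
    tangent = d1 / speed[:, None]
    cr = np.cross(d1, d2)
    kappa = np.linalg.norm(cr, axis=-1) / speed**3
    # principal normal from the tangent-orthogonal part of the acceleration
    acc_perp = d2 - (np.sum(d2 * tangent, axis=-1))[:, None] * tangent
    nrm = np.linalg.norm(acc_perp, axis=-1)
    defined = kappa > _STRAIGHT_TOL * np.maximum(1.0, 1.0 / np.maximum(speed, 1e-300))
    safe = np.where(nrm > 0, nrm, 1.0)
    e_p = np.where(defined[:, None], acc_perp / safe[:, None], 0.0)
    kappa = np.where(defined, kappa, 0.0)
    return SpaceCurve(
        points=np.asarray(points, float),
        tangent=tangent,
        principal_normal=e_p,
        curvature=kappa,
        frame_defined=defined,
        param=np.asarray(t, float),
    )


def curve_frame(points, t=None, first_deriv=None, second_deriv=None) -> SpaceCurve:
    """Tangent, principal normal and curvature along a 3-D curve.

    Parameters
    ----------
    points : (n, 3) array
        Ordered samples of the curve.
    t : (n,) array, optional
        Curve parameter at each sample (the axial coordinate z for fiber
        curves).  Defaults to cumulative chord length.
    first_deriv, second_deriv : (n, 3) arrays, optional
        Analytic derivatives with respect to ``t``.  When omitted they are
        estimated with a cubic spline, which limits the achievable accuracy;
        supply them for machine-precision frames.

    The curvature equals the Frenet value ``|X' x X''| / |X'|^3``.  Straight
    segments return zero curvature with ``frame_defined`` False.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise DomainError("points must have shape (n, 3)")
    if t is None:
        chord = np.linalg.norm(np.diff(points, axis=0), axis=1)
        t = np.concatenate([[0.0], np.cumsum(chord)])
    t = np.asarray(t, dtype=float)
    if first_deriv is None or second_deriv is None:
        sp = CubicSpline(t, points, axis=0)
        d1 = sp(t, 1) if first_deriv is None else np.asarray(first_deriv, float)
        d2 = sp(t, 2) if second_deriv is None else np.asarray(second_deriv, float)
    else:
        d1 = np.asarray(first_deriv, dtype=float)
        d2 = np.asarray(second_deriv, dtype=float)
    return _frenet(points, d1, d2, t)


def signed_normal_curvature(curve: SpaceCurve, normal: np.ndarray) -> np.ndarray:
    """Signed curvature of a surface curve: ``-kappa * (e_p . e_n)``.

    Positive when the principal normal points into the body (opposite the
    outward surface normal), so great circles on a sphere come out positive.
    Undefined-frame points return 0.
    """
    dot = np.sum(curve.principal_normal * normal, axis=-1)
    return np.where(curve.frame_defined, -curve.curvature * dot, 0.0)


def colinearity_residual(
    curve: SpaceCurve,
    profile: ProfileCurve,
    on_surface_tol: float = 1e-6,
) -> np.ndarray:
    """``|e_p x e_n|`` per point — zero exactly when the curve is a geodesic.

    The surface normal is evaluated from ``profile`` at the curve's own
    ``(theta, z)``; the curve must lie on the surface to ``on_surface_tol``.
    Points with an undefined frame (straight segments, which are geodesics
    whenever they lie in the surface) report residual 0.
    """
    x, y, z = curve.points.T
    r = np.hypot(x, y)
    dist = np.abs(r - profile(z))
    if np.max(dist) > on_surface_tol:
        raise DomainError(
            f"curve is not on the surface: max radial distance {np.max(dist):.3e}"
        )
    theta = np.arctan2(y, x)
    e_n = surface_normal(theta, z, profile)
    res = np.linalg.norm(np.cross(curve.principal_normal, e_n), axis=-1)
    return np.where(curve.frame_defined, res, 0.0)
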