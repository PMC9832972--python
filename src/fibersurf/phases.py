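"""Parameter sweeps and pressure-sign classification.

Iso-mu0 families in (kappa_T, g0) and (H_neck, g0) space, the zero-pressure
neck radii of the fiber and isotropic models, the proximity of
fiber-stabilized shapes to Delaunay (constant-mean-curvature) shapes, and
region classification for experimental (H_neck, g0) points.

Records are computed independently per grid point, so sweeps are
deterministic and order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .geometry import DomainError
from .reference import catenoid_neck, delaunay_solve, hyperboloid_neck
from .shooting import ShootingResult, solve_kappa

__all__ = [
    "SweepRecord",
    "sweep_iso_mu0",
    "sweep_to_frame",
    "pressure_region",
    "zero_pressure_neck",
    "delaunay_proximity",
    "overlay_experiment",
    "hyperboloid_H_neck",
]

DEFAULT_MU0_GRID = (0.0, 10.0, 20.0, 30.0, 35.0, 40.0, 50.0, 58.0, 70.0)


@dataclass(frozen=True)
class SweepRecord:
    """One point of a phase-diagram sweep.

    ``pressure_sign`` follows the fiber model, sign(kappa_T); non-converged
    records carry NaNs and sign 0.
    """

    mu0: float
    g0: float
    status: str
    kappa_T: float = math.nan
    H_neck: float = math.nan
    pressure_sign: int = 0


def _record_from(mu0: float, g0: float, result: ShootingResult) -> SweepRecord:
    if not result.converged:
        return SweepRecord(mu0=mu0, g0=g0, status=result.status)
    sol = result.solution
    return SweepRecord(
        mu0=mu0,
        g0=g0,
        status="converged",
        kappa_T=result.kappa_T,
        H_neck=sol.H_neck,
        pressure_sign=sol.pressure_sign,
    )


def sweep_iso_mu0(
    mu0_list=DEFAULT_MU0_GRID,
    g0_grid=None,
    R: float = 1.0,
    L: float = 1.25,
    bracket: tuple[float, float] = (-20.0, 20.0),
    n_scan: int = 97,
) -> list[SweepRecord]:
    """One shooting solve per (mu0, g0); no-solution points are recorded too.

    ``H_neck`` comes from the converged profile's g''(0) evaluated through
    the ODE right-hand side (not finite differences), so the symmetry point
    is noise-free.  Records are returned ordered by (mu0, g0).
    """
    if g0_grid is None:
        rho = math.hypot(R, L / 2.0)
        g0_grid = np.arange(0.05, rho + 1e-9, 0.01)
    records = []
    for mu0 in sorted(mu0_list):
        for g0 in sorted(np.asarray(g0_grid, float)):
            res = solve_kappa(
                float(g0), float(mu0), R=R, L=L, bracket=bracket, n_scan=n_scan, n_grid=81
            )
            records.append(_record_from(float(mu0), float(g0), res))
    return records


def sweep_to_frame(records) -> pd.DataFrame:
    """Sweep records as a tidy DataFrame (mu0_deg, g0, kappa_T, H_neck, ...)."""
    df = pd.DataFrame([asdict(r) for r in records])
    return df.rename(columns={"mu0": "mu0_deg"})


def pressure_region(record: SweepRecord, model: str = "fiber") -> int:
    """Sign of the tissue pressure induced by the surface stress.

    ``fiber`` model: p ~ kappa_T (contractile fibers of positive normal
    curvature compress the interior); ``isotropic`` model: p ~ H_neck via
    the classical Young-Laplace balance.  Zero marks the respective
    zero-pressure boundary (hyperboloids, resp. the catenoid).
    """
    if record.status != "converged":
        raise DomainError("pressure sign undefined for non-converged record")
    if model == "fiber":
        return int(np.sign(record.kappa_T))
    if model == "isotropic":
        return int(np.sign(record.H_neck))
    raise DomainError("model must be 'fiber' or 'isotropic'")


def hyperboloid_H_neck(g0: float, R: float = 1.0, L: float = 1.25) -> float:
    """Neck mean curvature of the hyperboloid with neck g0 (the kappa_T=0 line).

    ``H_neck = (1 - m) / (2 g0)`` with ``m = (R^2 - g0^2)/(L/2)^2``.
    """
    if not 0 < g0 <= R:
        raise DomainError("hyperboloids require 0 < g0 <= R")
    half = L / 2.0
    m = (R * R - g0 * g0) / (half * half)
    return (1.0 - m) / (2.0 * g0)


def zero_pressure_neck(
    model: str,
    mu0: float | None = None,
    R: float = 1.0,
    L: float = 1.25,
    method: str = "analytic",
) -> float:
    """Neck radius at which the induced pressure changes sign.

    * ``isotropic``: the catenoid neck radius (H = 0 Delaunay member).
    * ``fiber`` at fibril angle ``mu0``: the g0 where the iso-mu0 family
      crosses kappa_T = 0 — analytically the hyperboloid with ruling angle
      mu0, or numerically (``method="sweep"``) by locating the sign change
      of the shooting solver's kappa_T along g0.
    """
    if model == "isotropic":
        c, _ = catenoid_neck(R, L)
        return c
    if model != "fiber":
        raise DomainError("model must be 'fiber' or 'isotropic'")
    if mu0 is None:
        raise DomainError("fiber model requires mu0")
    if mu0 == 0:
        return R  # cylinder = degenerate hyperboloid
    g0_analytic = hyperboloid_neck(mu0, R, L)
    if method == "analytic":
        return g0_analytic

    def kappa_at(g0):
        res = solve_kappa(g0, mu0, R=R, L=L, bracket=(-3.0, 3.0), n_scan=49, n_grid=41)
        if not res.converged:
            raise DomainError(f"no solution at g0={g0} mu0={mu0}")
        return res.kappa_T

    lo, hi = 0.9 * g0_analytic, min(1.1 * g0_analytic, 0.999 * R)
    return brentq(kappa_at, lo, hi, xtol=1e-7)


def delaunay_proximity(
    mu0: float,
    g0_list,
    R: float = 1.0,
    L: float = 1.25,
    n_z: int = 201,
) -> pd.DataFrame:
    """Profile deviation between fiber-stabilized and Delaunay shapes.

    For each neck radius: solves both models at equal (g0, R, L) and reports
    the sup-norm meridian deviation ``max_z |g_fiber - g_delaunay|`` and the
    neck mean-curvature gap ``H_neck(fiber) - H(Delaunay)``.  Unsolvable
    cases are recorded with NaN deviations.
    """
    rows = []
    z = np.linspace(-L / 2.0, L / 2.0, n_z)
    for g0 in g0_list:
        row = {"g0": float(g0), "mu0": float(mu0)}
        try:
            fib = solve_kappa(float(g0), mu0, R=R, L=L)
            if not fib.converged:
                raise DomainError(fib.status)
            dela = delaunay_solve(float(g0), R=R, L=L)
            dg = np.abs(fib.solution.profile(z) - dela.profile(z))
            row.update(
                sup_deviation=float(np.max(dg)),
                H_neck_fiber=fib.solution.H_neck,
                H_delaunay=dela.H,
                delta_H_neck=fib.solution.H_neck - dela.H,
                status="ok",
            )
        except DomainError as exc:
            row.update(
                sup_deviation=math.nan,
                H_neck_fiber=math.nan,
                H_delaunay=math.nan,
                delta_H_neck=math.nan,
                status=f"gap: {exc}",
            )
        rows.append(row)
    return pd.DataFrame(rows)


def overlay_experiment(
    points_csv,
    R: float = 1.0,
    L: float = 1.25,
) -> pd.DataFrame:
    """Classify experimental (H_neck, g0) points under both pressure models.

    The CSV must have columns ``H_neck`` and ``g0``.  The fiber model's
    zero-pressure boundary is the hyperboloid line H_neck(g0); points above
    it (toward larger H at given g0, or any g0 > R) sit at positive induced
    pressure.  The isotropic boundary is the vertical H = 0 line.
    """
    df = pd.read_csv(points_csv)
    if df.empty:
        return df.assign(fiber_sign=pd.Series(dtype=int), isotropic_sign=pd.Series(dtype=int))
    missing = {"H_neck", "g0"} - set(df.columns)
    if missing:
        raise DomainError(f"points CSV lacks columns: {sorted(missing)}")

    def fiber_sign(row):
        if row.g0 > R:
            return 1
        return int(np.sign(row.H_neck - hyperboloid_H_neck(row.g0, R, L)))

    df = df.copy()
    df["fiber_sign"] = df.apply(fiber_sign, axis=1)
    df["isotropic_sign"] = np.sign(df["H_neck"]).astype(int)
    return df
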