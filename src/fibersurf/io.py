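"""Formats, configuration, mesh export and fixture generation.

Tabular data travels as CSV (UTF-8, '.' decimal, header row): profiles as
``z, g, g_prime``, space curves as ``t, x, y, z``, solved equilibria as
``z, g, g_prime, theta, alpha`` with a JSON metadata sidecar.  Run
configuration round-trips through YAML.  Surface meshes are written as OBJ
tubes with fiber polylines appended as OBJ line elements.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from . import reference
from .equilibrium import FiberSolution
from .geometry import DomainError, ProfileCurve, SpaceCurve
from .reference import DelaunaySolution

__all__ = [
    "RunConfig",
    "write_profile_csv",
    "read_profile_csv",
    "write_curve_csv",
    "read_curve_csv",
    "export_solution",
    "export_mesh",
    "fixture_suite",
]


# --------------------------------------------------------------------------- #
# tabular I/O
# --------------------------------------------------------------------------- #


def write_profile_csv(profile: ProfileCurve, path) -> None:
    pd.DataFrame(
        {"z": profile.z_grid, "g": profile.g, "g_prime": profile.g_prime}
    ).to_csv(path, index=False)


def read_profile_csv(path) -> ProfileCurve:
    df = pd.read_csv(path)
    missing = {"z", "g"} - set(df.columns)
    if missing:
        raise DomainError(f"profile CSV lacks columns: {sorted(missing)}")
    if "g_prime" in df.columns:
        z, g, gp = df["z"].to_numpy(), df["g"].to_numpy(), df["g_prime"].to_numpy()
        from scipy.interpolate import CubicHermiteSpline

        gpp = CubicHermiteSpline(z, g, gp)(z, 2)
        return ProfileCurve(z, g, gp, gpp)
    return ProfileCurve.from_samples(df["z"].to_numpy(), df["g"].to_numpy())


def write_curve_csv(curve: SpaceCurve, path) -> None:
    x, y, z = curve.points.T
    pd.DataFrame({"t": curve.param, "x": x, "y": y, "z": z}).to_csv(path, index=False)


def read_curve_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    missing = {"t", "x", "y", "z"} - set(df.columns)
    if missing:
        raise DomainError(f"curve CSV lacks columns: {sorted(missing)}")
    return df[["x", "y", "z"]].to_numpy()


def export_solution(solution: FiberSolution, prefix) -> tuple[Path, Path]:
    """Write a solved equilibrium as ``<prefix>.csv`` + ``<prefix>.json``."""
    prefix = Path(prefix)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    pd.DataFrame(
        {
            "z": solution.z,
            "g": solution.g,
            "g_prime": solution.profile.g_prime,
            "theta": solution.theta,
            "alpha": solution.alpha,
        }
    ).to_csv(csv_path, index=False)
    p = solution.params
    meta = {
        "g0": p.g0,
        "mu0": p.mu0,
        "kappa_T": solution.kappa_T,
        "K": None if math.isinf(p.K) else p.K,
        "H_neck": solution.H_neck,
        "L": p.L,
        "R": p.R,
        "chirality": p.chirality,
        "pressure_sign": solution.pressure_sign,
    }
    json_path.write_text(json.dumps(meta, indent=2))
    return csv_path, json_path


# --------------------------------------------------------------------------- #
# configuration
# --------------------------------------------------------------------------- #


@dataclass
class RunConfig:
    """Geometry, solver tolerances and sweep grids for a run.

    The solver itself is deterministic; ``seed`` only feeds property-test
    sampling and fixture randomization.
    """

    R: float = 1.0
    L: float = 1.25
    rtol: float = 1e-10
    atol: float = 1e-12
    kappa_bracket: tuple[float, float] = (-20.0, 20.0)
    n_scan: int = 97
    chirality: int = 1
    mu0_grid: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 35.0, 40.0, 50.0, 58.0, 70.0)
    g0_min: float = 0.05
    g0_step: float = 0.01
    outdir: str = "."
    seed: int = 0

    def save(self, path) -> None:
        d = dataclasses.asdict(self)
        d["kappa_bracket"] = list(self.kappa_bracket)
        d["mu0_grid"] = list(self.mu0_grid)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["kappa_bracket"] = tuple(d["kappa_bracket"])
        d["mu0_grid"] = tuple(d["mu0_grid"])
        return cls(**d)


# --------------------------------------------------------------------------- #
# mesh export
# --------------------------------------------------------------------------- #


def surface_mesh(profile: ProfileCurve, n_theta: int = 64, n_z: int = 65) -> trimesh.Trimesh:
    """Triangulated tube over the (theta, z) grid, watertight in theta.

    ``n_theta`` vertices per ring (wrapped), ``n_z`` rings, giving
    ``2 n_theta (n_z - 1)`` triangles and the Euler characteristic of an
    open tube (0).
    """
    if n_theta < 3 or n_z < 2:
        raise DomainError("need n_theta >= 3 and n_z >= 2")
    z = np.linspace(profile.z_min, profile.z_max, n_z)
    th = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
    g = profile(z)
    zz, tt = np.meshgrid(z, th, indexing="ij")
    gg = np.repeat(g[:, None], n_theta, axis=1)
    verts = np.column_stack(
        [(gg * np.cos(tt)).ravel(), (gg * np.sin(tt)).ravel(), zz.ravel()]
    )
    faces = []
    for i in range(n_z - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c = (i + 1) * n_theta + j
            d = (i + 1) * n_theta + (j + 1) % n_theta
            faces.append([a, b, d])
            faces.append([a, d, c])
    return trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)


def export_mesh(
    solution: FiberSolution | DelaunaySolution | ProfileCurve,
    path,
    n_theta: int = 64,
    n_z: int = 65,
    n_fibers: int = 0,
) -> trimesh.Trimesh:
    """Write an OBJ tube mesh; fiber polylines are appended as OBJ lines.

    ``n_fibers > 0`` requires a solved :class:`FiberSolution` (the fibers
    are the rotated copies of its base fiber).
    """
    profile = solution if isinstance(solution, ProfileCurve) else solution.profile
    mesh = surface_mesh(profile, n_theta=n_theta, n_z=n_z)
    path = Path(path)
    path.write_text(mesh.export(file_type="obj"))
    if n_fibers:
        if not isinstance(solution, FiberSolution):
            raise DomainError("fiber export needs a FiberSolution")
        from .equilibrium import fiber_family

        n_base = len(mesh.vertices)
        lines = ["\n# fiber polylines"]
        for curve in fiber_family(solution, n_fibers):
            start = n_base + 1  # OBJ indices are 1-based
            for p in curve.points:
                lines.append(f"v {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
            n_pts = len(curve.points)
            idx = " ".join(str(start + i) for i in range(n_pts))
            lines.append(f"l {idx}")
            n_base += n_pts
        with path.open("a") as fh:
            fh.write("\n".join(lines) + "\n")
    return mesh


# --------------------------------------------------------------------------- #
# fixture generation
# --------------------------------------------------------------------------- #


def fixture_suite(seed: int = 0, R: float = 1.0, L: float = 1.25) -> dict:
    """Deterministic catalog of analytic oracle shapes for testing.

    Covers every named family — sphere, cylinder, hyperboloid, catenoid,
    torus segment, unduloid, nodoid, and 2-/3-sphere stacks — with
    parameters drawn reproducibly from ``seed``.  Each entry carries the
    profile and the closed-form constants a test needs to verify it.
    """
    rng = np.random.default_rng(seed)
    half = L / 2.0
    catalog: dict[str, dict] = {}

    prof, rho, kT, mu_max = reference.sphere_segment(R, L)
    catalog["sphere"] = {
        "profile": prof, "rho": rho, "kappa_T": kT, "mu_max": mu_max, "H": 1.0 / rho,
    }

    r_cyl = R
    catalog["cylinder"] = {
        "profile": ProfileCurve.from_callable(
            lambda z: r_cyl + 0.0 * z, -half, half,
            lambda z: 0.0 * z, lambda z: 0.0 * z,
        ),
        "radius": r_cyl,
        "H": 0.5 / r_cyl,
    }

    g0_h = float(rng.uniform(0.4, 0.9)) * R
    prof_h, mu0_h = reference.hyperboloid(g0_h, R, L)
    catalog["hyperboloid"] = {"profile": prof_h, "g0": g0_h, "mu0": mu0_h, "kappa_T": 0.0}

    c, _ = reference.catenoid_neck(R, L)
    catalog["catenoid"] = {
        "profile": reference.catenoid_profile(c, L), "c": c, "H": 0.0,
    }

    g0_t = R * float(rng.uniform(1.05, 1.3))
    prof_t, kT_t = reference.torus_segment(g0_t, R, L)
    catalog["torus_segment"] = {"profile": prof_t, "g0": g0_t, "kappa_T": kT_t}

    g0_u = float(rng.uniform(0.75, 0.95)) * reference.catenoid_neck(R, L)[0]
    dela_u = reference.delaunay_solve(g0_u, R, L)
    catalog["nodoid" if dela_u.H < 0 else "unduloid"] = {
        "profile": dela_u.profile, "g0": g0_u, "H": dela_u.H, "solution": dela_u,
    }
    g0_v = float(rng.uniform(1.02, 1.12)) * R
    dela_v = reference.delaunay_solve(g0_v, R, L)
    catalog["unduloid" if dela_v.H > 0 else "nodoid"] = {
        "profile": dela_v.profile, "g0": g0_v, "H": dela_v.H, "solution": dela_v,
    }

    g0_2 = float(rng.uniform(0.6, 0.95)) * R
    prof2, g0_2, kT2 = reference.stacked_spheres(2, R, L, g0=g0_2)
    catalog["stack2"] = {"profile": prof2, "g0": g0_2, "kappa_T": kT2}
    g0_3 = float(rng.uniform(1.02, 1.1)) * R
    prof3, g0_3, kT3 = reference.stacked_spheres(3, R, L, g0=g0_3)
    catalog["stack3"] = {"profile": prof3, "g0": g0_3, "kappa_T": kT3}

    return catalog
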