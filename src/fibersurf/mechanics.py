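"""Pressure-tension relations: classical and fiber-modified Young-Laplace laws.

Three balances relate surface stress to the pressure jump across a membrane:

* isotropic surface stress ``gamma_s``:  ``p = -gamma_s (1/R1 + 1/R2) = -2 gamma_s H``
* general membrane forces:               ``p = N1/R1 + N2/R2``
* pure fiber stress (transverse force 0): ``p = d sigma_T / R_T``

The first two equations carry opposite orientation conventions for p in the
source formulations (the isotropic law measures p against the outward
normal, the membrane law along ``e_1 x e_2``); each function here implements
its own printed form and the docstrings state the orientation, so the
single package-wide physical convention is: p is interior minus exterior,
positive when tension on a convex (sphere-like) surface compresses the
interior.  On that convention the membrane and fiber laws are used directly
and the isotropic law's output must be negated.

A minimal units layer guards against mixing scales: the functions accept
plain floats (assumed SI) or :class:`Quantity` values with explicit units;
quantities of the wrong dimension raise.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

__all__ = [
    "Quantity",
    "parse_quantity",
    "UnitError",
    "young_laplace",
    "membrane_pressure",
    "fiber_pressure",
    "effective_tension",
]


class UnitError(ValueError):
    """Mismatched or unknown physical units."""


# unit -> (dimension, factor to SI)
_UNITS = {
    "Pa": ("pressure", 1.0),
    "kPa": ("pressure", 1e3),
    "MPa": ("pressure", 1e6),
    "m": ("length", 1.0),
    "mm": ("length", 1e-3),
    "um": ("length", 1e-6),
    "µm": ("length", 1e-6),
    "μm": ("length", 1e-6),
    "nm": ("length", 1e-9),
    "N/m": ("tension", 1.0),
    "mN/m": ("tension", 1e-3),
}


@dataclass(frozen=True)
class Quantity:
    """A value in SI units with an explicit physical dimension."""

    si_value: float
    dimension: str

    def to(self, unit: str) -> float:
        dim, factor = _lookup(unit)
        if dim != self.dimension:
            raise UnitError(f"cannot express {self.dimension} in {unit}")
        return self.si_value / factor

    def __float__(self) -> float:
        return self.si_value


def _lookup(unit: str):
    if unit not in _UNITS:
        raise UnitError(f"unknown unit {unit!r}; known: {sorted(_UNITS)}")
    return _UNITS[unit]


_QTY_RE = re.compile(r"^\s*([+-]?[0-9.eE+-]+)\s*([A-Za-zµμ/]+)\s*$")


def parse_quantity(text: str) -> Quantity:
    """Parse strings like ``"2kPa"``, ``"10 um"``, ``"20 mN/m"``."""
    m = _QTY_RE.match(text)
    if not m:
        raise UnitError(f"cannot parse quantity {text!r}")
    value, unit = m.groups()
    dim, factor = _lookup(unit)
    return Quantity(float(value) * factor, dim)


def _as_si(value, dimension: str, name: str) -> float:
    """Accept a float (SI assumed) or a Quantity of the right dimension."""
    if isinstance(value, Quantity):
        if value.dimension != dimension:
            raise UnitError(
                f"{name} must be a {dimension}, got {value.dimension}"
            )
        return value.si_value
    if isinstance(value, str):
        return _as_si(parse_quantity(value), dimension, name)
    return float(value)


def young_laplace(gamma_s, R1, R2):
    """Isotropic Young-Laplace pressure ``-gamma_s (1/R1 + 1/R2)`` (Pa).

    ``R1, R2`` are the signed principal curvature radii.  The sign follows
    the isotropic law's own orientation (p measured against the outward
    normal): a unit sphere under unit tension gives -2.
    """
    g = _as_si(gamma_s, "tension", "gamma_s")
    r1 = _as_si(R1, "length", "R1")
    r2 = _as_si(R2, "length", "R2")
    if r1 == 0 or r2 == 0:
        raise UnitError("curvature radii must be nonzero")
    return -g * (1.0 / r1 + 1.0 / r2)


def membrane_pressure(N1, N2, R1, R2):
    """General membrane balance ``p = N1/R1 + N2/R2`` (Pa).

    ``N1, N2`` are membrane forces per length along the principal curvature
    lines; p is measured along ``e_1 x e_2``.  With isotropic forces
    ``N1 = N2 = gamma_s`` this is the negative of :func:`young_laplace`;
    with the force transverse to the fiber zero it reduces exactly to
    :func:`fiber_pressure`.
    """
    n1 = _as_si(N1, "tension", "N1")
    n2 = _as_si(N2, "tension", "N2")
    r1 = _as_si(R1, "length", "R1")
    r2 = _as_si(R2, "length", "R2")
    if r1 == 0 or r2 == 0:
        raise UnitError("curvature radii must be nonzero")
    return n1 / r1 + n2 / r2


def fiber_pressure(d, sigma_T, R_T):
    """Fiber-generated pressure ``p = d sigma_T / R_T`` (Pa).

    ``d`` is the contractile layer thickness, ``sigma_T`` the fiber stress,
    ``R_T`` the signed fiber curvature radius; p inherits the sign of 1/R_T
    (positive normal curvature compresses the interior; straight fibers,
    as on a hyperboloid, give zero).
    """
    dv = _as_si(d, "length", "d")
    s = _as_si(sigma_T, "pressure", "sigma_T")
    rt = _as_si(R_T, "length", "R_T")
    if dv <= 0:
        raise UnitError("layer thickness d must be positive")
    if rt == 0:
        raise UnitError("fiber curvature radius R_T must be nonzero")
    return dv * s / rt


def effective_tension(sigma_T, d) -> float:
    """Surface-tension equivalent ``sigma_T * d`` of the contractile layer, in mN/m.

    A 10 um myofibroblast layer contracting at 2-5 kPa is equivalent to
    20-50 mN/m of surface tension — up to two orders of magnitude above
    reported bare tissue surface tensions (0.1-3 mN/m).
    """
    s = _as_si(sigma_T, "pressure", "sigma_T")
    dv = _as_si(d, "length", "d")
    if s < 0 or dv <= 0:
        raise UnitError("sigma_T must be >= 0 and d > 0")
    return Quantity(s * dv, "tension").to("mN/m")
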