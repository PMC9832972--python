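"""Phase-diagram figures: neck radius vs fiber curvature or neck mean curvature.

Static exports only (SVG/PNG via matplotlib); landmarks drawn alongside the
swept families: the cylinder line, the hyperboloid (zero-pressure) locus,
the single-sphere point and the stacked-sphere limit curves.
"""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .phases import hyperboloid_H_neck, sweep_to_frame

__all__ = ["plot_phase_diagram"]


def plot_phase_diagram(
    records,
    x: str = "kappa_T",
    R: float = 1.0,
    L: float = 1.25,
    path=None,
    ax=None,
):
    """Plot iso-mu0 families from sweep records.

    ``x`` selects the abscissa: ``"kappa_T"`` (fiber curvature) or
    ``"H_neck"`` (neck mean curvature).  Returns the matplotlib Axes;
    ``path`` additionally writes the figure (format from the suffix).
    """
    if x not in ("kappa_T", "H_neck"):
        raise ValueError("x must be 'kappa_T' or 'H_neck'")
    df = sweep_to_frame(records)
    conv = df[df.status == "converged"]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))

    for mu0, grp in conv.groupby("mu0_deg"):
        grp = grp.sort_values("g0")
        ax.plot(grp[x], grp.g0, "-o", ms=2.5, lw=1, color="0.45")
        ax.annotate(f"{mu0:g}°", (grp[x].iloc[-1], grp.g0.iloc[-1]),
                    fontsize=7, color="0.3")

    rho = math.hypot(R, L / 2.0)
    g0s = np.linspace(0.2, R, 120)
    if x == "kappa_T":
        ax.axvline(0.0, color="tab:red", lw=1, label="hyperboloids ($\\kappa_T=0$)")
        mus = np.linspace(0.0, 60.0, 60)
        ax.plot(np.sin(np.radians(mus)) ** 2, np.ones_like(mus), "k--", lw=1,
                label="cylinders")
        ax.plot(1.0 / rho, rho, "ko", ms=6, label="single sphere")
        g_stack = np.linspace(R, rho, 40)
        ax.plot(1.0 / g_stack, g_stack, "b-", lw=1, label="3-sphere stacks")
        ax.set_xlabel("fiber curvature $\\kappa_T$ (1/R)")
    else:
        ax.plot([hyperboloid_H_neck(g, R, L) for g in g0s], g0s, "r-", lw=1,
                label="hyperboloids")
        ax.axvline(0.0, color="0.6", lw=0.8)
        ax.plot(0.5 / R, R, "ko", ms=5, label="cylinder")
        ax.plot(1.0 / rho, rho, "bo", ms=5, label="single sphere")
        ax.set_xlabel("neck mean curvature $H_{neck}$ (1/R)")
    ax.set_ylabel("neck radius $g_0$ (R)")
    ax.legend(fontsize=7, loc="best")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
    return ax
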