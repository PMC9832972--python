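"""Draw the (kappa_T, g0) and (H_neck, g0) phase diagrams.

Grey curves: iso-mu0 families from the shooting solver.  Landmarks: the
cylinder line kappa_T = sin^2(mu0) at g0 = 1, the hyperboloid zero-pressure
locus, the single-sphere point shared by every family with mu0 < 58 deg,
and the three-sphere stack limit kappa_T = 1/g0.
"""

from pathlib import Path

import numpy as np

import fibersurf as fs

out = Path("scratch")
out.mkdir(exist_ok=True)

records = fs.sweep_iso_mu0(
    mu0_list=(0.0, 20.0, 35.0, 50.0),
    g0_grid=np.round(np.arange(0.3, 1.21, 0.1), 10),
    bracket=(-8.0, 8.0),
    n_scan=49,
)
for x in ("kappa_T", "H_neck"):
    path = out / f"phase_{x}.svg"
    fs.plot_phase_diagram(records, x=x, path=path)
    print(f"wrote {path}")
print("x < 0 regions: fiber tension lowers interior pressure (growth-friendly);"
      " x > 0: it raises it.")
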