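"""Sweep the phase diagram: neck radius vs fiber curvature for fixed fibril angles.

Reproduces the structure of the (kappa_T, g0) diagram: cylinders at
kappa_T = sin^2(mu0) with g0 = 1, hyperboloids on the kappa_T = 0 line,
the single-sphere landmark at (0.848, 1.179) shared by every family with
mu0 < 58 degrees, and no-solution gaps beyond the stacked-sphere limits.
"""

import numpy as np

import fibersurf as fs

records = fs.sweep_iso_mu0(
    mu0_list=(0.0, 20.0, 35.0, 50.0),
    g0_grid=np.round(np.arange(0.3, 1.21, 0.1), 10),
    bracket=(-8.0, 8.0),
    n_scan=49,
)
df = fs.sweep_to_frame(records)
print(df.to_string(index=False, float_format=lambda v: f"{v:8.4f}"))
print()
conv = df[df.status == "converged"]
print(f"{len(conv)}/{len(df)} grid points converged.")
print("kappa_T < 0 rows: fibers reduce interior pressure (growth-friendly necks);")
print("kappa_T > 0 rows: fibers pressurize the interior (barrels, sphere stacks).")

# the zero-pressure boundary of each model
print(f"\nzero-pressure neck, isotropic model (catenoid): "
      f"{fs.zero_pressure_neck('isotropic'):.4f}")
print(f"zero-pressure neck, fiber model at 35 deg (hyperboloid): "
      f"{fs.zero_pressure_neck('fiber', mu0=35.0):.4f}")
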