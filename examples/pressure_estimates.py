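"""Order-of-magnitude mechanics: from fiber stress to tissue pressure.

Myofibroblast-like cells in the top ~10 um of a growing microtissue contract
at 2-5 kPa.  As an equivalent surface tension that is 20-50 mN/m — one to
two orders of magnitude above reported bare tissue surface tensions
(0.1-3 mN/m) — which is why the fibers, not the isotropic tension, set the
shape.
"""

import fibersurf as fs

for sigma in ("2kPa", "5kPa"):
    t = fs.effective_tension(sigma, "10um")
    print(f"sigma_T = {sigma:>5}, d = 10 um  ->  effective tension {t:5.1f} mN/m")

# pressure generated on a fiber of 1 mm curvature radius
p = fs.fiber_pressure("10um", "2kPa", "1mm")
print(f"\nfiber law: d sigma_T / R_T = {p:.1f} Pa for R_T = 1 mm")
print("straight fibers (hyperboloid rulings) give exactly zero pressure:")
print(f"  p = {fs.fiber_pressure('10um', '2kPa', float('inf')):.1f} Pa")

# classical isotropic comparison on a 1 mm sphere at 1 mN/m
print(f"\nisotropic Young-Laplace, 1 mN/m on a 1 mm sphere: "
      f"{fs.young_laplace('1mN/m', '1mm', '1mm'):.1f} Pa (law's own sign convention)")
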