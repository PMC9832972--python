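# fibersurf

Equilibrium shapes of growing tissue surfaces stabilized by contractile
fibers — an anisotropic generalization of the Young–Laplace law.

## The problem

Microtissues grown between two anchoring disks remodel fast enough to
behave as fluids: their shape is set by surface stress. For an isotropic
surface tension γ_s the Young–Laplace equation `p = −2 γ_s H` forces
constant mean curvature, and the bridge takes a **Delaunay shape**
(sphere, cylinder, catenoid, unduloid or nodoid). But the cells in the
top ~10 µm of such tissues contract through highly aligned actin stress
fibers, so the surface is strongly anisotropic. When all surface load is
carried by fibers under tension σ_T in a layer of thickness d, mechanical
equilibrium requires each fiber to

* follow a **geodesic** of the surface (its principal normal **e**_p
  colinear with the surface normal **e**_n), and
* keep a **constant normal curvature** κ_T = 1/R_T, so that the uniform
  interior pressure obeys `p = d σ_T / R_T` instead of Young–Laplace.

For surfaces of revolution `X(θ, z) = (g(z) cos θ, g(z) sin θ, z)` with a
fiber `θ(z)`, these conditions become the ODE system

```
g''  = (1+g'²) / (g (K g² − 1)) · (1 − K κ_T g³ √(1+g'²)),
θ'   = (1/g) √((1+g'²)/(K g² − 1)),      K = 1/(g₀² sin² μ₀),
```

with neck radius g₀ and fibril angle μ₀ at the neck, boundary condition
`g(±L/2) = R`, and Clairaut's relation `g sin α = g₀ sin μ₀` as an exact
first integral. The package solves this boundary-value problem by shooting
on κ_T, provides the closed-form limit shapes (cylinder, one-sheet
hyperboloid, spherical segments and stacks, torus segments, catenoid), the
Delaunay comparison family, phase-diagram sweeps in (κ_T, g₀) and
(H_neck, g₀), pressure-sign classification, and stress-to-tension
estimates. It is written for quantitative biologists and biophysicists
modeling tissue growth on scaffolds, and for anyone studying geodesics of
constant normal curvature on surfaces of revolution.

## Worked example

```python
import fibersurf as fs

res = fs.solve_kappa(g0=0.6, mu0=35.0, R=1.0, L=1.25)
print(res.kappa_T, res.solution.H_neck, res.residual)
```

prints

```
-0.680904... -0.082614... 1.53e-13
```

the fiber curvature required to hold a neck of radius 0.6 with 35° fibers
(negative: the fibers *reduce* interior pressure, favoring growth), the
mean curvature at the neck, and the boundary residual |g(L/2) − R|. The
narrative scripts in `examples/` cover each capability — solving a shape
and verifying its geodesic/Clairaut invariants, comparing with Delaunay
surfaces, sweeping the phase diagram, pressure and tension estimates, and
OBJ mesh export with fiber paths. For instance
`python examples/pressure_estimates.py` prints

```
sigma_T =  2kPa, d = 10 um  ->  effective tension  20.0 mN/m
sigma_T =  5kPa, d = 10 um  ->  effective tension  50.0 mN/m
```

the equivalent surface tension of a contracting myofibroblast layer — one
to two orders of magnitude above bare tissue surface tension, which is why
the fibers control the shape. A thin CLI wraps the same library calls:

```
fibersurf solve --g0 0.6 --mu0 35 --out run
fibersurf sweep --mu0 0,35,58 --g0-min 0.4 --g0-max 1.1 --out sweep.csv
fibersurf pressure --d 10um --sigma 2kPa --rt 1mm
```

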