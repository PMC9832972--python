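# Methods

## The model

Growing microtissues remodel fast enough to behave as inviscid fluids: their
shape is set by the stress state of their surface. When that surface is a
thin layer of aligned contractile actin fibers rather than an isotropic
film, the classical Young–Laplace balance `p = -2 γ_s H` no longer applies.
Force balance on a fiber bound to the surface imposes two conditions
instead:

1. the fiber's principal normal must be colinear with the surface normal —
   the fiber has zero geodesic curvature, i.e. it follows a **geodesic**;
2. because the interior pressure is uniform and the fiber tension constant,
   the fiber's **normal curvature κ_T is constant** along its length, and
   the pressure it supports is `p = d σ_T / R_T` with `R_T = 1/κ_T`,
   layer thickness `d` and fiber stress `σ_T`.

For a surface of revolution `X(θ, z) = (g(z) cos θ, g(z) sin θ, z)` carrying
a fiber `θ = θ(z)` these conditions reduce to

```
g''  = (1 + g'²) / (g (K g² − 1)) · (1 − K κ_T g³ √(1 + g'²))
θ'   = (1/g) √((1 + g'²) / (K g² − 1))
```

with primes denoting d/dz. The θ equation is the classical geodesic
equation on a surface of revolution; the g equation enforces constant
normal curvature. `K = 1/(g₀² sin² μ₀)` is fixed by the neck radius `g₀`
and the fibril angle `μ₀` between fiber and meridian at the neck (z = 0).
Clairaut's relation `g(z) sin α(z) = g₀ sin μ₀` is an exact first integral
and is used both to report the local fiber angle α and as a conservation
check on every integration.

### Boundary-value problem

The bridge spans two coaxial disks: `g(±L/2) = R`, with symmetric solutions
`g(−z) = g(z)`, `θ(−z) = −θ(z)` and neck conditions `g(0) = g₀`,
`g'(0) = 0`, `θ(0) = 0`. Working in units of the disk radius, the default
geometry is `R = 1`, `L = 1.25` (half-length 0.625); these are config
values, not constants. All angles are degrees on the interfaces, radians
internally.

The solver fixes `(g₀, μ₀)` and shoots on κ_T: the residual `g(L/2) − R`
is scanned over a κ_T bracket (default [−20, 20], 97 points), every sign
change is polished by Brent iteration (κ tolerance 1e-12), and each
candidate is verified by a tight re-integration; converged roots keep the
boundary to better than 1e-8. All roots are reported and the smallest
|κ_T| is flagged primary — the families approach stacked-sphere limit
cases at positive κ_T, where multiple-root structure is expected. Where
integration fails inside a bracket (singular set, pinch-off, vertical
meridian) the residual is continued by a signed distance-to-failure
penalty so brackets spanning failure regions still resolve; a root is
accepted only if its own integration succeeds.

### Sign conventions

The outward normal points away from the axis. Mean curvature is
`H = (κ_meridian + κ_circumferential)/2` with `κ_meridian = −g''/(1+g'²)^{3/2}`,
so spheres have `H = +1/ρ`, catenoids `H = 0`, and at a neck
`H_neck = (1/g₀ − g''(0))/2`, evaluated through the ODE right-hand side
rather than finite differences. The signed fiber curvature is
`κ_T = −κ·(e_p·e_n)`: positive when the principal normal points into the
body, so spheres and barrels sit at κ_T > 0 (positive induced pressure)
and necked shapes at κ_T < 0. The printed Cartesian form of the fiber
equations orients the curvature the opposite way; the Cartesian integrator
maps `κ_cart = −κ_T` internally so that both routes trace the same curve.
Winding chirality is right-handed by default with a mirror flag; the model
is equally valid for both.

### Numerics

Integration uses `scipy.integrate.solve_ivp` with DOP853, rtol 1e-10 /
atol 1e-12, dense output, and terminal events for the three failure modes:
the singular set `K g² → 1` (the fiber turns tangent to a parallel circle),
pinch-off `g → 0`, and vertical meridians `|g'| → ∞`. The right-hand side
clamps wildly large trial-stage states; accepted steps never reach the
clamps because the events fire first. Profiles are stored on uniform grids
with analytic nodal derivatives (from the ODE itself) and C¹ cubic Hermite
interpolation between nodes; the meridian-fiber limit μ₀ = 0 is handled by
the degenerate form `g'' = −κ_T (1+g'²)^{3/2}` (circular meridian arcs —
torus segments), and μ₀ = 90° is excluded (the fiber degenerates to the
neck circle). Mirroring uses the exact symmetry rather than re-integration,
so outputs are symmetric to machine precision. The curve-frame utilities
accept analytic derivatives (machine-precision Frenet data for solver
output) or estimate them by spline when only points are given; straight
segments return zero curvature with an explicit undefined-frame flag.

### The Delaunay comparison family

The isotropic benchmark is the constant-mean-curvature surface of
revolution through the same boundary. It is solved by shooting on H with
the meridian in arc-length form `(g, z, φ)`, `dφ/ds = cos φ/g − 2H`, which
is robust through vertical tangents (nodoid branches); the profile is then
resampled as a z-graph with derivatives recovered from the exact first
integral `g/√(1+g'²) − H g² = B`, `B = g₀ − H g₀²`. The root of smallest
|H| is returned; along the boundary family this branch is continuous in
g₀ and passes through the catenoid (H = 0) at g₀ ≈ 0.704 and the sphere
(H = 1/ρ) at g₀ = ρ ≈ 1.179.

### Stacked spherical segments

Positive-κ_T families approach stacks of congruent spherical segments,
continuous but not differentiable at the joints. The two-segment stack is
parameterized by its joint radius g₀ (each sphere through `(g₀, 0)` and
`(R, L/2)`). For three segments, symmetry of the central segment about the
equator forces its sphere to be centered there, so `g₀ = ρ_segment` and the
family is `κ_T = 1/g₀` for g₀ ≥ R, with the joint height fixed by the outer
boundary; the single-sphere landmark lies on this curve. Equal segment
heights would over-constrain the three-segment family to a single point,
so congruence plus symmetry, with the joint height free, is the
construction used.

## Parameters that matter

| parameter | meaning | units | default |
|---|---|---|---|
| `R` | boundary disk radius | length scale | 1 |
| `L` | disk separation | units of R | 1.25 |
| `g0` | neck radius at z = 0 | units of R | — |
| `mu0` | fibril angle at the neck | degrees | — (experiments: ~30–40°) |
| `kappa_T` | fiber normal curvature | 1/R | solved by shooting |
| `d` | contractile layer thickness | m | 10 µm in estimates |
| `sigma_T` | fiber stress | Pa | 2–5 kPa in estimates |
| rtol/atol | integration tolerances | — | 1e-10 / 1e-12 |

## What the fixture generator emulates

`fixture_suite` produces the analytic shapes the theory names — sphere,
cylinder, hyperboloid, catenoid, torus segment, unduloid, nodoid, 2- and
3-sphere stacks — with randomized but valid parameters, as oracles: each
substitutes exactly into the governing equations with its known
`(μ₀, κ_T)` or `H`. These are idealized geometries. They contain none of
the features of real microtissue data — measurement noise, deviations
from axisymmetry, finite fiber length, partial alignment, or lateral load
transfer between fibers — so passing tests demonstrate correctness of the
mathematics and the solvers, not fit to any particular experiment.
Experimental `(H_neck, g₀)` points can be overlaid and classified via
`overlay_experiment`, but no measured coordinates ship with the package.

## Problem sizes

Default profile grids use 201 nodes per solution (801 for reference
shapes); shooting scans use 97 κ points (tests use 25–49 where a coarse
scan suffices); sweeps in the test suite cover a handful of angles on
0.1–0.15 g₀ steps. These sizes keep every quantity reported here well
inside its quoted tolerance while keeping the full suite fast; the
phase-diagram structure is insensitive to further refinement.

## Known limitations

* Only rotationally symmetric, z-graph meridians: nodoid-like fiber
  surfaces whose meridians fold back in z are treated as integration
  failures (vertical-meridian mode), consistent with the symmetric
  boundary-value families studied.
* Only symmetric solutions (`g(−z) = g(z)`) are sought.
* The light region between the two- and three-segment stack curves in the
  phase diagram is bounded here by its endpoint curves; the interior is
  not modeled.
* No time dependence: the model is purely geometric equilibrium; viscous
  tissue dynamics would require a different treatment.
* The units layer covers the pressure/length/tension dimensions used by
  the mechanics functions; it is not a general unit system.
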