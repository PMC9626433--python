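# Methods

`cerebrofsi` is a desk-scale, two-dimensional fluid–structure
interaction (FSI) pipeline for studying how atherosclerotic stenoses
alter the hemodynamics of an intracranial arterial bifurcation and of an
atherosclerotic saccular aneurysm.  Three scenarios are compared on a
common parametric geometry: a healthy bifurcation (INTACT), the same
artery occluded by three plaques (ICAS), and the stenosed bifurcation
carrying a saccular aneurysm at the flow divider (ACA).  The quantities of
interest are wall shear stress (WSS), velocity, pressure, and wall
displacement, compared across scenarios and against the 1–7 Pa
physiological WSS band for healthy arteries.

## Blood rheology

Blood is a shear-thinning yield-stress fluid, modelled with the
Herschel–Bulkley law

    eta(gamma') = kappa * gamma'^(n-1) + tau0 / gamma'

with consistency `kappa = 8.9721e-3 Pa s^n`, power-law index `n = 0.8601`,
yield stress `tau0 = 0.0175 Pa` and density `rho = 1020 kg/m^3`.  The raw
law diverges as the shear rate vanishes; a bi-viscosity regularization
freezes the viscosity below `gamma_min = 1e-3 1/s` (about 17.5 Pa s there,
~4400x the high-shear value).  At arterial shear rates (100–1000 1/s) the
yield term contributes less than 1%; it matters only in stagnation zones
and in the aneurysm sac.  A reference Newtonian viscosity of 0.004 Pa s
(the historical 0.04 g/(cm s)) is kept for Reynolds-number reporting.

The scalar shear rate is the second invariant `sqrt(2 e:e)` of the
symmetric rate-of-deformation tensor, frame-indifferent and zero for
rigid-body motion.

`channel_flow_oracle` provides the exact fully developed plane-channel
solution of the HB law (linear shear-stress profile, unyielded plug core,
velocity by integration of the constitutive law, mean velocity by
adaptive quadrature).  It is the independent reference for every flow
solver verification in the test suite.

### Reynolds number

With the nominal values (mean velocity 0.23 m/s, diameter 3.2 mm,
rho = 1020, mu = 0.004) the Reynolds number is ~188, comfortably laminar.
A value of 223 sometimes quoted for this configuration is not
recoverable from any combination of these parameters (plausible
combinations give 188–245); the package reports its own computed value.

## Arterial wall

The wall is an incompressible neo-Hookean membrane: strain energy
`W = C1 (I1 - 3)` with `C1 = 166 kPa` and exact incompressibility
(`D1 = 0`; the volumetric term `(J-1)^2 / D1` is dropped and `J = 1`
enforced; a sometimes-seen `C1 (I1 - 1)` variant would give nonzero
energy at the identity and is not used).  Uniaxial nominal
stress is `2 C1 (lambda - lambda^-2)`; the small-strain Young's modulus is
`6 C1` ~ 1 MPa.  Wall thickness is 125 um on the artery and 27 um on the
aneurysm sac, blended linearly over a 0.3 mm band across the neck.

Closed-form thin-wall equilibria anchor the membrane solver:

* **Tube** (axially tethered, plane strain): the Laplace balance in the
  deformed configuration reduces to
  `lambda = (mu / (mu - P R0/t0))^(1/4)`, `mu = 2 C1`; equilibrium exists
  only below `P = mu t0 / R0` (~25.9 kPa for the artery).
* **Sphere** (the sac): the classic balloon relation
  `P = 2 mu (t0/R0)(lambda^-1 - lambda^-7)` with its limit point at
  `lambda* = 7^(1/6) = 1.3831` and, for the sac parameters,
  `P_max = 4.44 kPa`.

### Discrete membrane

The structural half of the FSI loop is a 1D geometrically nonlinear
membrane along each wall curve.  Nodes displace along their reference
outward normals; segment tension follows the neo-Hookean law applied to
arc-length stretch, `T = T0 + 2 C1 t0 (lambda - lambda^-3)`; nodal
equilibrium balances the two adjacent tensions against the applied normal
traction (a discrete Young–Laplace balance).  The pressure load is a
follower load per *deformed* wall length — with a dead reference-length
load the inflated-circle solution is biased by exactly `1/lambda`, which a
convergence study against the tube closed form exposed; with the follower
load the discrete arc agrees with the closed form to 4e-5 relative.
Inlet/outlet end nodes are clamped.  A damped Newton iteration with a
tridiagonal finite-difference Jacobian solves the balance; the flat
unstressed membrane has a singular tangent at zero displacement, so the
iteration starts from a small load-aligned bump.  In the rigid limit
(`C1 = 1e12 Pa`) tension differences cancel catastrophically in floating
point, so a stagnated iterate is accepted once the residual is below 1e-6
of the load scale (the default tolerance is 1e-12).

### Prestress convention

The imaged in-vivo geometry is already loaded: 16 kPa on the stress-free
sac exceeds its 4.4 kPa limit point, so no stress-free reference can carry
the physiological load.  The pipeline therefore treats the built geometry
as the equilibrium under the uniform reference pressure (16 kPa ~
120 mmHg, the inlet datum) minus the perivascular pressure (default 0, a
config knob — the study never states it).  The wall carries the Laplace
pre-tension `T0 = (p_ref - p_ext) R_eff` (local half-width of the channel,
or the sac radius) and responds to the *anomaly* of the flow load: local
pressure plus viscous traction minus the inlet-mean pressure.  Reported
displacements are relative to that in-vivo datum, which is the only
convention consistent with the small (0.05–0.2 mm) displacements the
study discusses.

A consequence worth stating explicitly: on a *straight* prestressed wall
the transverse stiffness is the pre-tension, not the material — a
tensioned membrane sags by `q L^2 / (8 T0)` regardless of `C1`, and a flat
*stress-free* membrane stiffens only as `C1^(1/3)`.  Displacement vanishes
in the rigid-material limit only on curved walls, where it scales as
`q R^2 / (8 C1 t0)`.  The rigid-limit verification therefore runs on a
curved (annular) vessel segment with `prestress=False`, where
`C1 = 1e12 Pa` gives displacements below 1e-9 m.

## Scenario geometry

All geometry is parametric and deterministic.  The flow-divider apex sits
at the origin, the parent artery (diameter 3.2 mm, length 12 mm) runs
along −x, and the daughters (diameter 2 mm, length 10 mm) leave at ±50°
— the bifurcation angle, plaque placement and sac neck width have no
single canonical value, so the defaults are explicit package choices: a 100° total opening typical of intracranial bifurcations;
plaques of cosine profile, 1.6 mm long, degree 0.5, one in the parent
4.8 mm upstream of the centerline junction and one per daughter 3 mm
downstream; a 2.2 mm sac neck.  Branch lengths are chosen so the flow is
developed at Re ~ 190 before reaching the junction.

Each plaque inset follows `(degree*w/2)(1 + cos(2 pi (s-c)/L))/2`, C1-
continuous, applied symmetrically to both walls so the throat width is
`(1 - degree) * w` (a one-sided variant is available per plaque).  The
aneurysm replaces the apex: the inner walls are cut where their separation
equals the neck width, short neck segments run to the chord of a circular
arc of radius 2.5 mm, and the chord position is pushed outward just far
enough that the sac circle clears the daughter walls (preventing the
self-intersection that a chord at the cut points would cause).  The sac
vertex lies on the symmetry axis, about `neck offset + 2 R` beyond the
apex.

Meshing: the outline is sampled at the mesh size (default 0.2 mm, i.e. 16
elements across the parent), the interior is seeded with a triangular
lattice clipped away from the boundary, and a Delaunay triangulation is
filtered to the polygon with a conformity check (missing boundary edges
trigger midpoint refinement and a retry).  Interior nodes are Laplacian-
smoothed with an inversion guard.  Symmetric specs produce exactly
mirror-symmetric outlines because the lower half is built by sign-flipping
the upper half.  Everything is byte-reproducible; `seed` is carried in the
spec for the determinism contract but no stochastic choice currently
consumes it.

Target points snap to the nearest wall node: the bifurcation apex for
INTACT/ICAS, the sac vertex for ACA — the two measurement locations of the
comparative study.

## Flow solver

Steady incompressible generalized-Newtonian Navier–Stokes, discretized
with equal-order P1–P1 triangles and SUPG/PSPG stabilization
(`tau = [(2|u|/h)^2 + (4 nu/h^2)^2]^(-1/2)`, unit scale factor).  The
viscous term is assembled in gradient form: its natural outflow condition
`eta du/dn - p n = -p_out n` is exact for developed channel flow, and for
unidirectional flows the gradient and symmetric-stress forms coincide.

Boundary conditions: parabolic inlet velocity (peak 1.5x mean, nodal
values rescaled so the P1 interpolant carries exactly `mean x width` of
flux), no-slip walls, and 4 kPa prescribed as the natural condition on
both outlets.  The study's inlet is over-specified (both 0.3 m/s and
16 kPa); a well-posed incompressible problem admits one inlet condition,
so the velocity is imposed — the stated mean 0.23 m/s, whose 2D parabolic
peak is 0.345 m/s, close to the quoted 0.3 m/s — and 16 kPa enters only
as the wall prestress datum above.

The nonlinearity is resolved by a layered fixed-point strategy:

1. **Lagged viscosity, damped in log space** (60% new / 40% old):
   near-yield elements otherwise toggle across the bi-viscosity cap and
   sustain a limit cycle.
2. **Aitken dynamic relaxation** of the velocity iterate (clamped to
   [0.05, 1.2]), which damps the slowly oscillating modes of
   recirculating flow.
3. **A Newton phase** once the iterate is close (relative change below
   3e-3): the convection is linearized about the iterate and the
   viscosity derivative `d eta/d gamma` enters as a rank-one element
   update, clipped at −0.9 eta/gamma so the tangent stays positive
   definite across the yield plateau.  If the residual grows, the solver
   falls back to the Picard path.
4. In the creeping near-yield regime (solve Reynolds number < 20, i.e.
   the start of the inflow ramp) the accelerations are disabled: the
   plain damped Picard map is stable there, whereas extrapolation
   amplifies plug-boundary flicker.

Convergence is declared when the relative velocity change drops below
1e-8, measured against `max(|u|, 0.05 * nominal full-inflow norm)` so
that near-rest ramp states (whose own norm is round-off of the pressure
solve) register as converged.  The iteration cap is 150; the aneurysm
scenario genuinely needs ~75 iterations, which is why the cap is three
times the 50 an early design assumed.  Each linearized saddle system is
solved with a sparse LU factorization (about 10k unknowns at the default
mesh, well within a single-core budget).

The quasi-steady startup ramp (`ramp_series`) raises the inlet mean from
0 to its value over 0.1 s with a smooth sin^2 schedule, one steady solve
per step (50 by default), warm-started from the previous step.  The ramp
is the quasi-static stand-in for a short flow-onset transient; its intermediate
near-rest states barely yield the fluid and their Picard map stalls at a
plateau (plug-boundary flicker, up to ~1e-4 of the full-inflow norm), so
they are accepted at a proportionate 5e-4 tolerance while the final
full-inflow state is held to the strict 1e-8.

Verification (all in the test suite, against `channel_flow_oracle`):
Newtonian channel velocity L2 error 0.2% and WSS within 1.4% at the
default mesh; HB channel with the developed inlet profile within 1% (WSS)
and 0.3% (velocity); discrete mass conservation to ~1e-12 (summing the
PSPG continuity rows telescopes to the boundary flux); observed
convergence order >= 1.5 under refinement; solutions equivariant under a
30° rotation of the whole configuration to 1e-8.

One subtlety the oracle comparisons exposed: at Re ~ 190 a parabolic
inlet needs ~30 mm to relax to the flatter HB developed profile — longer
than the vessel.  Oracle comparisons therefore impose the developed
profile at the inlet (`inlet_values`); the scenario runs keep the
parabolic inlet of the study.

## Partitioned FSI

Quasi-static partitioned coupling replaces a full ALE formulation: the
reference solution is steady, so the ALE time terms vanish and mesh
motion reduces to morphing.  Each outer iteration solves the flow on the
current mesh, extracts the interface traction
`(-p I + 2 eta e) . n` (recovered gradients, local effective viscosity),
feeds the normal-load anomaly to the membrane, under-relaxes the
interface displacement (Aitken, clamped [0.1, 1], initial 0.5), and
morphs the mesh (wall nodes along their normals, interior by harmonic
extension of the boundary displacement; inversion is an error, as is any
displacement beyond 10% of the local width).  Convergence: maximum
displacement increment below 1e-7 m, two orders below the micron-scale
signals.  All three default scenarios converge in 4 outer iterations.

## WSS extraction and summaries

Velocity gradients at wall nodes are recovered by least-squares quadratic
fits over each node's topological 2-ring (3-ring for small patches) —
exact for quadratic fields, hence exact for sampled Poiseuille flow, and
immune to reaching across thin solid wedges (the patch is topological,
not metric).  WSS is the tangential part of `2 eta e . n` with the local
converged effective viscosity (consistent with the momentum equation; the
constant reference viscosity would misstate shear-thinned near-wall
stress by ~15%).  Tangentiality is asserted to round-off on every field.

Wall-wide medians are weighted by adjacent wall-edge length so they are
stable under refinement.  Target-point series sample nodal values exactly
(no interpolation); displacement series come from one-way membrane
responses along the ramp, with the fully coupled solve providing the
final state.

The cross-scenario report records per scenario the wall max/median WSS,
target-point WSS, peak velocity and pressure, and max/median displacement,
plus three ordering flags: `peak_wss_icas_ge_intact`,
`peak_wss_aca_ge_icas`, and `stenosed_peak_ge_2x_reference` (reference =
the intact model's median, i.e. developed-parent, WSS).

## Problem sizes

Default meshes: ~2200–2900 nodes (0.2 mm resolution).  The steady intact
solve takes seconds; the full three-scenario pipeline (51-step ramps,
coupled FSI, extraction) runs in minutes on one core.  These sizes are
the package's reference configuration; refinement studies in the tests
use 2x finer meshes.

## Known limitations

* **2D midplane reduction.**  All fields are per unit depth; peak values
  are mesh- and corner-sensitive and are interpreted as band/ordering
  comparisons, never as point predictions of 3D values.  Full 3D
  simulations of comparable configurations report peak WSS around
  19–25 Pa and wall displacements of 0.05–0.2 mm; such values hinge on
  geometric details (stenosis degrees, bifurcation angle, neck shape)
  that a midplane model cannot pin down, and are out of reach here by
  construction.
* **Peak WSS values are corner- and mesh-sensitive.**  The scenario peaks
  live at near-singular features — the flow-divider impingement zone
  (stenosed model) and the sac neck lip where the stenotic jet skims the
  opening (aneurysm model) — whose shear layers are one or two elements
  wide at the default resolution.  Across mesh variants the measured peaks
  move by tens of percent (e.g. the aneurysm peak spans ~5–10 Pa) even
  though their *ordering* (aneurysm > stenosed > intact, and stenosed peak
  more than double the healthy reference) is reproduced at the default
  study conditions.  The ordering flags are therefore qualitative checks,
  and no peak value should be read as a point prediction.
* **Steady laminar flow only.**  No pulsatile waveform, no turbulence or
  transition model, no oscillatory shear indices (they require a cardiac
  cycle).
* **Membrane wall.**  No bending stiffness, no axial displacement, no
  anisotropy or viscoelasticity; the 1D curvilinear membrane has no hoop
  direction, so straight-wall compliance is pre-tension dominated (see
  the prestress discussion).
* **Synthetic geometry.**  The generator emulates nominal morphometric
  dimensions and an idealized plaque/sac layout, not patient anatomy: branches are
  straight, plaques are smooth cosine bumps, the sac is a circular arc.
  Passing tests demonstrate correctness of the numerics and the stated
  qualitative physics on this idealized family, not predictive accuracy
  for real vessels.
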