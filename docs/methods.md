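# Methods

`stentbench` simulates the four standard mechanical bench tests applied to
bioresorbable polymer vascular scaffolds — radial compression (crimping),
inflation, three-point bending and two-plate crush — with an implicit
nonlinear finite-element solver whose material law is driven directly by
families of measured uniaxial stress–strain curves.  This note records the
model, its assumptions, the numerical choices, and what the synthetic test
conditions do and do not establish.

Units are mm, MPa, N and s throughout.

## Constitutive model

PLLA (poly-L-lactic acid) is elasto-visco-plastic: its uniaxial true-stress
response increases with strain rate and decreases with temperature.  Rather
than fitting a parametric plasticity model, the solver interpolates the
measured multilinear curves directly.

At every Gauss point the scalar state is the von Mises equivalent stress

    σ̄ = √(½[(σ₁₁−σ₂₂)² + (σ₂₂−σ₃₃)² + (σ₃₃−σ₁₁)² + 6(σ₁₂²+σ₂₃²+σ₃₁²)])

and the equivalent strain

    ē = [⅔(e₁₁²+e₂₂²+e₃₃²) + ⅓(γ₁₂²+γ₂₃²+γ₃₁²)]^½ ,

with engineering shears γ.  Internally the curve-lookup strain applies this
measure to the deviatoric part of the accumulated strain tensor (the
uniaxial experimental abscissa maps onto 3D states under the plastic
incompressibility assumption; the two coincide for traceless tensors).

A load step updates the stress in five stages:

1. the tangent modulus `E_T` is the local slope of the interpolated
   equivalent curve at the previous equivalent strain, and the isotropic
   tangent matrix `C^E` is built from `(E_T, ν)`;
2. a trial stress `σ_trial = σ_t + C^E Δe` is formed;
3. the target equivalent stress at the updated equivalent strain is read
   from the curve family and the stress ratio
   `r = σ̄_target / σ̄(σ_trial)` evaluated (guarded to 1 when the trial
   equivalent stress vanishes);
4. the final stress is the radially scaled trial stress `r σ_trial`;
5. the scaled tangent `r C^E` is exported for assembly.

The elastic/plastic split `Δe = Δe^E + Δe^P` with
`Δe^E = C(E₀)⁻¹ (σ_final − σ_t)` uses the *initial* elastic modulus: on the
hardening plateau the tangent modulus would classify nearly all deformation
as elastic, which is not the physical split.  The decomposition is exact by
construction.

**Elastic consistency.**  `C^E` is built with shear modulus `G = E_T/3`, so
the elastic identity `σ̄ = 3 G ē` holds for *any* strain state and the
stress ratio is exactly 1 throughout the elastic segment — no plastic strain
accumulates there and an elastic reversal retraces the loading line exactly.
A matrix with Young's modulus `E_T` would give `r = 2(1+ν)/3 ≠ 1` and a
spurious plastic drift.  The Poisson ratio ν (default 0.30, typical for
PLLA) sets only the volumetric stiffness; it is not reported with the curve
data and is configurable.

**Rate and temperature interpolation.**  Curves are stored on a full
(temperature × strain-rate) grid — by default {25, 37, 48 °C} ×
{0.001, 0.01, 0.1 s⁻¹}.  Lookup interpolates linearly in rate between the
bracketing curves at each bracketing temperature, then linearly in
temperature.  Below the lowest tested rate the stress scales proportionally
with rate (`σ = (ė/ė_min) σ_min`); above the highest it extrapolates
linearly from the two highest-rate curves.  Both branches are continuous
with the interior interpolation at the bounds.  Temperatures outside the
grid are clamped — no extrapolation rule exists for temperature.
The proportional low-rate rule sends stress to zero as the rate vanishes;
it is implemented as specified, and the protocols therefore evaluate the
material at a *nominal rate class* (default 0.01 s⁻¹, configurable)
rather than at the per-increment rate `|Δē|/dt`, which at quasi-static
bench speeds would spuriously relax barely-straining Gauss points.  The
single-point driver uses the per-increment rate.

**Phases.**  Each Gauss point is in one of three phases.  *Loading* follows
the rate/temperature envelope.  When the equivalent strain drops, the point
enters *unloading* on an anchored hysteresis branch running from the
reversal point `(ē_rev, σ̄_rev)` down to zero stress at the residual strain,
which is taken as the equivalent plastic strain at reversal — this gives an
exact elastic retrace (zero residual) for pre-yield reversals and a strictly
positive residual after yield.  The branch shape comes from the family's
unloading curves (normalised and interpolated across rate and temperature
like the loading curves); a linear branch is the fallback when no unloading
data are provided.  *Reloading* retraces the branch back to the reversal
anchor and rejoins the loading envelope there.  Driving the strain below the
residual holds the stress at zero; compressive re-yielding below the
residual is not modelled.

## Finite elements and solver

8-node trilinear hexahedra with full 2×2×2 Gauss quadrature (no reduced
integration, hence no hourglassing).  The scheme is updated-Lagrangian and
incremental: each step builds the strain-displacement operators on the
geometry committed at the start of the step and accumulates small strain
increments tensorially, so the accumulated measure approximates true
(logarithmic) strain when per-step increments stay small (protocols keep
them around 1–2%).  Geometric stiffness is not assembled (modified Newton
with the material-scaled tangent only).

The incremental balance is

    (M/Δt² + K) ΔU = F_ext − F_int − (1/Δt²) M (U⁽ⁱ⁻¹⁾ − Uᵗ) ,

quasi-static by default (`M = 0`).  Two regularisations are available:

* **Tikhonov stabilisation** (`stabilization`, default 1e-6 of the mean
  stiffness diagonal in protocols): matrix-only, never enters the residual,
  so converged equilibria are unchanged; it fixes the zero-energy modes that
  frictionless contact leaves (e.g. rotation about the stent axis inside a
  crimping sleeve).
* **Scaled-mass dynamic regularisation** (`dynamic_reg`): a lumped mass
  term sized as a fraction of the mean stiffness diagonal that enters both
  matrix and residual.  Scaffold patterns snap-buckle during deep crimping
  and during re-expansion of a folded state; a quasi-static iteration
  cannot traverse these limit points, and the mass term carries the
  solution through on a quasi-dynamic path.  The inertia bias it adds is
  proportional to the per-step displacement increment and vanishes as steps
  are refined.  Defaults: 0.15 for crimping, 0.05 for the other tests; all
  elastic verification problems (patch test, pressurised tube, beam and
  ring oracles) run with it off.

Newton iteration uses the radially scaled material tangent (floored at 5%
of the elastic matrix so fully unloaded Gauss points do not create
zero-stiffness regions — the floor affects only the iteration matrix, never
the converged stress), a lagged LU factorisation (rebuilt on residual
rises, contact-set drift, phase freezing or every 8 iterations), adaptive
under-relaxation (an update level that produced a residual rise is not
returned to within the step), near-convergence freezing of the
material-phase assignments, and a stiff (initial-modulus) tangent for
Gauss points whose phase keeps flipping between iterations — assembling
the soft envelope slope for a point that may unload makes the iteration
non-contractive, since its one-sided stiffness in the unloading direction
is the elastic one.  Convergence requires the free-DOF residual norm to
fall below `newton_tol` (default 1e-5; the desk-scale design studies relax
it to 1e-3 of the load scale) times the force scale
`max(‖F_ext + F_contact‖, ‖F_int‖)`.  A step that fails to converge — or
converges onto a geometry with inverted elements — is rejected and bisected
by the protocol driver (up to 4 levels).  Committed steps always satisfy
their configured tolerance.

## Contact

Rigid tools are analytic surfaces: the crimping sleeve (inner cylinder
surface), the expansion mandrel and the bending rollers (outer cylinder
surfaces) and the crush plates (half-spaces).  Whenever a surface node
penetrates a tool, a one-dimensional elastic support element (penalty
spring along the tool normal) is generated; it adds `k d dᵀ` to the
stiffness and `−k·gap·d` to the residual.  Springs are regenerated every
iteration of every step.  The tool reaction is the exact negative sum of
the nodal spring forces (action–reaction to machine precision by
construction).

The penalty force is regularised near zero penetration: below a smoothing
depth `g₀` (default half the penetration tolerance, i.e. 5e-4 mm) the force
ramps quadratically, beyond it linearly with stiffness `k`.  This removes
the on/off flapping of barely-touching nodes.  The default per-node
stiffness is `20 E₀ h` (initial modulus × characteristic element size),
which keeps converged penetrations well below the 1e-3 mm tolerance while
remaining well-conditioned; doubling it shifts desk-scale load–radius
curves by well under 1%.  Contact is frictionless and normal-only; there is
no self-contact between struts, so deeply folded configurations overlap
instead of stacking.

## Geometry

The commercial scaffolds' crown/connector patterns are proprietary; the
generator reproduces the *parameters* the design comparisons sweep — radii,
length, wall thickness, strut width, pocket slots — on a generic pattern:
sinusoidal zig-zag rings (amplitude chosen so crown tips touch the stent
ends) joined by straight axial connectors placed at sinusoid zeros.  The
pattern is carved from a structured cylindrical hex grid by keeping cells
whose (θ, z) centre lies inside the strut bands (slope-corrected so the
width perpendicular to the centreline is the nominal strut width).  This
keeps the mesh conforming and all-hex by construction, makes scale
invariance and the cylindrical envelope exact, and lets slot variants be
produced by deleting through-wall element blocks from an otherwise
identical mesh.  The carved pattern must form a single face-connected
component; a slot that severs a strut raises an error.  Pattern resolution
is referenced to the inner radius, so designs differing only in wall
thickness share identical connectivity.

Preset designs carry the published envelope dimensions (outer/inner radius,
length, wall thickness 0.160 vs 0.130 mm for the two thickness variants;
0.184 mm strut width and 15.68 mm length for the slot pair).  Strut width
for the thickness pair and the slot dimensions are not published; the
presets use 0.19 mm and slots of half the strut width × 0.5 mm placed at
connector midpoints — fixed once, as these comparisons are parameter sweeps
on a common pattern, not reproductions of the proprietary lattice.
Published element counts of the proprietary meshes are treated as context,
not targets.

## Bench protocols

All four tests share: temperature 37 °C (the clinically relevant bath
condition), nominal material rate class 0.01 s⁻¹ (the middle tested rate —
the bench machines move slowly), linear tool schedules, per-step history
records (tool position, reaction, radii, stress extremes), and adaptive
bisection of failed steps.  Compressive tool reactions are reported
positive.  Protocol chains carry the full converged state — displacements,
stresses, plastic strains, phase anchors — bit-for-bit into the next test.

* **Radial compression**: a coaxial rigid sleeve closes linearly onto the
  scaffold (axial fixation u_Z = 0 at one end); the summed normal contact
  force is the radial crimping load.
* **Inflation**: either a follower pressure on the inner faces (ramped
  until the mean inner radius reaches the target or the pressure cap) or an
  expanding rigid internal mandrel (the cylinder-based bench arrangement).
  When initialised from a crimp result, the crimping sleeve is first opened
  gradually — removing it in one step releases the entire recoil at once,
  which the equilibrium iteration cannot absorb.  With `release=True` the
  load is removed afterwards and the radial recoil fraction
  (spring-back / loaded radius) reported.
* **Three-point bending**: two fixed rollers below, one driven roller at
  mid-span, axes along X; symmetry conditions u_X = 0 on YZ-plane nodes and
  u_Z = 0 on XY-plane nodes (node sets captured within ~half a cell of the
  planes).  The flexibility metric is the secant stiffness of the
  load–deflection record.
* **Two-plate crush**: the plates close symmetrically by half the travel
  each — mechanically identical to a fixed bottom plate, and consistent
  with the u_Y = 0 mid-plane symmetry condition — until the diameter
  reduction exceeds the target fraction; u_Z = 0 at one end plus the two
  symmetry planes.  A force-controlled mode drives the plates by a secant
  iteration on their position.

Chained tests (bending/crush after inflation) first ramp the prior test's
remaining load down gradually before their own tools engage, for the same
reason the crimp sleeve is opened gradually.

`compare_designs` tabulates peak and 99th-percentile effective stress,
plastic strain and the load metrics across designs run under identical
protocols, and flags the design with the higher stress concentration.  The
99th percentile is used for "better stress distribution" statements because
the raw peak sits on re-entrant pattern corners and is mesh-noise-prone.

## Synthetic test conditions (and what they do not show)

The synthetic curve family emulates the qualitative shape of measured PLLA
data: initial modulus 3000 MPa and yield 60 MPa (at 2% strain) at the
25 °C / 0.01 s⁻¹ reference, hardening 40 MPa, +8% stress per rate decade,
−0.8% per °C, knots to 30% strain, and power-law unloading branches whose
initial slope equals the elastic modulus (curvature exponent 1.5).  These
are representative magnitudes for the polymer class, not measurements of
any proprietary material, so test outcomes validate the *machinery* —
interpolation, phase logic, contact, protocol orchestration and the
direction of design effects — not absolute forces or stresses of a real
device.

Desk-scale studies run on miniature scaffolds (two rings, four crowns,
outer radius 1.6 mm, ~600–1400 elements; the thickness pair at walls
0.160/0.130 mm, the slot pair at identical three-cell strut density with a
one-cell-wide slot per connector).  The thickness comparison crimps to 60%
of the initial radius; the slot-pair crimp comparison to 72% (the finer
slot-capable mesh resolves more buckling modes than the quasi-static
solver can fold through at full depth).  The inflation, bending and crush
comparisons start from the as-designed geometry — re-expanding a fully
folded miniature pattern traverses snap-through cascades beyond what the
solver tracks, and these comparison statements do not depend on the crimp
prior; crimp-state carry-over into inflation (gradual sleeve opening, then
loading) is exercised separately.  The generic carved pattern has closed,
hoop-stiff rings that expand by membrane stretching rather than crown
opening, so the inflation comparison uses a few-MPa pressure cap to reach
meaningful wall stresses.  Real scaffolds differ in pattern, size, element
budget and material: the desk runs reproduce the *qualitative* design
findings (thinner struts concentrate crimp stress; slots relieve crimp
stress concentrations but barely affect the other tests), not the published
stress magnitudes.

## Numerical parameters (defaults)

| parameter | default | notes |
|---|---|---|
| Poisson ratio ν | 0.30 | volumetric stiffness only; not in the curve data |
| Newton tolerance | 1e-5 (protocols) | relative to the force scale |
| max iterations | 200 | with lagged LU + under-relaxation |
| penalty stiffness | 20 E₀ h | per contact node |
| penetration tolerance | 1e-3 mm | checked on every committed step |
| contact smoothing g₀ | 5e-4 mm | quadratic force ramp depth |
| stabilization | 1e-6 | matrix-only Tikhonov (protocols) |
| dynamic_reg | 0.15 crimp / 0.05 others | scaled-mass term |
| mesh density | 2 through wall, 2–4 across strut | desk default |
| nominal rate class | 0.01 s⁻¹ | curve lookup rate in protocols |
| temperature | 37 °C | clinical bath condition |

## Known limitations

* No self-contact, friction, balloon membrane, vessel/plaque interaction,
  degradation kinetics, anisotropy, or viscoelastic creep/relaxation.
* Radial stress-ratio scaling inherits the source model's character: the
  stress *direction* follows the trial elastic predictor, not an associated
  flow rule; cyclic behaviour below the residual strain is truncated at
  zero stress.
* No geometric stiffness: stability limit points are traversed with the
  scaled-mass term rather than arc-length continuation, so reaction curves
  through a snap carry a small rate-of-stepping bias.
* The voxel-carved pattern has stair-stepped strut edges at desk density;
  peak stresses sit on these corners, which is why distribution comparisons
  use the 99th percentile.
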