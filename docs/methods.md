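# Methods

This note documents the modelling choices behind `kneesquat`: what is
simulated, the defaults and their units, the numerics, and what the synthetic
geometry does and does not capture.

## The simulated experiment

A weight-bearing squat of a left leg fitted with a cruciate-retaining knee
prosthesis, in a rig configuration: the ankle is a fixed spherical joint at
the origin (translations locked, rotations free), the femoral head slides on
the vertical axis, and the squat is driven by prescribing the hip drop in 30
equal load steps from 0 to 150 mm. The quadriceps (vastus intermedius) force
is the control input: after each load step the vertical ankle reaction is
measured, and the step is re-solved with an adapted quadriceps force until
that reaction lies in the 50–55 N band. Three scenarios are compared under
otherwise identical conditions: an unreleased PCL, and PCL stiffness scaled
to 50 % and 25 % ("50 % and 75 % release"). The run stops once knee flexion
exceeds 73°, because the model does not include quadriceps-tendon–femur
wrapping, which would engage above that angle.

"Quasi-static" is meant literally: each load step is an independent
equilibrium (no inertia, no damping); the sequence of steps provides the
loading history that friction and the controller warm starts act on.

## Bodies, frames, units

Units are mm, N, MPa (N/mm² = MPa) and degrees in reported metrics. The
global frame is right-handed with z superior, x mediolateral (the flexion
axis, +x lateral) and y anterior; origin at the ankle. Body frames: tibia
(origin at the ankle), femur (origin at the knee centre, i.e. the midpoint of
the condylar arc centres), patella (origin at its centre, posterior facet
towards −y). AP translation is reported with "tibia moves anterior" positive;
internal rotation with the tibial tuberosity moving medially positive.

## Tissue models

**Ligaments** are straight-line tension-only springs, one per bundle: LCL,
MCL anterior/oblique/deep, PCL anterior/posterior, plus the patellar tendon.
Default stiffnesses (N/mm) and reference strains at the 15° pose:

| bundle | k (N/mm) | ε_ref |
| --- | --- | --- |
| LCL | 91.3 | 0.02 |
| MCL anterior | 27.9 | 0.02 |
| MCL oblique | 21.1 | 0.02 |
| MCL deep | 72.2 | 0.02 |
| PCL anterior | 125.0 | −0.10 |
| PCL posterior | 60.0 | −0.02 |

Strain is engineering strain relative to the slack length,
ε = (L − L0)/L0, so the slack length is calibrated as L0 = L_ref/(1 + ε_ref)
from the origin–insertion distance at the 15° reference pose; a negative
reference strain means the bundle is slack there (both PCL bundles only
engage in deeper flexion). A PCL release scales stiffness only — slack
lengths are untouched. The patellar tendon, whose properties are not part of
the ligament table, is a stiff tension-only spring (2000 N/mm, zero reference
strain at 15°); this is a repo constant. No toe region, no viscoelasticity,
no wrapping.

**Muscles** are constant-preload actuators: vastus lateralis and medialis
20 N each, two hamstrings 10 N each, and the controllable vastus intermedius
(initial 21 N). The preload rides on a 0.001 N/mm spring whose only role is
to keep the line of action defined while the muscle path lengthens over the
squat; the delivered force therefore stays within F0 ± 0.001·|ΔL| — about
±0.05 N over a 50 mm excursion.

## Contact

Both articulations use an elastic-foundation (bed-of-springs) model on the
deformable side: per patch, p = k_f · max(0, −gap), with the foundation
modulus derived as the constrained-column stiffness of the layer,
k_f = E(1−ν)/((1+ν)(1−2ν)·h):

* PE inlay: E = 312.5 MPa, ν = 0.46, layer h = 8 mm → k_f ≈ 180.6 MPa/mm;
* retropatellar cartilage: E = 5.0 MPa, ν = 0.46, h = 3 mm → k_f ≈ 7.7 MPa/mm.

The femoral component (CoCr, E = 217 000 MPa) is rigid; inside the solver it
is an analytic signed-distance surface (two torus condyles for the
tibiofemoral joint; a grooved cylindrical trochlear flange for the
patellofemoral joint), which keeps every energy evaluation closed-form.
Triangle-mesh rigid surfaces are supported through a ray-cast gap query for
user-supplied STL geometry.

Friction is regularized Coulomb, t = −μ·p·v/(|v| + ε_v) with
ε_v = 0.1 mm/step, μ = 0.05 femorotibial and 0.02 patellofemoral; the cone
bound |t| ≤ μp holds patch-wise by construction. Because friction is
non-conservative it enters the equilibrium through a fixed-point outer
iteration: tractions computed from the slip since the previous converged step
are applied as constant generalized forces and the energy re-minimized
(2 iterations by default). A small slip-history dependence of frictional
equilibria is inherent to Coulomb friction and is why the warm-start
uniqueness check is run frictionless.

The surface "von Mises" proxy maps contact pressure through the
confined-layer factor (1−2ν)/(1−ν) (≈ 0.148 at ν = 0.46): a laterally
constrained layer under pressure p carries σ = diag(p, ηp, ηp) with
η = ν/(1−ν). The factor is a documented proportionality constant; the
quantities of scientific interest are trends across scenarios and flexion,
not absolute magnitudes (the volumetric stress field is available from the
FE module).

## Synthetic geometry

No subject anatomy is used. The geometry is parametric, chosen once to be
physiological and then frozen:

* femoral condyles: torus patches, sagittal radius 30 mm, frontal 20 mm,
  centres 44 mm apart; epicondylar width 80 mm;
* inlay: two biradial dished troughs — tight mediolateral conformity
  (frontal radius 22 mm, which centres the condyles and carries
  varus/valgus) and low sagittal conformity (AP radius 250 mm, which lets the
  femur translate AP as fixed-bearing inlays do), with the 3° posterior slope
  applied as a rotation about the mediolateral axis;
* trochlea: cylinder of the condylar sagittal radius with a shallow
  parabolic groove (100 mm) centring the patella; the retropatellar facet is
  biradial (30 mm mediolateral, 70 mm proximodistal) so curvature mismatch
  gives the patella spin stiffness;
* segment lengths 400 mm each, so the 150 mm hip drop from the 15° pose ends
  near 73° flexion;
* attachment coordinates are repo constants loosely following
  anatomical-landmark descriptions; the quadriceps origins sit anterior of
  the femoral shaft so the extensor mechanism acts as a frictionless pulley
  over the trochlea without needing tendon-bone wrapping below the 73° cap.

What this emulates well: the closed-chain squat kinematics, the
band-controlled load transfer, PCL recruitment with flexion, and the
*directions* of the release effects (anterior translation, deep-flexion
inlay stress and collateral loads all fall as the PCL is released, while the
extensor chain is nearly unaffected). What it does not: subject-specific
magnitudes (AP translations, stress values in MPa, quadriceps forces are all
geometry-dependent and not comparable to any individual knee); geometric
femoral rollback (the condylar sagittal radius is constant, so early-flexion
AP motion is force- not shape-driven); and internal rotation, which is only
weakly constrained — ball-shaped condyles in shallow troughs provide little
yaw stiffness and no eminence/post is modelled, so absolute internal-rotation
angles (several degrees) are larger and noisier than in a real TKA, and they
are the main reason the cross-scenario quadriceps-force agreement is a few
percent rather than sub-percent: releasing the PCL shifts the yaw equilibrium
slightly, which feeds back into the GRF plant at matched quadriceps force.
Passing trend tests therefore support the release *orderings*; they say
nothing about magnitudes in real knees.

## Solver numerics

Equilibrium minimizes the total potential energy over 11 DOFs (tibia
rotations ×3, femoral flexion + varus/valgus, patella pose ×6) with exact
analytic gradients (rotation increments via the SO(3) exponential map and its
right Jacobian). Rotational DOFs are scaled by 1/400 mm so every gradient
component is an equivalent force in N at a 400 mm lever; the residual
contract is the max-norm of that scaled gradient < 1e-3 N (default,
configurable). The pipeline per step:

1. closed-chain kinematic warm-start prediction (splits the extra flexion
   implied by the new drop between the segment tilts and carries the patella
   with the femur) — this keeps even coarse schedules on the flexed branch of
   the energy landscape;
2. diagonally preconditioned L-BFGS (per-DOF inverse-sqrt curvature from a
   finite-difference Hessian diagonal), up to 4 restarts × 200 iterations;
3. damped Newton polish on the 11×11 finite-difference Hessian of the
   analytic gradient, with eigenvalue clamping for the soft patellar modes —
   this routinely drives residuals to 1e-8…1e-10 N, which is what makes
   warm-start independence hold to better than 1e-4 mm.

Ties/multistability: a seeded start perturbation is available
(`perturbation_seed`, off by default) for exactly symmetric configurations;
the ground reaction force is obtained by direct force bookkeeping on the
tibia (springs + contact + friction), and the whole-system balance
(ankle + hip reactions + patella residual = 0) holds to machine precision at
every step.

## Controller

Bracketed bisection on the quadriceps force towards the band midpoint,
geometric bracket expansion (factor 2), band endpoints inclusive, budget 50
restarts per step. An in-band first solve is accepted unchanged. The starting
force per step derives from the previous step's converged value; by default a
secant correction towards the band midpoint is applied
(`warm_start="secant"`), using a plant-slope estimate maintained from the
controller's own evaluations — plain reuse of the previous force
(`warm_start="previous"`) is available but produces force plateaus followed
by restart jumps, i.e. hysteresis between scenarios that the physical system
does not have. Monotonicity of the plant is verified while bracketing; a
non-monotone response or an unreachable band (GRF above the band at zero
quadriceps force) raises a controller error carrying the probe evaluations.

## Release comparison and its metrics

The three scenarios are generated from one base configuration differing in
nothing but the release percentage (verified by a config diff before
running). Cross-scenario orderings are computed only over load steps present
in all traces. The anterior-translation metric is the posterior-to-anterior
excursion — the largest rise of the AP curve above its running minimum —
which is the natural way to compare squats that first drift posterior and
later come anterior. Invariance checks use max relative differences at
matched steps: quadriceps force (tolerance 1 %) and patellar peak stress
(2 %); collateral mid-flexion means (40–62° window) are compared with a
0.5 N resolution floor reflecting the patch-discretization and
controller-step noise of the load curves. As noted above, the quadriceps and
patellar invariances are tight for this synthetic geometry and can exceed
their tolerances through the internal-rotation pathway.

## FE module

Linear 4-node tetrahedra by default, quadratic 10-node optional (same
assembly path, 4-point degree-2 quadrature for stiffness). Nodal stress
averaging for the error energy is volume-weighted over the elements sharing
the node; the error-energy integrand (quadratic for tet4, quartic for tet10)
is integrated with a rule exact for its degree (4-point / 15-point Keast).
The D matrix is isotropic from (E, ν); its inverse enters the error energy
per element. Contact pressures map onto the inlay block as per-face normal
tractions with the distal face fixed (cemented tray); the one-way coupling
keeps the FE solve linear. The convergence study runs mesh sizes from 3 mm
down to 1.5 mm and flags convergence when the peak von Mises change between
successive sizes falls below 5 % (config-exposed; the threshold is a repo
decision). Degenerate inputs: insufficient fixities raise a rank error naming
the unconstrained rigid-body modes; a failed size marks its row and the study
continues.

## Problem sizes and determinism

Defaults used throughout (tests and the acceptance script): 30 load steps,
1.5 mm contact-patch spacing (≈ 2 300 inlay + 700 patellar patches), FE
meshes up to a few thousand tet10 elements. A full three-scenario comparison
takes tens of seconds on one CPU; a single default squat runs in ~10 s.
Identical configurations reproduce traces byte-for-byte; figures are written
without timestamps so reruns are file-identical.

## Known limitations

* Magnitudes are synthetic-geometry magnitudes; only directions and orderings
  carry over to real knees.
* Internal rotation is under-constrained (see above) and can settle on
  different yaw branches between scenarios.
* No inertia, no muscle dynamics, no wrapping, no geometric rollback; squat
  capped at 73° flexion.
* The elastic-foundation law is linear in penetration: it does not stiffen as
  the penetration approaches the layer thickness, so extreme loads
  under-predict contact pressure.
* Coulomb friction makes equilibria mildly history-dependent; results are
  reported along the prescribed loading path only.
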