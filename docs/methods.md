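# Methods

`trunksim` models the elephant trunk — a muscular hydrostat — as a network
of point masses joined by axially loaded rods, estimates the internal
muscle-analogue forces that reproduce observed planar reaching movements,
and distills those forces into per-segment linear "stereotypical laws" that
map a desired segment curvature and length to the forces producing them.
This note documents the model, its assumptions, the numerical choices, and
what the synthetic experiments do and do not demonstrate.

## The discrete trunk

The trunk is discretized into 10 elliptical cross-sections (50 point
masses: per section a center node O and four outer nodes at the semi-axis
tips — dorsal P, ventral Q, and laterals B/A), spanning 9 segments over a
reference length of 1.85 m (~0.2056 m per segment). Mass (100 kg by
default) is allocated to sections proportionally to truncated-cone
sub-volumes with radii tapering linearly from 0.15 m at the base (an
assumption) to 0.05 m at the tip, then split equally over the five nodes of
each section. At rest the trunk hangs straight along −Z (gravity is −Z,
dorsal is +X, planar movements happen in the X–Z plane); all five nodes of
the base section are clamped (the attachment to the skull).

Rods come in three families:

* **longitudinal** — same-role outer nodes of adjacent sections (the
  bending/shortening muscle analogues);
* **radial** — section center to its four outer nodes (the narrowing
  muscle analogues);
* **connective** — passive tissue, in two groups: the four perimeter rods
  of each section, and a diagonal *web* joining each section's center and
  outer nodes to the neighbouring section (O_i–X_{i+1} and X_i–O_{i+1},
  X ∈ {P,B,Q,A}).

The web deserves emphasis because it is load-bearing in a structural sense:
in a straight configuration every non-web rod is either parallel or
perpendicular to the backbone, so the assembled stiffness decouples axial
from transverse displacements exactly — differential longitudinal tension
then folds sections without bending the trunk, and the center nodes have no
axial support at all. The diagonal web supplies both first-order bending
stiffness/authority and axial support of the backbone centers, emulating
the connective-tissue web that surrounds the nasal passages of the real
organ. It is never actuated. `connective_web=False` restores the
perimeter-only topology for comparison.

Each rod is a standard 3D truss element: local 6×6 stiffness with a single
axial mode k = E·A/L₀, rotated into the global frame by its direction
cosines and scatter-added into the 150×150 global stiffness; the mass
matrix is diagonal with each node mass repeated for X, Y, Z. Rod areas are
fixed fractions of the local cross-section area (longitudinal 0.15, radial
0.10, connective and web 0.05 of π·a·b) — the apparent Young's modulus
E = 1×10⁶ N/m², uniform by default, is the only material datum available
for trunk tissue, so the areas are the knobs that set realistic axial
stiffnesses (~10³–10⁵ N/m). A three-region (proximal/middle/distal)
modulus profile is configurable.

## Dynamics

The equation of motion, per node,

  M q̈ + F_el(q, q̇) + c·M q̇ + F_act(q) = F_ext,

is integrated with an adaptive Dormand–Prince 4/5 scheme. Passive
elasticity is evaluated geometrically: each rod carries the tension
k·(|d| − L₀) along its *current* axis (the linearization of this force at
rest is exactly the assembled stiffness matrix). The geometric form is
required, not cosmetic: the backbone centers and the bending mode rely on
rotation of rod axes for their restoring forces. Active forces (positive =
contraction) also act along the current rod axes and are equal and
opposite at the two endpoints.

Two damping terms are ours (the physical data constrain neither):

* mass-proportional viscous damping c = 2 s⁻¹ (damps slow pendular modes);
* a Kelvin–Voigt dashpot per rod, tension β·k·(stretch rate) with
  β = 0.01 s, which damps the high-frequency rod-stretch ringing that
  mass-proportional damping cannot touch (ζ ∝ 1/ω) and that otherwise
  destabilizes per-step force estimation.

Both are configurable and may be zeroed; the conservation tests (energy
drift, momentum bookkeeping, oscillator period) run undamped.

## Kinematic descriptors and classification

A movement trial is a time series of 10 cross-section ellipses (center,
ZYX-intrinsic Euler angles, semi-axes). Segment length L is the distance
between consecutive centers; the bend angles α, β are the components of
the relative rotation between consecutive section frames about the two
in-plane section axes (the torsional component about the normal is
discarded — planar analysis); curvatures are K_α = α/L, K_β = β/L and
K = √(K_α² + K_β²), reported in deg/m. A movement is *bending* (B) when K
exceeds 20 deg/m in at least one segment at some time, and
*bending+elongation* (BE) when additionally some segment lengthens by more
than 0.02 m relative to the trial's first sample (10% of the resting
segment length). Everything else — including twisting classes this planar
model does not treat — is OTHER.

Ellipse fitting from raw markers uses a total-least-squares plane fit
followed by a direct algebraic in-plane ellipse fit; a warning reports
rows whose markers cover ≤120° of arc (dorsal-only rows), where the fit is
poorly conditioned.

## Inverse dynamics

At each sampling interval the per-segment unknowns — FL_dorsal,
FL_ventral and FR (27 for the full trunk) — are estimated by minimizing
the squared mismatch between simulated and observed node displacements
over the interval, with forces held constant within it. The two lateral
longitudinal rods mirror the segment's mean drive Fm_L (driving only one
side of a planar mover leaves the lateral columns hanging on passive
elasticity); connective rods are never actuated.

Numerical design, each choice forced by a measured failure mode of the
naive scheme:

* **Tracked DoFs.** Backbone centers (X, Z) are the default comparison
  set for mocap-style data, but parameter recovery tracks all free nodes
  and kinematic (generator) targets track the *outer* nodes only: radial
  forces are unobservable from center motion, while the centers' axial
  position is uncontrollable near straight configurations (radial rods ⊥
  backbone) and demanding it saturates the optimizer.
* **Target formation.** The default target is the observed increment plus
  a small feedback correction (gain 0.2, clipped at 10 mm per step) on the
  accumulated deviation. Pure increments are open-loop and drift; full
  one-step correction is a deadbeat demand that destabilizes the lightly
  damped structure.
* **Solver.** The step response is affine in the forces to high accuracy,
  so each step solves a bounded linear least-squares system around the
  warm start, using a finite-difference force Jacobian refreshed every few
  steps, with backtracking when the affine prediction degrades. A
  reference trust-region nonlinear path exists for Jacobian-free use.
* **Bounds and tie-break.** Active forces live in [−1000, +5000] N.
  Muscles pull; the negative margin stands for limited compression
  transmission through surrounding tissue and stays below the ~1.5 kN
  load at which the compressed rod columns of this truss buckle. A strict
  contraction-only bound is available but makes dFL and Fm_L exactly
  collinear whenever one longitudinal rod rests on the bound, degrading
  the law fits. A weak ridge (weight 1e−5 on forces scaled by the bound,
  optionally centered on a nonzero tonus) resolves the under-observed
  directions toward minimum norm.
* **Initialization.** Trials start from the static equilibrium nearest
  the first sample, found by a bounded Gauss–Newton gravity balance in
  which the center nodes are eliminated (placed at their analytic sag for
  any candidate radial force), followed by a short settle integration.
  Pinning idealized, unsagged targets injects a pendular transient that
  rings for seconds.

On targets generated by the forward model itself the estimator recovers
the generating force histories to ~1–2% relative RMS. On idealized
kinematic trials the simulated trunk tracks commanded bending to ~10 mm;
commanded elongation is only fractionally realized, because the truss's
radial-to-axial geometric coupling (through the web diagonals,
dL/L ≈ (r/L)²·dr/r) is far weaker than the ideal constant-volume coupling
dL/L = −2·dr/r. Axial errors in BE movements are therefore the model's
weakest axis, and BE trajectory errors exceed B errors.

## Stereotypical laws

For every segment, ordinary least squares fits

* K-law: K = β₀ + β₁·dFL + β₂·FR + β₃·Fm_L + ε
* L-law: L = β₀ + β₁·dFL + β₂·FR + β₃·Fm_L + ε
* F-law: FR = β₀ + β₁·dFL + β₃·Fm_L + ε

with R², adjusted R² (standard (n−1)/(n−p−1) correction) and RMSE
reported; units are deg/m, m and N throughout. Laws are fitted per
movement class, pooled over trials; the forces of interval j are paired
with the shape at the interval's end. Crucially, the shapes come from the
*inverse-dynamics simulation*, not the idealized trial: the laws then
describe the model's own force–shape relation — which is what the
controller must invert — and the weakly force-dependent length direction
retains genuine signal. The three laws of a segment form a determined 3×3
system; given a desired (K, L) it is solved exactly for (dFL, FR, Fm_L),
with a condition-number guard at 1e12. The exact solution is fragile along
the nearly collinear length direction, so commanded shapes should lie on
the model's manifold and the reaching controller clamps the resulting
forces to the actuation bounds.

On the synthetic study (three B trials, peak curvatures 15/30/45 deg/m,
3 s at 20 Hz, bend weighted toward the tip), adjusted R² of the curvature
law exceeds 0.99 in the proximal segments. Pairwise correlations on a
constant-volume BE movement reproduce the hydrostat signature: FR against
Fm_L strongly negative (antagonism), FR against L positive (radial
contraction accompanies lengthening).

## Reaching controller

Reaching is open loop: curvature and length of each segment are
interpolated as convex combinations between the initial and final
configurations at f_s = 100 Hz by default (t_j = j/f_s, 0 ≤ j < T·f_s; the
exact final target is never evaluated unless `--include-endpoint` adds one
extra piece), the laws are inverted at each sample, the per-segment
aggregates are expanded to rods (FR split equally over the four radial
rods by default) and held constant over each interval while the dynamics
integrate forward. The run starts from the settled equilibrium of the
initial commanded forces. On the synthetic closed loop (laws fitted as
above, fresh 35 deg/m reference movement) the final tip-center position
lands within ~7% of the reference tip path length.

## Error metrics and volume

Trajectory errors are per-node MAE and RMSE of the planar (X, Z) Euclidean
deviation; the relative MAE divides by the arc length of that node's
*reference* path (zero-length paths are flagged NaN, never divided).
Trunk volume sums 9 hexahedra spanned by the outer nodes of consecutive
sections, each decomposed into six tetrahedra sharing a fixed diagonal
(bit-reproducible); an elliptic-frustum variant computes volume directly
from ellipse parameters. Conservation is reported as mean absolute
deviation from the resting volume in percent. Tip-specific metrics use the
most distal section's center node.

## Synthetic data generator

Trials emulate the structure of mocap-derived trunk recordings: 10 ellipse
rows at a uniform rate, minimum-jerk time profiles for commanded curvature
and length, section frames composed segment-by-segment (commanded L is the
chord length, so the kinematics module recovers commanded K and L
exactly), optional per-segment bend weights (the pipeline's default grades
0.3→1.0 base-to-tip, echoing tip-led reaching), and optional Gaussian
center noise, all seeded. For BE trials both semi-axes scale as
√(L_rest/L(t)), which preserves every segment's elliptic-frustum volume
exactly — the analytic incompressibility of a muscular hydrostat. The
ground-truth force generator draws non-negative two-harmonic force
envelopes and forward-integrates them, providing the recovery oracle.

What the generator does not emulate: real curvature-front propagation,
twisting, marker dropout, or the sag of a real trunk at "rest" — its
trials are exact geometric constructions, which is precisely why the
static-equilibrium initialization described above is needed.

## Problem sizes and defaults used in the shipped experiments

Tests and the acceptance script run the full 50-node trunk for kinematics,
statics, classification, volume and the law pipeline (trials of 3 s at
20 Hz; three fitting trials plus one test trial), and a 3-section
(15-node) trunk for force-recovery oracles (40 steps at 50 Hz). These
sizes were chosen so the whole study re-runs in a few minutes on one core
while every number is computed from scratch.

## Known limitations

* Elongation under-actuation, as discussed: the truss realizes only a
  fraction of a commanded constant-volume elongation.
* The determined law system is ill-conditioned along the length direction;
  off-manifold (K, L) demands produce clamped, distorted force schedules.
* No torsion, no oblique actuation, no contact; classification folds all
  non-planar classes into OTHER.
* The stiffness parameters (areas, taper, damping) are plausible choices,
  not measurements; conclusions about the real organ should rest on the
  qualitative reproductions (antagonism, volume conservation, law
  structure), not on absolute force magnitudes.
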