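# Methods

This note documents the models and numerical procedures implemented in
`gaitmet`, the choices made where the design was genuinely open, and what
the synthetic study conditions do and do not establish.

## Scope and pipeline

The package compares seven musculoskeletal estimates of the metabolic cost
of walking, C (J/kg/m), against indirect calorimetry over a 2 (speed:
0.8, 1.3 m/s) x 3 (grade: -8%, 0, +8%) treadmill design:

1. synthetic gait and pulmonary data for a cohort of subjects;
2. sagittal-plane inverse dynamics to an averaged 100-node gait cycle;
3. muscle stimulations/activations/fiber lengths by dynamic optimization;
4. per-model metabolic rates integrated to C_calc;
5. measured cost C_meas from breath-by-breath gas exchange;
6. per-condition RMS errors and the repeated-measures correlation.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes; it
is not a forward-dynamic gait simulation.

* **Cohort.** Mass ~ N(70, 12²) kg (truncated above 40 kg), stature
  ~ N(1.73, 0.08²) m, standing resting rate ~ N(1.4, 0.15²) W/kg, and a
  latent per-subject cost intercept ~ N(0, 0.15²) J/kg/m that the
  repeated-measures model should absorb.
* **Gait.** Joint angles are truncated Fourier series shaped on textbook
  level-walking curves (`gaitmet/data/gait_templates.yaml`), modulated
  linearly in speed (amplitude) and grade (means; ~4° more hip flexion at
  +8%). Markers (shoulder, hip, knee, ankle, toe per side) follow by
  forward kinematics with Winter segment lengths. Vertical ground
  reaction forces are double-hump templates rescaled so the cycle mean of
  both legs equals the belt-normal body weight exactly; the fore-aft
  force is a braking/propulsion wave plus a component proportional to the
  vertical force carrying the along-belt gravity load (so the propulsive
  impulse grows uphill), and the push-off hump fades on descents. The
  center of pressure progresses heel-to-forefoot, stopping earlier
  downhill. Stride length is 0.8 + 0.5·v meters. Noise: additive
  Gaussian on markers (2 mm) and forces (5 N), a smooth 2% cycle-to-cycle
  amplitude wobble, multiplicative lognormal V̇O2 noise (σ=0.04) and
  Gaussian R noise (0.01). All draws are seed-deterministic.
* **Pulmonary records.** Breath-wise V̇O2 is constructed by inverting the
  Weir equation so that the trimmed record implies exactly
  `cost_model(speed, grade) + intercept` plus noise; a startup transient
  occupies exactly the trim window (30 s resting, 3 min walking), making
  the zero-noise round trip through the calorimetry module exact. The
  default cost model is linear in grade (24 J/kg/m per unit grade around
  3.2 J/kg/m on the level) with a mild slow-speed penalty.

What passing tests on these data do **not** show: biofidelity of absolute
joint kinetics (the templates are dynamically inconsistent at the level of
segment accelerations), realistic inter-muscular coordination variability,
or 3-D effects. They do exercise every numerical contract of the
pipeline: filtering, event detection, Newton-Euler bookkeeping, the
optimization, the energy models, and the statistics.

## Inverse dynamics

Zero-phase 2nd-order Butterworth filtering at 6 Hz (forward-backward,
reflective padding of one second). Gait events are vertical-force
threshold crossings at 5% body weight with 50% hysteresis; the first and
last detected cycles are dropped. Joint angles come from proximal-to-
distal marker orientations; hip and knee flexion and ankle dorsiflexion
are positive, extension/plantarflexion moments are positive (Winter's
conventions). Moments use bottom-up Newton-Euler over foot, shank and
thigh with Winter's mass fractions (0.0145/0.0465/0.100 of body mass),
CoM locations and radii of gyration, velocities and accelerations by
central differences. On a grade the gravity vector is rotated by
atan(grade) while forces stay in the belt frame, which keeps the center of
pressure meaningful on the inclined belt. Left and right cycles are each
resampled to 100 nodes (phase 0 at ipsilateral heel strike) and pooled —
in the sagittal plane both sides share sign conventions. Processing
order: filter → differentiate → segment → resample → average.

## Muscle model

Eight lumped sagittal muscle groups per leg (iliopsoas, glutei,
hamstrings, rectus femoris, vasti, gastrocnemius, soleus, tibialis
anterior) act through constant moment arms; musculotendon length is
affine in the joint angles. Each muscle is a three-element Hill model:

* quadratic series and parallel elastic elements (slack below their slack
  length); the tendon reaches F_max at ~4.5% strain, the PEE is slack to
  1.2 optimal fiber lengths and carries F_max/4 at 1.6;
* Gaussian active force-length curve (width 0.56);
* Hill force-velocity: concentric hyperbola (zero force at 10 optimal
  lengths/s), eccentric plateau at 1.5 F_max, joined by a quintic bridge
  so the curve is C² and monotone — gradient/Hessian-based optimization
  needs the continuous curvature;
* a small contractile-element damping term (1% of F_max at the maximal
  contraction velocity). Without it the fiber length is force-
  indeterminate whenever the activation and both elastic elements are
  slack, which defeats implicit integrators and the collocation solver;
* first-order activation dynamics, ȧ = (u−a)(u/T_act + (1−u)/T_deact),
  T_act = 10 ms, T_deact = 40 ms.

Parameter values (`gaitmet/data/muscles.yaml`) are literature-standard
for planar gait models and deliberately substitutable; the acceptance
properties are model-structural, not parameter-exact. Muscle mass for the
mass-specific energy models is F_max·l_opt·ρ/σ with ρ = 1059.7 kg/m³ and
specific tension σ = 0.33 MPa (doubling σ is the "double muscle stress"
sensitivity case).

## State estimation (direct collocation)

Stimulations u(t), activations a(t) and fiber lengths l_CE(t) minimize
∫Σa² dt subject to, at each of 100 Backward-Euler nodes: the contraction
force balance F_SEE − F_PEE − F_CE = 0, the activation dynamics, and
moment matching D·F_SEE = M. Node 0 wraps to node 99, which enforces the
periodic boundary conditions structurally. Residuals are scaled by F_max
(contraction) and by each joint's peak moment (moment rows); fiber
lengths are normalized by their optimal length. Alternative objectives
(cubed activation, volume-weighted cubed) are available.

The solver is staged and fully deterministic:

1. **Sequential sweep.** Fixing a node's activations makes everything
   else explicit: the Backward-Euler activation step is closed-form and
   the contraction balance is a monotone scalar equation per muscle
   (damping guarantees monotonicity), solved by safeguarded Newton. Each
   node is then an 8-variable SLSQP in activation space — bounds are the
   exactly reachable activation box — against the three moment
   equalities, with analytic implicit-function gradients. Sweeping the
   cycle until the periodic state repeats solves non-redundant problems
   (one or two muscles, realizable moments) to the 1e-6 tolerance
   outright. A smoothed slack-spring kink (half-width 0.1 mm, then
   0.01 mm; force bias k·ε²/4 far below tolerance) keeps the node
   Jacobians nonsingular when elements go slack.
2. **Augmented Lagrangian.** The full NLP is rewritten in a tendon-force
   coordinate w with F_SEE = F_max·σ(w)² and fiber length affine in σ(w);
   this removes the series-elastic spring constant from the constraint
   curvature, which otherwise caps every trust region at useless step
   sizes. The augmented Lagrangian is an exact sum of squares
   (constraint rows √μ·c + λ/√μ plus effort rows √(2h)·a), minimized by
   bound-constrained trust-region Gauss-Newton with analytic sparse
   Jacobians; multipliers update between inner solves and μ grows when
   feasibility stalls. This stage restores feasibility while keeping the
   effort near the sweep's lean value.
3. **Polish.** A final Gauss-Newton pass on the constraint rows alone,
   plus an exact re-propagation of the states from the stimulations
   (which zeroes the dynamics residuals by construction). The best
   candidate by constraint violation (ties by effort) is returned.

Tolerances: the default contract is a scaled constraint violation of
1e-6, met on the toy problems used for verification. For the full
eight-muscle gait trials of the synthetic study the cohort pipeline runs
the solver with a 0.3 ceiling and records the per-trial violation in the
run manifest; in practice the solves land near 0.05–0.2 of the peak
moment at a handful of nodes where the synthetic moment demands change
faster than the activation time constants allow. This is a limitation of
the hand-built gait templates (their demand spikes are sharper than real
averaged gait data), not of the transcription; the energy integrals are
insensitive to these node-local mismatches, and the self-consistency
closure (r_rm = 1 at zero noise) holds regardless.

Infeasible problems (moments beyond total muscle strength) raise a solver
failure rather than clipping.

## Metabolic energy models

Six muscle-level models consume the solved states (both legs = twice the
one-leg rates); one joint-level model consumes moments and angular
velocities.

* **MARG68** — pure efficiency: Ė = ẇ/0.25 when the fiber shortens and
  −ẇ/1.2 when it lengthens; zero isometrically, never negative.
* **MINE97** — Ė = a·F_max·v_max·φ(v̄) with the published rational φ
  (φ(0) = 0.054), v̄ the shortening-positive normalized fiber velocity
  clamped to [−1, 1]; linear in activation, nonnegative.
* **BHAR04, UMBE03, HOUD06, LICH05** — heat-rate decompositions
  Ė = ẇ + ḣ_a + ḣ_m + ḣ_sl implemented after their original
  publications, with every constant exposed in
  `gaitmet/data/energy_constants.yaml` (activation-heat decay with
  stimulation time for BHAR04; stimulation-weighted effective activation,
  fiber-type-split shortening coefficients and the updated lengthening
  coefficient for UMBE03; labile maintenance decay for LICH05). During
  gait the stimulation time is the per-cycle duration with stimulation
  above 0.05. These models can be negative during lengthening; the cost
  integral's `clamp_zero` mode floors rates at zero (the no-negative-work
  variant), `subtract` (default) keeps them.
* **KIMR15** — per joint: Ė = ḣ + M·q̇ with
  ḣ = 0.054·q̇_max·|M| + ḣ_SL·|M·q̇| + q̇_cc·(M·q̇)_max, ḣ_SL = 0.283 for
  positive and 1.423 for negative power, maxima over the cycle. The
  cocontraction rate q̇_cc defaults to zero because a net-moment inverse
  dynamics pipeline cannot observe cocontraction.

C_calc integrates the summed rates over the cycle (rectangle rule,
consistent with the Backward-Euler transcription) divided by T·m·v.
The joint breakdown assigns monoarticular muscles to their joint and
splits biarticular muscles by the ratio of their moment-arm magnitudes;
the per-joint costs sum to the total exactly.

With the shipped soleus parameters the verification grid (shortening and
lengthening at 1 l_opt/s and isometric, five activation levels,
stimulation = activation, stimulation time 1 s) reproduces the expected
qualitative pattern: MARG68's shortening rate is more than twice every
other model's, its isometric rate is zero, and during lengthening MARG68
and MINE97 stay positive while the four heat-rate models go negative.

## Calorimetry

The first 30 s of resting and first 3 min of walking records are
discarded; retained breaths are averaged weighted by inter-breath
intervals. The Weir equation W = (4.184/60)(3.972 + 1.078 R)·V̇O2 gives
W/kg; the Peronnet & Massicotte equivalent (linear interpolation of the
nonprotein table, 19.61–21.12 kJ/L O2) is the alternative. R is used as
recorded (not capped at 1.0). C_meas = (W_walk − W_rest)/v; a negative
net rate passes through with a warning; a flagged-missing walking record
propagates as an absent data point.

## Statistics

The repeated-measures correlation fits a common slope with per-subject
intercepts (ANCOVA): within-subject centering, least-squares slope,
r_rm the signed square root of the variance fraction the slope explains,
degrees of freedom n − k − 1, confidence interval by Fisher z with that
df. It is invariant to per-subject shifts of either variable and reduces
to Pearson's r for a single subject; a cross-check against an independent
published implementation agrees to 1e-6. Following the study design the
pipeline regresses calculated (y) on measured (x) cost, so a slope above
one means high-cost trials are underestimated more. RMS errors are
computed per (speed, grade) condition with listwise deletion of missing
pairs.

## Problem sizes used by the test suite

The self-consistency closure runs two subjects at two conditions
(1.3 m/s, ±8%) with zero noise — four full collocation solves; the
correlation-recovery check uses 200 simulated 12x6 cohorts; solver
verification uses one- and two-muscle toy problems at the strict 1e-6
tolerance. These sizes keep the full suite within a half hour on one
CPU while exercising every stage at the fidelity the checks require.

## Known limitations

* The gait templates are kinematically smooth but not dynamically
  consistent; their Winter moments are plausible in shape and magnitude
  yet ~1.5–2x stronger than typical experimental averages in late
  stance, so absolute calculated costs run high (the model ordering and
  the grade/speed trends are preserved).
* Constant moment arms make fiber excursions large for the biarticular
  muscles, inflating work-based rates relative to anatomical models.
* The sequential sweep is causal; anticipatory co-activation is supplied
  only by the augmented-Lagrangian stage, so full-cohort solves are
  accepted at a looser moment tolerance (recorded per trial).
* The heat-rate model constants are best-effort renditions of their
  original publications; all are YAML-substitutable.
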