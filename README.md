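# gaitmet

Model-based estimates of the metabolic cost of walking, compared against
indirect calorimetry.

`gaitmet` is for biomechanists and movement scientists who want to know how
well musculoskeletal **metabolic energy-expenditure models** track the real
energetic cost of gait when the walking conditions change — here, two
treadmill speeds (0.8 and 1.3 m/s) crossed with three grades (−8%, level,
+8%). The package implements the full chain as tested, reusable modules:

* **`gaitmet.synthetic`** — seedable generator for cohorts (mass
  70 ± 12 kg, height 1.73 ± 0.08 m), periodic marker + ground-reaction-force
  recordings, and breath-by-breath pulmonary gas exchange whose implied
  cost equals a configurable ground truth plus per-subject intercepts.
* **`gaitmet.inverse_dynamics`** — zero-phase 6 Hz Butterworth filtering,
  heel-strike segmentation, sagittal joint angles, Winter link-segment
  joint moments, and the averaged 100-node gait cycle.
* **`gaitmet.muscle` / `gaitmet.estimation`** — an eight-muscle Hill-type
  model (contractile element with activation dynamics, force–length and
  force–velocity curves; quadratic series and parallel elastic elements)
  and the dynamic optimization that finds stimulations u(t), activations
  a(t) and fiber lengths l_CE(t) minimizing ∫Σaᵢ² dt subject to the
  contraction balance F_SEE − F_PEE − F_CE = 0, the activation dynamics
  ȧ = (u−a)(u/T_act + (1−u)/T_deact), and moment matching
  D·F_SEE = M_winter, discretized by Backward Euler on 100 periodic
  collocation nodes.
* **`gaitmet.energy`** — the seven energy models: four heat-rate models
  (Ė = ẇ + ḣ_a + ḣ_m + ḣ_sl; **BHAR04**, **HOUD06**, **UMBE03**,
  **LICH05**), the velocity-function model **MINE97**
  (Ė = a·F_max·v_max·φ(v̄), φ(0) = 0.054), the efficiency model
  **MARG68** (25% efficient shortening, 120% lengthening), and the
  joint-level model **KIMR15**; the cost of transport
  C = (1/Tmv)∫ΣĖᵢ dt in J/kg/m with a per-joint breakdown.
* **`gaitmet.calorimetry`** — measured cost from V̇O2 and the respiratory
  quotient via the Weir equation W = (4.184/60)(3.972 + 1.078R)·V̇O2 (or
  the Peronnet–Massicotte equivalent), resting-rate subtraction and trial
  trimming.
* **`gaitmet.stats`** — the repeated-measures correlation r_rm (common
  slope, per-subject intercepts, Fisher-z CI with df = n − k − 1) and
  per-condition RMS errors.
* **`gaitmet.pipeline` / CLI `gaitmet`** — end-to-end orchestration with
  manifests, tables and figures.

See `docs/methods.md` for the models, assumptions, numerical choices and
limitations.

## Worked example

The soleus verification grid evaluates every muscle-level model at three
contraction speeds and five activation levels (stimulation = activation,
stimulation time 1 s, fiber at optimal length):

```text
$ gaitmet verify-models --model MARG68
 model   condition  activation           E
MARG68  shortening        0.05   54.811429
MARG68  shortening        0.25  281.097143
MARG68  shortening        0.50  563.954286
MARG68  shortening        0.75  846.811429
MARG68  shortening        1.00 1129.668571
MARG68   isometric        0.05    0.000000
...
MARG68 lengthening        1.00  458.700000
```

`E` is the soleus metabolic rate in watts. The isometric column is zero —
this model charges only for mechanical work (at 25% efficiency while
shortening, hence 1129.7 W to produce the 282.4 W of fiber work at full
activation, and 120% while lengthening). Rates rise linearly with
activation because the force does.

A small end-to-end run:

```sh
gaitmet -v analyze --subjects 2 --seed 1 --models MARG68,KIMR15 --out results/
gaitmet report --results results/
```

writes per-trial calculated and measured costs (`trial_costs.csv`),
per-condition RMS errors, the repeated-measures correlation table
(`rmcorr.csv`), a run manifest with seeds and solver diagnostics, and
figures (verification grid, per-joint cost breakdown, measured-vs-
calculated scatter with per-subject fits). With the default generator a
calculated cost rises from downhill to level to uphill walking for every
model, and the heat-rate model HOUD06 yields the lowest, the efficiency
model MARG68 the highest cost — the qualitative pattern such comparisons
are designed to probe. Expect roughly two minutes of computation per
subject-condition for the collocation solves.

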