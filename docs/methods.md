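# Methods

## Scope and model structure

`willisflow` couples three layers into one closed loop:

1. **1D arteries.** Straight axisymmetric compliant tubes carrying the
   (A, Q) system with friction `−K_R Q/A`, `K_R = 22πμ/ρ`
   (μ = 0.0047 Pa·s, ρ = 1060 kg/m³), closed by the square-root tube law
   `P = P0 + β(√A − √A0)`, `β = √π·Eh/((1−σ²)A0)`, σ = 0.5,
   P0 = 85 mmHg.  Wall stiffness follows an exponential-plus-constant
   empirical law `Eh(r0) = r0(k1·e^{k2 r0} + k3)` with
   (k1, k2, k3) = (2.0·10⁶ Pa, −2253 m⁻¹, 8.65·10⁴ Pa), overridable per
   segment in the config.
2. **Stenoses.** A lumped interface inside the host segment imposing
   `ΔP = R_v Q + K_t·8ρ/(π²D_n⁴)·{(1−SR)⁻²−1}²·Q|Q| + K_u·4ρL_s/(πD_n²)·Q̇`
   between the total pressures of the two halves.  `K_u = 1.2` fixed;
   `Q̇` by backward difference.  An "intact" specification
   (R_v = SR = K_t = 0) is not inserted at all, so its loss is identically
   zero.
3. **0D circulation.** Three-element Windkessel outlets (PR split
   proximal/distal by a fixed fraction, default 0.1), RLC body blocks in
   series (capillaries–venules–veins), and a left-atrium + left-ventricle
   time-varying-elastance heart with diode-plus-resistance valves.  The
   pulmonary circulation is folded into the venous-return path: the model's
   purpose is systemic afterload and cerebral flow distribution, for which
   a single-sided heart with the correct stroke volume and filling dynamics
   suffices.  The cardiac period is fixed at 1 s.

Two networks ship as literature defaults (assembled from the classic
systemic-tree and cerebral modelling literature, not fitted to any
patient): the 83-segment systemic tree whose 22 carotid/cerebral segments
form and feed the circle of Willis (3 inlets, 6 outlets, communicating
arteries closing the ring), and a 5-segment toy loop (trunk → two branches
→ two outlet arteries, one branch hosting the stenosis) sized to carry a
cerebral-scale ~850 mL/min with its own scaled-down heart.  Every
parameter is serializable to a YAML config that round-trips exactly.

## Numerics

* **Scheme.** Richtmyer two-step Lax–Wendroff on the conservative form
  with flux `(Q, Q²/A + β/(3ρ)A^{3/2})`; per-segment uniform grids with an
  odd node count (≥ 3) so an exact middle node exists; default spacing
  2.5 mm (10 mm on the toy loop, where segments are short).
* **Boundaries.** All couplings go through Riemann invariants
  `W± = u ± 4c`, `c = √(β√A/2ρ)`, interpolated at the characteristic foot.
  Junctions solve mass conservation plus equality of total pressure
  `P + ½ρu²` across all connected ends by Newton–Raphson (analytic
  Jacobian, tolerance 1e-10, ≤ 50 iterations, hand-rolled Gaussian
  elimination for the ≤ 6-end systems).  The same machinery handles
  bifurcations, merges (vertebrals → basilar) and the CoW ring.
* **Heart/0D.** Classical RK4 with the 1D couplings frozen over the step;
  the 0D step is sub-divided to ≤ 0.2 ms because the open-valve chamber
  dynamics are stiffer than the CFL limit.  The ventricular outflow used
  by the volume ODE is exactly the flow the 1D root accepted, which keeps
  the 1D–0D volume exchange consistent (without this the loop slowly
  drains).
* **Time step.** Global Δt from CFL 0.9 against the maximum `|u| + c`
  (margin factor 1.25), recomputed every cycle.
* **Periodicity.** Cycles repeat until every cycle-averaged output changes
  by < 1e-3 relative (denominator floored at one output unit) between
  consecutive cycles; default cap 30 cycles; averages come from the final
  cycle.  A small residual volume-closure drift of order 5·10⁻⁴ per cycle
  remains at coarse grids (first-order boundary-flux closure); it halves
  with the grid spacing and sits below the periodicity tolerance at the
  default grids.
* **Initial state.** Arteries at reference area, zero flow; Windkessel
  capacitors at 85 mmHg; body blocks at 15 mmHg; chambers at a 5 mmHg
  filling pressure.  The toy loop reaches periodicity in ~9 cycles, the
  83-segment network in ~7.

## Input/output contract

Each network carries a machine-readable manifest. For the 83-segment
network it is the 60-slot layout (22 diameters, 22 lengths, 6 CoW outlet
PRs, total-PR scaling, age, left/right {R_v, D_n, SR}, left/right K_t) with
published sampling ranges per artery; outputs are the 45 cycle-averaged
quantities (22 flows mL/min, 22 pressures mmHg, MAP at the left subclavian
middle node).  Applying an input vector re-derives wall stiffness from the
sampled diameter, rescales non-CoW outlet PRs relative to their build-time
base values (so application is idempotent), applies the aortic age mapping
(piecewise-linear stiffness/diameter factors over ages 25–90, reference
40), and installs the stenosis specs.  The toy network exposes the same
kinds through a 14-slot manifest and 9 outputs.

## Learning data and surrogate

Inputs are drawn uniformly and independently within the manifest ranges
under four scenarios (intact / left / right / bilateral stenosis; the toy
network supports the first two).  The stenosis R_v is drawn in
[0, min(128μL_s,max/(πD_n,min⁴(1−SR)⁴), 500)] mmHg·s/mL with
L_s,max = 40 mm and D_n,min = 2.9 mm.  Samples with negative mean
pressure, reversed cycle-averaged flow in an outlet-bearing artery, or no
periodic state are rejected and redrawn ("reversed terminal flow" is
interpreted at the Windkessel-bearing flagged arteries, which is what the
45-output contract exposes).  Splits are stratified 6:2:2 with the
remainder to train.

The surrogate is a fully connected network: linear → batch norm → ReLU
hidden layers and a linear output layer, written in plain numpy (forward,
backprop and Adam authored here).  Inputs scale affinely so the declared
bounds map to [−1, 1]; outputs are standardized with training-set
statistics only.  Training minimizes the pooled MSE with mini-batch Adam;
the pooled validation R² is logged every epoch, the trailing-100-epoch mean is
compared every 100 epochs, training stops after three successive
non-improving evaluations, and the best-epoch weights (including batch-norm
running statistics) are restored.  The early-stopping R² is the pooled
45-output coefficient of determination computed in scaled space.  The
trainable-parameter count sums linear weights and biases only — batch-norm
scale/shift are trained but excluded from the count, so the reference
60 → 7×200 → 45 architecture counts exactly 262 445.  Checkpoints are
self-describing JSON (weights, batch-norm statistics, scaling, metadata).

## Calibration

Measured per-outlet flows are rescaled to the measured total CoW inflow at
constant distribution ratios; those targets plus the measured MAP drive the
adjustment of the 6 CoW outlet PRs (damped multiplicative fixed point,
`PR_i ← PR_i (Q_i/Q_i^target)^0.8`, justified by the near-inverse PR→flow
relationship) interleaved with a secant iteration of the total-PR scaling
factor on MAP.  Defaults: flow tolerance 0.5 % relative, MAP tolerance
1 mmHg, ≤ 200 iterations, PRs clamped to the manifest bounds; a stall
detector (no 5 % score improvement for 25 iterations) aborts hopeless
iterations early.  Non-convergence is a reported result, not an exception.
The predictor is any manifest-compatible x → y map, so the simulator and
the surrogate run through identical code.

## Uncertainty quantification

A patient record carries measured diameters (± 2 pixels uniform,
intersected with the sampling ranges), stenosis geometry (one shared
diameter offset δ ∈ [−2 px, +2 px] applied to the whole profile, from which
R_v — via the quadrature over a parabolic throat profile — SR and D_n are
recomputed jointly), K_t ∈ [1.0, 2.699], total CoW inflow (± 16 % PC-MRI,
± 35 % ultrasound) and per-outlet perfusion flows (± 16 %).  A flagged
possibly-absent anterior communicating artery spans 0.1–2.6 mm regardless
of the measured value.  All uncertain quantities are independent uniform
draws; MAP is not varied.  Each realization: draw → preoperative
calibration (non-converged draws rejected and counted) → virtual stenting
(R_v = SR = K_t = 0, D_n = sampled ICA diameter; adjusted PRs and geometry
held fixed) → postoperative prediction → per-outlet percentage flow
increase.  The sample grows in increments (default 10 000) until the mean
and variance change < 0.1 % relative; reported statistics are mean,
variance, Freedman–Diaconis-mode, min–max interval and P(increase > 100 %).

Synthetic records are validated against the simulator: measured flows and
MAP are taken from a simulator run at the measured geometry, so the
calibration targets are attainable by construction.  What passing tests on
such records demonstrate is the correctness of the pipeline mechanics and
estimators — not agreement with clinical outcomes, which would require real
imaging and flow data.

## Sensitivity analysis

Saltelli design [A; B; AB_i] from scrambled Sobol sequences (N·(D+2)
evaluations; no second-order terms), Saltelli-2010 first-order estimator
and Jansen total estimator, percentile bootstrap (default 1000 resamples)
over evaluation blocks for 95 % CIs.  The SA model function is the full UQ
pipeline evaluated at the design points; non-converged calibrations are
imputed with the nearest previously accepted evaluation and counted.

## Problem sizes and verification

The shipped study conditions are: toy-network grid 10 mm, datasets of
2000 samples (1000 per scenario) for the reduced-scale surrogate check,
UQ increments of a few thousand samples on analytic or toy problems, and
Sobol bases of 2¹⁴ for the estimator oracles.  The oracle suite pins the
physics: steady friction limit within 1 % (grid-limited, first-order in
Δx), linearized pulse speed within 3 %, junction mass closure at 1e-10,
closed-loop conservation within 1 %, stenosis interface jump within 0.5 %
(compared on total pressure), Ishigami and additive-model Sobol indices
within Monte Carlo tolerance, bootstrap coverage ≥ 90/100, calibration
recovery within 0.5 %, and the hyperperfusion-probability estimator within
three binomial standard errors of a closed form.

## Known limitations

* The 83-segment geometry, Windkessel/0D/heart values are literature-style
  defaults, not a reproduction of any published parameter table; absolute
  flows are physiological but not patient-matched.
* No viscoelastic walls, tapering, curvature, autoregulation dynamics or
  peripheral collateral pathways; the heart has no right side.
* The boundary-flux closure is first order, leaving a small grid-dependent
  volume drift (quantified above).
* Real patient data stay out of scope; all records here are synthetic.
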