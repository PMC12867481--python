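# Methods

## The measurement model

Walking on a split-belt treadmill perturbs gait symmetry. Each stride yields a
*step length asymmetry*

    sla = Δstep_length / stride_length,

which decomposes exactly into a belt-driven *perturbation* and a compensatory
*Δ motor output*:

    sla(k) = u(k) − p(k),
    p(k) = (mean_time / stride_length) · Δstep_velocity,
    u(k) = Δstep_position / stride_length − (mean_velocity / stride_length) · Δstep_time,

with Δ = right − left and `mean` the right/left average; all three quantities
are dimensionless. `gait_metrics.compute_gait_series` evaluates these per
stride and also returns the diagnostic residual `sla − (u − p)`: for synthetic
kinematics the identity is exact by construction; for real marker data it may
be violated numerically, so it is reported rather than assumed.

## Protocols

`paradigm.build_protocol` assembles stride-indexed belt-speed schedules:

* tied baseline (default 120 strides ≈ 2 min), baseline ramp (right belt
  0.35→0.65 m/s, 7 configurations), second tied baseline, adaptation (right
  1.5 / left 0.5 m/s, default 750 strides ≈ 15 min),
* Exp 1: Ramp Down, right 1.5→0.5 m/s in 0.05 m/s steps held 3 strides each
  (21 configurations, 63 strides);
* Exp 2: Ramp Up & Down, 1.5→2.0 then 1.95→0.5 m/s with no pause (41
  configurations, 123 strides; the descent returns to the adaptation speed
  after 60 strides — the segment used for subgroup analysis).

Speeds are held internally as integer multiples of 0.01 m/s and materialized
so that `speed × 20` is exactly integral for 0.05-grid values; configuration
counting and tied-belt endpoints are therefore exact, never
floating-point-approximate. Tied-baseline and adaptation stride counts are
configurable because the underlying protocol specifies those phases in
minutes, not strides.

## Synthetic cohorts

`synthetic.generate_participant` plants a known ground truth over any
schedule:

* ideal perturbation p*(k) = p_gain · (right − left speed)(k), with
  p_gain = 0.27 per m/s so a 1 m/s split produces a plateau perturbation of
  0.27 — a typical split-belt asymmetry scale;
* adaptation: u = p* + A₁e^(−k/τ₁) + A₂e^(−k/τ₂) with defaults
  (−0.12, 322.072, −0.15, 29.662); the amplitudes sum to −p_plateau so
  adaptation starts near u = 0 (sla ≈ −0.27) and, over 750 strides, ends with
  u_plateau ≈ 95% of p_plateau (incomplete adaptation of realistic size);
* post-adaptation ramps: u = max(p*, r_true) for p* ≤ p_plateau — the
  recalibration + mapping rule; above the plateau (Exp 2 ramp-up),
  memory-based participants hold u = p_plateau while structure-based
  participants keep tracking p*;
* observation noise: one iid N(0, 0.02²) sequence added to u, with
  sla = u − p* defined from the noisy u, so the decomposition identity holds
  exactly under noise; 0.02 is a typical stride-to-stride sla SD;
* default planted recalibration r_true = 0.56 · p_plateau and PSE bounds
  0.64 / 0.39 m/s — the compensation levels the generator is meant to emulate;
* button presses land on the ramp configuration nearest to the true PSE
  (nearest-grid quantization is unbiased; a floor rule would bias the
  recovered PSE low by half a 0.05 m/s step), optionally jittered by a rounded
  Gaussian in strides with press order enforced.

What the generator does **not** emulate: autocorrelated stride noise, slow
drifts, forgetting during the ramp (available as planted dual-state dynamics
via `generate_dual_state_participant`, but off in the piecewise generator),
biomechanically detailed kinematics, or perceptual decision dynamics beyond
press-stride jitter. Tests passing on this generator therefore validate the
pipeline's correctness and discriminative power under idealized noise, not
robustness to structured artifacts of real data. One consequence measured on
the generator: structure-based participants flag ~26 of 60 ramp-up strides
below their baseline CI (an iid-noise stride falls below a CI of the *mean*
almost half the time), more than the 3–21 strides real structure-based
participants show; the memory/structure separation that drives the subgroup
analysis is preserved.

## Adaptation models

Seven forward simulators of u given p (in sla units), all deterministic and
length-preserving (`models`):

* **recal_map** — u(k) = p(k) if p(k) ≥ r else r; one parameter.
* **dual_state** — fast/slow states with retention A_f < A_s and error
  sensitivities B_s < B_f; u = x_f + x_s.
* **optimal_control** — LQG over hidden state [p; s] with forgetting rate a,
  A = [[a,0],[−1,0]], B = [0;1], observation y = s; u = −G(k)·x̂ with
  finite-horizon LQR gains (horizon = series length), steady-state Kalman
  gain from noise covariances diag(σ_p², σ_s²) and σ_y², innovation
  −p(k)+p̂(k). The cost is J = Σ(q·y² + r_u·u²) with defaults q = 1,
  r_u = 0.01: LQG frameworks leave the cost functional task-specific, so
  the weights are exposed parameters and results depend on these defaults.
* **memory_of_errors** — u(k+1) = a·u(k) + η(e)·e with η carried by a
  Gaussian basis over error space (21 centers on [−0.5, 0.5] sla, a grid wide
  enough to cover every error this task produces). The learning rate uses
  sum-normalized activations, η = wᵀ g(e)/Σg(e) with w initialized at η₀:
  this makes the naive rate exactly error-independent, so the β = 0 limit
  reduces identically to a single-rate learner (with raw activations the
  reduction would hold only approximately, degrading toward the grid edges).
  The w update uses sign(e(k−1)·e(k)) with e(0) = 0, so no update occurs at
  the first stride.
* **premo** — perceived sla is W_p·x_p + (1−W_p)·G (no visual shift without
  vision); the perceptual error drives x(k+1) = x(k) + K(G − x_p^per);
  p_per = p − (x_p^per − x_p).
* **pea** — Bayesian perceived movement x̂_p = W_p·x_p + (1−W_p)·T drives
  x(k+1) = A·x + B(T − x̂_p); the reported sla mixes again with
  W_R = W_p/(1+W_p).
* **pm_remap** — PReMo-style integration plus *learned* perceptual shifts:
  β_p relaxes at rate K toward η_p(x_v^I − x_p^I), and in mapping mode
  (ramp-down only) the goal re-targets the motor output,
  G(k+1) = max(0, β_p(k)/W_p + p(k+1)). Default η_v = 0: without visual
  feedback the perception of the actual asymmetry is not shifted (mirroring
  the no-shift assumption PReMo makes for its unsensed channel). With
  η_v = η_p the converged perceived perturbation at plateau would be
  W_p·p·(1 − 2η_p) — already negative for η_p > ½, i.e. the belts would feel
  reversed before the ramp even starts, contradicting the behavior the model
  exists to produce; with η_v = 0 the sign flip lands at p ≈ η_p·p_plateau,
  so the predicted PSE normalizes to ≈ η_p. Mapping-mode initial conditions
  are chosen as the adaptation-plateau fixed point:
  x_p(1) = p(1), β_p(1) = −η_p·W_p·p(1), β_v(1) = 0.

## Fitting and model comparison

Models are fitted per participant by bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective, tolerances 1e-12)
on the squared difference between measured and simulated u over the
post-adaptation ramp strides only (n = 63 for Exp 1). History-dependent
models (dual state, optimal control, memory of errors, PReMo, PEA) are
simulated from the start of the paradigm; recal_map and PM-ReMap are
simulated on the ramp alone. recal_map uses init r = p_plateau/2 and bounds
[0, p_plateau], with p_plateau the mean perturbation over the last 30
adaptation strides. The dual-state ordering constraints are enforced by
fitting (A_s, A_f/A_s, B_f, B_s/B_f), each in (0, 1) — a smooth
reparameterization rather than linear constraints. A single start is the
default (multistart is available for robustness studies).

Comparison uses the Gaussian-residual BIC, n·ln(RSS/n) + k·ln(n); additive
constants cancel in the reported differences (alternative − recal_map).
Zero RSS (noise-free synthetic fits) yields a flagged −∞ sentinel. Group
inference on ΔBIC uses the participant bootstrap below.

## Perception

PSE bounds are the belt-speed differences at the two press strides (speeds
are piecewise constant per configuration; no interpolation). Compensation
percentages: perceptual = PSE / adaptation speed difference (1 m/s by
default, exposed for other protocols), motor-recalibration = r/p_plateau,
motor-total = u_plateau/p_plateau, each ×100. The PM-ReMap predicted PSE is
the perturbation at the first positive→negative sign flip of p_per,
normalized to p_plateau; absence of a flip is a flagged, valid outcome.
Only bounds are reported — no point estimate between them is defined.

## Subgroup clustering

The per-participant feature is the count of strides (strictly) outside the
participant's own baseline CI — below it on the first 60 strides of the Exp 2
ramp, above it on the Exp 1 Ramp Down. The baseline CI is a 10,000-sample
percentile bootstrap of the mean over the second tied-belt block.

DBSCAN runs on this 1-D feature with no user input: min_pts = 4 (the
original DBSCAN recommendation; with 3, three-point tail clumps of a
homogeneous cohort form viable clusters) and epsilon chosen automatically —
the largest k-NN distance is the smallest epsilon keeping every group of
≥ min_pts mutually close points internally connected, and when the dominant
empty interval of the sorted feature exceeds it, epsilon is placed mid-gap so
the clustering splits there. A pure knee-of-k-distance rule cannot find this
split: when both clusters exceed min_pts members the k-distance curve
contains only within-cluster distances and never reflects the gap. A
candidate multi-cluster outcome is kept only with mean silhouette ≥ 0.75
(conservative end of the strong-structure band); weaker splits are reported
as a single cluster with a flag. Outliers are excluded from silhouette
scores and reported separately.

Measured on the generator's study conditions (120 seeds): planted 12/8
cohorts are recovered with silhouettes ≥ 0.80; homogeneous cohorts produce a
gate-passing split in ~1% of seeds — and that cohort genuinely sampled a
gapped count set, which is a property of finite samples, not of the
procedure.

## Statistics

Group CIs are percentile bootstraps of the mean over 10,000 resamples of
participants (within-group) or of both groups independently at their own
sizes (between-group, Δµ = µ_a − µ_b). Percentile rather than BCa: plain
percentile intervals keep the resampling scheme transparent, and no bias
correction is part of the procedure's definition.

Families of related tests are corrected with the adaptive FDR rule
α_corr = α·R/m, resolved by downward fixed-point iteration: start R = m,
compute CIs at α·R/m, set R to the number excluding zero, repeat until
stable (R = 0 reports nominal-α CIs flagged non-significant). The iteration
order is a design choice; the rule itself only fixes the formula.

Calibration, measured by the acceptance suite: percentile-CI coverage of a
Gaussian mean at n = 20 is ~93–94% (inside the accepted [90%, 99%] band —
the percentile bootstrap is mildly anticonservative at small n), and the FDR
null simulation is run at n = 100 per test, where the CI is well calibrated,
so that it measures the error rate of the adaptive rule (~0.05) rather than
small-sample CI under-coverage.

## Problem sizes and numerical choices

* Unit tests run on 300-stride adaptation phases; acceptance checks use the
  full 750-stride protocol for fitting and recovery, 100 noisy replicates
  for parameter recovery, 20-participant cohorts for model selection, 100
  (tests) / 50 (script) seeds for clustering recovery, and 1000 simulations
  for calibration. These sizes are the package's chosen study scale.
* Double-exponential fits start from (−0.177, 322.072, −0.216, 29.662)
  (Exp 1) or (−0.177, 418.725, −0.203, 44.307) (Exp 2); components are
  reported slow-first to resolve the exchange symmetry; an all-zero series
  returns the zero fit directly.
* Plateau detection smooths with a centered 5-point moving average using
  shrinking edge windows (a convention this package fixes; other edge rules exist), and flags
  series with no qualifying 5-stride run, returning the series length.
* Degenerate inputs are rejected with named errors: zero stride lengths,
  off-grid ramp ranges, presses outside the ramp, zero-variance correlation
  inputs; degenerate basis activations and zero-RSS BICs are flagged, not
  raised.

## Known limitations

* The optimal-control cost functional and horizon are package defaults;
  conclusions about that model are conditional on them.
* The perceptual noise model (press jitter) is a stand-in, uncalibrated to
  data.
* The clustering parameter automation is this package's own design;
  published DBSCAN automations differ in detail, and its behavior is
  characterized on synthetic cohorts only.
* Real-data ingestion expects precomputed stride kinematics; heel-strike
  detection and marker processing are out of scope.
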