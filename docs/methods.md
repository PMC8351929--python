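# Methods

## Problem and model

Step events in running — foot-strike (FS) and toe-off (TO) — are conventionally
read off the vertical ground reaction force (vGRF) of an instrumented
treadmill: contact is the phase where vGRF ≥ 50 N, FS its first frame and TO
its last. When no force data are available, this package detects the same
events from kinematics alone. The detection is cast as per-frame binary
sequence labelling: for one gait cycle, four channels sampled at the
motion-capture rate — distal-tibia anteroposterior velocity, ankle
dorsi/plantar-flexion angle (dorsiflexion positive), and the anteroposterior
and vertical velocities of the foot centre of mass — are mapped to a per-frame
probability of ground contact. FS and TO are then the first and last frame of
the predicted contact phase.

The classifier is a stack of two bidirectional LSTM layers, a per-timestep
dense ReLU layer, and a single sigmoid output node. Each LSTM cell follows the
standard gated equations on the concatenated input `[h_{t-1}, x_t]`:

    f_t, i_t, o_t = sigmoid(W [h_{t-1}, x_t] + b)        (gates)
    c_t = f_t ⊙ c_{t-1} + i_t ⊙ tanh(w_c [h_{t-1}, x_t] + b_c)
    h_t = o_t ⊙ tanh(c_t)

In each bidirectional layer a second cell consumes the time-reversed sequence
and the two hidden-state sequences are concatenated, so every frame's output
conditions on both past and future — appropriate here because a cycle is
available in full before events are extracted.

The full-size configuration (2×400 LSTM units, 200 dense nodes, dropout 0.5
after each recurrent and dense layer, Adam on masked binary cross-entropy,
mini-batches of 200 cycles, ≤100 epochs with early stopping after 10 stagnant
validation epochs, best weights restored) is the package default. A
`scaled_down` profile (2×64 units, 32 dense nodes) exists so that the complete
protocol trains in minutes on one CPU; the package's own tests and the
acceptance script use it.

The network, backpropagation through time and the Adam optimiser are
implemented directly in NumPy. This keeps the arithmetic transparent and lets
the test suite verify the cell equations against independent scalar-loop
oracles to 1e-6.

## Ground truth, QC and preprocessing

* Trials are divided into cycles at successive apices of the foot-COM vertical
  position (local maxima; a plateau of equal maxima takes its first index).
* Instrumented treadmills show aberrant plateaus/bumps in the vGRF near
  toe-off. A cycle is discarded when, in the interval where the vGRF drops
  from 100 N to 50 N (anchored at the *last* downward crossing of 100 N —
  the rule targets the unloading tail, not the loading phase), any
  frame-to-frame loading rate reaches +200 N/s (at 200 Hz: 1 N per frame).
  A trace that never reaches 100 N is accepted with an "interval absent" note.
* Contact labels are thresholded on the **raw** (unfiltered) vGRF at 50 N
  (≥ 50 N is contact, boundary inclusive). The first and last contact force
  frames are converted to times and rounded to the nearest mocap frame;
  round-half-up on `time × rate` breaks ties, since "closest frame" alone does
  not define one.
* Position and angle channels are smoothed with a 4th-order zero-lag
  Butterworth filter at 10 Hz (forward–backward, so the effective attenuation
  order is 8; even/reflective padding of 3·(order+1) samples fixes the edge
  convention). Velocities use central differences (one-sided at the ends),
  computed after filtering.
* Model inputs are z-scored per channel with mean/SD from the **training**
  cycles only, then zero-padded at the *start* to a fixed 200 frames, enough
  for a full stride at any supported speed. A cycle longer than 200 mocap
  frames is an error.
* Splits always operate on participants, never cycles: 30% of participants per
  dataset form the test set; the rest are dealt round-robin into 5 folds
  stratified by dataset. Cross-validation trains one model per held-out fold
  and refits the winner on all folds for final testing.

### Masking semantics

The padded prefix must be inert. The recurrence is therefore gated by the
sample mask: at masked timesteps the cell and hidden states pass through
unchanged, so no value stored in padding can reach a real frame's output, and
the loss and accuracy are computed over unmasked frames only. The output
probability over the fully padded prefix is exactly 0.5 (a zero logit
placeholder). The reported accuracies always exclude padded frames; whether
published figures for comparable detectors include them is typically unstated,
so reports say so explicitly.

## Event extraction and assessment

Predicted probabilities are binarised at 0.5 (the sigmoid midpoint; exposed as
a flag for calibration studies) and the **longest** contiguous supra-threshold
run becomes the contact phase — robust to isolated spurious frames in the
swing, unlike a first-run rule. Detection errors are `predicted − force truth`
in ms (positive = late detection / longer contact); by construction the
contact-time error equals the TO error minus the FS error.

Because frame-quantised event errors are heavily discretised and non-normal,
agreement is summarised non-parametrically: bias = median error, 95% limits of
agreement = 2.5th/97.5th percentiles (linear interpolation between order
statistics — other percentile conventions shift limits by up to one sample
spacing, so the choice is fixed and documented). Normality is tested with a
Kolmogorov–Smirnov test against a normal with estimated mean/SD; estimating
the moments from the sample makes the p-values anti-conservative
(Lilliefors-style caveat), but the non-parametric estimates are what the
report carries either way. RMSE is reported per event type. Associations
between errors and speed, foot-strike angle or incline use Pearson's r with
magnitude bands trivial (<0.1), small (≥0.1), moderate (≥0.3) and large
(≥0.5), boundaries inclusive on the left; OLS slope/intercept and r² are
attached for non-trivial correlations (α = 0.05 throughout).

The sensitivity analysis shifts each ground-truth event by −5…+5 frames
(excluding 0) and records the change in sagittal hip/knee/ankle angle at the
shifted frame. Cells are banded by their **mean absolute error**: <2°
acceptable, 2–5° reasonable, >5° unacceptable. The statistic behind the
banding was a genuinely open choice (per-cycle proportions would be an
alternative); mean absolute error is used because the distributions' means are
what the banding most naturally summarises. Offsets falling outside a cycle
exclude that cycle from that offset and are counted in the report.

## Synthetic data generator

The generator produces labelled cycles so that every stage is testable without
laboratory data. What it emulates:

* **Study conditions.** Speeds 2.5–5 m/s; rearfoot/midfoot/forefoot strike
  mix 0.7/0.1/0.2 (the approximate participant-level mix across typical
  treadmill cohorts); optional inclines; mocap 200 Hz / force 1000 Hz by
  default (150/300 Hz combinations are equally valid, the force rate must be
  an integer multiple); body mass ~N(70, 8) kg clipped to [50, 95].
* **Timing.** Cycle duration falls from 0.9 s at 2.5 m/s to 0.6 s at 5 m/s
  and duty factor from 0.45 to 0.30, both with small per-cycle jitter — the
  physiological trend; the exact mapping is a free modelling choice. Contact
  starts ~22% into the cycle (cycles run apex-to-apex, so they open
  mid-swing). Durations snap to the mocap grid and contact boundaries to the
  force grid, which makes nearest-frame mapping exact and lets noise-free
  recovery be asserted at 100%.
* **vGRF.** A raised-cosine active peak spanning contact, scaled so the
  50 N crossings fall exactly on the recorded contact boundaries (peak
  ≈ body weight × (1.7 + 0.25·speed)), plus a short early-stance impact
  transient for rearfoot strikers. QC violations are injected as a one-frame
  positive step of 400 N/s inside the 100→50 N unloading tail, confined to
  (50, 100) N so contact boundaries and interval anchors are untouched.
* **Kinematics.** Piecewise-cosine/spline curves phase-locked to contact:
  AP velocities sit at −belt speed during stance and swing forward to
  ~2.4× speed; the foot-COM height peaks exactly at the cycle boundary (the
  segmentation convention); ankle/hip/knee angles are periodic cubic splines
  through physiologic keypoints, with the ankle angle at contact equal to the
  foot-strike angle (positive/dorsiflexed for rearfoot, negative for
  forefoot strikers).
* **Noise.** Added only after the truth record is fixed. The scalar
  `noise_sd` is relative (fraction of each kinematic channel's RMS; a mapping
  of absolute per-channel SDs is also accepted); noisy kinematics are then
  re-smoothed with the standard 10 Hz zero-lag filter, emulating preprocessed
  mocap channels. Force noise (`vgrf_noise_sd`) is separate and defaults to
  0 N because the QC rule differentiates the force frame-to-frame; broadband
  noise at kilohertz force rates would reject essentially every cycle and
  make the injected-violation rate meaningless.

What it does **not** emulate: marker-level artefacts (soft-tissue motion,
marker loss), inter-laboratory differences in treadmill stiffness or marker
sets, belt-speed fluctuation, pathological gait, or overground running.
Consequently, passing tests demonstrate that the pipeline's machinery is
correct and that the detector can recover contact phases from smooth
contact-locked kinematics under moderate noise — not that the trained synthetic
model transfers to real runners. For real data the full-size configuration
should be retrained on force-labelled cycles.

## Numerical choices

* Default training dtype float32 (single-CPU throughput); weights initialise
  Glorot-uniform with forget-gate bias 1, seeded. Cell-level verification and
  the statistics run in float64.
* The logistic function is evaluated as `(1 + tanh(z/2))/2`, which is stable
  and fast; Adam uses the conventional defaults (step 1e-3, β₁ 0.9, β₂ 0.999,
  ε 1e-8) — the step size is a backend default, not a tuned value.
* Fully padded batch-prefix columns are skipped in the forward/backward pass;
  under the gated recurrence this is an exact no-op.
* Thresholding ties: a vGRF or probability exactly at threshold counts as
  contact. Equal-length probability runs take the earliest. Equal apices take
  the first index.
* Degenerate inputs raise explicit errors: zero-variance channels in a
  training scaler, cycles over 200 frames, traces with no contact, constant
  inputs to a correlation, fewer than 3 points for Bland–Altman.

## Study sizes used by the tests and the acceptance script

The seeded end-to-end study uses 14 synthetic participants × 108 cycles
(~1 500 cycles; ~5% carry injected QC violations), mixed strike patterns,
speeds 2.5–5 m/s, relative kinematic noise 0.05, the scaled-down model
profile, and at most 15 training epochs — sizes chosen so the whole protocol
(generation through evaluation) completes in a few minutes on one CPU while
leaving ample signal for the published-style assessment. The cross-validation
protocol itself is exercised on smaller folds; the full-size model
configuration is unchanged as the package default for real use.

## Known limitations

* The synthetic waveforms are qualitative: no published numeric
  characterisation of the kinematic channels exists to validate against, so
  generator realism is qualitative by construction.
* The QC rule and contact threshold are fixed at their conventional values
  (200 N/s, 50 N, 100→50 N window) and not configurable per dataset.
* Event timing is frame-resolution; no sub-frame interpolation.
* The KS normality p-value is anti-conservative (estimated moments).
* Training determinism holds for a fixed BLAS/backend; across backends
  floating-point reduction order may differ.
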