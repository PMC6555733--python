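# Methods

`gaitpower` estimates steady-state metabolic power (W) during walking from
ground reaction forces (GRF) and electromyography (EMG), either once per gait
cycle or once per fixed four-second interval, and quantifies how well such
estimators generalize to unseen conditions and unseen subjects.  This note
documents the models, the processing choices, the synthetic data the package
is validated on, and the limits of what those validations show.

## Ground truth: indirect calorimetry

Metabolic power is computed per breath with the Brockway equation using the
gaseous terms only,

    P [W] = (16.58 · V̇O2 + 4.51 · V̇CO2) · 1000 / 60,

with V̇O2 and V̇CO2 in L/min.  The urinary-nitrogen term cannot be measured
from gas exchange and is neglected, as is conventional in exercise
physiology.  A condition's label is the unweighted mean of per-breath power
over the final 120 s of the recording ("last two minutes"), once the subject
is at steady state.  Breaths are averaged with equal weight rather than
time-weighted; for quasi-regular breathing the two differ negligibly.

## Signal conditioning

All filters are 4th-order Butterworth, applied zero-phase
(forward-backward via `scipy.signal.sosfiltfilt`, with its standard
odd-reflection edge padding).  Zero-phase filtering is the norm in gait
analysis, where timing alignment between channels matters; the caveat is
that the effective magnitude response is the square of the single-pass
response, which the tests account for.

* GRF: 30 Hz low-pass.
* EMG: 30–500 Hz band-pass → full-wave rectification → 6 Hz low-pass
  (linear envelope) → division by the envelope maximum of the same muscle
  during the subject's normal-walking trial.  The normalizer is taken on the
  processed envelope rather than the raw rectified signal; this choice is
  exposed in the configuration.
* Raw mode (the "raw subject" use case): no filtering at all; EMG channels
  are only rectified and not normalized.

Heel strikes are rising crossings of the right vertical GRF through 30 N
(sample `i` with `x[i-1] < 30 ≤ x[i]`), with a 0.5 s refractory period.
30 N sits far above the filtered-noise floor and far below bodyweight; the
refractory period rules out within-stance chatter at walking cadences.

## Segmentation and features

*Per gait cycle*: signals are sliced half-open between consecutive right
heel strikes.  Each channel of a cycle of length L is averaged into 30 bins
with boundaries `round(b·L/30)` (half-up); this keeps bin widths within one
sample of each other, tiles the cycle exactly, and conserves the
width-weighted channel mean.  Bins are concatenated in channel order, giving
a vector of length 30 × C (660 for the 22-channel assisted design).  Every
cycle of a condition inherits the condition's steady-state power as its
label — there is no per-cycle ground truth.

*Fixed interval*: consecutive non-overlapping 4 s spans, block-averaged
every 32 samples; at 2000 Hz this yields 250 time steps per window.  A
trailing partial span is discarded.

## Estimators

* **Linear**: ordinary least squares `y = aᵀx + b`, no regularization or
  feature selection.  `lstsq` is called with a numerical-rank cutoff of
  1e-9 relative to the largest singular value: directions below it carry no
  target signal, and inverting them would amplify round-off into
  out-of-sample noise on near-degenerate designs.  On rank-deficient designs
  the minimum-norm solution is returned with a logged warning.
* **Feedforward network**: 3–4 hidden ReLU layers of 300–1000 units
  (default 3 × 512, the midpoints of the band), dropout (0.2) and L2
  (1e-4) on hidden layers, linear output unit, mean-absolute-error loss.
* **Recurrent network**: two stacked LSTM layers of 64 units over the
  250-step windows, followed by a fully connected scalar head; trained with
  mean-squared error, evaluated with mean absolute error.

Both networks are implemented directly in NumPy (forward pass, manual
backpropagation, Adam at learning rate 1e-3, batch 64/32).  Inputs and
targets are standardized internally; predictions are returned in Watts.
Training optionally early-stops on a 10% in-training holdout.  One integer
seed drives initialization, dropout masks, and shuffling, so the same seed
and data reproduce predictions bit-for-bit.  Dropout is applied to hidden
layers only, and the LSTM clips the global gradient norm at 5 for
stability.

## Evaluation protocol

Fold count always equals the subject count; accuracy is averaged across
folds.

* *Novel condition*: per fold, `round(0.10 · n_pairs)` random
  (subject, condition) pairs are held out — not necessarily the same
  conditions for every subject.
* *Novel subject*: leave-one-subject-out.  Variants: *subject vertical
  force* (inputs restricted to vertical GRF + EMG) and *raw subject*
  (unfiltered inputs), reusing the same folds.
* *Both-novel*: one subject held out together with two condition ids
  removed from every subject's training data; only those conditions of the
  held-out subject are estimated.  The held-out conditions are resampled
  per fold from a seeded generator.

Percent error is computed per condition as 100 · MAE / true power, averaged
condition-first within a fold and then across folds (sample-first averaging
is available as a flagged alternative in `compute_metrics` consumers).
RMSE and MAE in W are divided by the mean mass of the test subjects
(W/kg).  Condition-level estimates used for ordering are the mean of that
condition's per-sample estimates.

Ordering across a subject's conditions is scored pairwise with a three-way
outcome: the first value is *greater than*, *within*, or *less than* a
threshold of the second, where *within* means `|v_i − v_j| ≤ 0.042 · v_j`.
The 4.2% threshold corresponds to the uncertainty of respirometry shortened
to two minutes; it is applied relative to the second member of the pair (the
reference is configurable).  The rank confusion matrix puts true rank on
rows and estimated rank on columns, accumulating one count per subject and
normalizing by the subject count, so perfect estimation yields the identity
and every row and column of a complete matrix sums to 1.

## Synthetic study designs

The generator emulates the two treadmill designs the pipeline targets:

* `assisted`: 22 channels (3-axis GRF × 2 feet, 8 muscles × 2 legs), nine
  assistance strategies with net work −40…+40 J/cycle, mass 77.5 ± 5.6 kg,
  metabolic model `P = 4.43 W/kg · m − 1.9 W per J/cycle · w`, spanning
  roughly 270–420 W (mean ≈ 343 W).
* `incline_load`: 14 channels (6 GRF, 8 right-leg muscles), 4 loads
  (0–30% bodyweight) × 3 inclines (0/5/10% grade) = 12 conditions, mass
  68.8 ± 11.5 kg, `P = m·(2.7 + 50·grade + 15·load) W`, spanning roughly
  190–890 W.

Signals are analytic: the vertical GRF is a double-peaked stance waveform
scaled by `1.05·(1+load)·m·g` whose first stance sample is 15% of peak —
far above the 30 N threshold — so planted strike indices are recovered
exactly by the detector; shear axes are phase-locked low-amplitude
waveforms; EMG channels are 30–500 Hz band-limited carriers modulated by
Gaussian activation bursts at muscle-specific gait phases.  Burst amplitude
responds linearly to incline, load, and assistance with muscle-specific
coefficients (plantarflexors respond most to incline, quadriceps to load),
so the condition parameters are separately identifiable from the envelopes.
Breaths invert the Brockway equation at a fixed respiratory exchange ratio
of 0.85 with multiplicative noise (CV 3%).  Subject heterogeneity enters as
mass variation plus an additive per-subject power offset (sd ≈ 8% of mean
power) — the minimal structure that makes novel-subject estimation
measurably harder than novel-condition estimation.  Everything is
determined by one seed through spawned per-subject/per-condition
generators.

**Planted-linear mode** is the full-pipeline correctness oracle: all noise
and stride jitter are zero, EMG carriers are deterministic sinusoids
phase-locked to the cycle, the GRF amplitude is held constant (800 N)
across all trials so that detected cycle boundaries are identical
everywhere, and the true power is an exact linear map of the condition
parameters (intercept 300 W, 1200 W per unit grade, 250 W per unit load
fraction, −1.9 W per J/cycle).  Because the binned features then encode
those parameters exactly linearly, ordinary least squares must reach ~1e-7 W
test error on *every* cross-validation split — any regression in filtering,
detection, segmentation, binning, labeling, or splitting breaks this.  The
constant amplitude is deliberate: with mass-scaled GRF, the fixed 30 N
threshold is crossed at slightly amplitude-dependent times on the filtered
signal, which would shift cycle boundaries per subject and (correctly but
unhelpfully for an oracle) break exact linearity.

### What the generator does not emulate

Real gait variability (kinematic drift, fatigue, step-to-step neuromotor
noise), EMG nonstationarity and electrode artifacts, cross-talk between
muscles, force-plate crosstalk, non-steady-state metabolic transients, and
any nonlinear condition→signal coupling.  Passing tests therefore
demonstrate the correctness of the pipeline and the qualitative
generalization structure (condition < subject ≈ both-novel difficulty, high
ordering accuracy), not field accuracy on human data.

## Problem sizes used in tests and the acceptance script

Validation runs use 6 subjects (the assisted study's retained count) with
25 s of signal per condition — about 22 gait cycles per condition and
~1200 cycles per dataset, chosen so the 661-column OLS design is
comfortably overdetermined while keeping a full multi-seed evaluation on a
single CPU in minutes.  (At much shorter trials the linear model enters its
interpolation regime, m < n, and novel-condition error becomes unstable —
the real studies' several-minute recordings correspond to thousands of
cycles.)  The planted-linear oracle uses 12 s trials (~540 cycles).  The
feedforward configuration for these runs is 3 × 300 units, 40 epochs,
early-stopping patience 8.

## Known limitations

* The recurrent model is validated on representable synthetic targets and
  shift-augmented data, not on the full synthetic study designs (training
  it there is computationally disproportionate to what it would add).
* Percent-error averaging order (condition-first) and the ordering
  threshold reference (second pair member) follow common reading of the
  protocol; both are configurable.
* The EMG normalizer uses the processed envelope maximum; using the raw
  rectified maximum instead rescales features per muscle by a constant and
  leaves linear-model fits unchanged.
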