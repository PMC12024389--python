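# Methods

This note documents the models, the synthetic-data generator, and the
numerical choices behind `equigait`, in the spirit of a methods appendix.

## Problem setting

A rider wears tri-axial accelerometers (units of g; x points toward the
ground, so gravity reads +1 g at rest; z points away from the rider) at up
to four body sites: knee, backbone, chest, arm. Streams are nominally 50 Hz.
Ground truth is an interval annotation with 11 fine activities — halt plus
collected/medium/normal variants of walk, trot and canter — which collapse
onto 4 gait superclasses. The task is 4-way window classification, and the
experimental questions are which of eight architectures, which window length
(0.6–6 s), which rate (5/10/25/50 Hz) and which sensor site classify best,
judged on data from horses never seen in training.

## Synthetic cohorts

Real rider-worn recordings of this kind are not redistributable, so the
package ships a generator that emulates their *statistical structure* rather
than their biomechanics:

* **Bouts.** A session is tiled by activity bouts with lognormal durations
  (median 6.3 s, shape 0.5, truncated at 1 s — the observed median bout
  length in mounted training data). Gaits are drawn with probability equal
  to the target class mix; since durations are identically distributed
  across gaits, expected time share equals the mix. The default mix (walk
  0.434, trot 0.396, canter 0.136, halt 0.034) reproduces the reference
  cohort's class imbalance.
* **Signals.** Each moving gait is a sum of 3 phase-locked harmonics of a
  stride fundamental per axis, plus white Gaussian noise. Defaults: walk
  0.9 Hz (fundamental dominates), trot 1.3 Hz with a dominant 2nd harmonic
  at 2.6 Hz (a 2-beat gait ridden rising, so the rider strongly imprints
  the stride rhythm; the fundamental is also boosted), canter 1.7 Hz with
  an asymmetric 3-beat overtone mix. Amplitudes grow with gait speed
  (dominant x-axis amplitudes ≈ 0.25 / 0.55 / 0.65 g), so both spectral
  location and power separate classes. Halt is gravity plus noise only.
  These are simulator defaults chosen inside physiologic stride ranges so
  that the four classes are learnable yet imperfectly separated across
  horses; nothing in the source study constrains signal spectra.
* **Horses.** Each horse gets a stride-frequency multiplier ~ U(0.9, 1.1)
  and an amplitude multiplier ~ U(0.85, 1.15). Cross-horse generalisation —
  the point of subject-exclusive validation — is therefore a real gap: a
  held-out horse's canter band can approach the training horses' trot band.
  An optional *aberrant* horse (stride scale 1.5) emulates the reference
  cohort's dominant horse whose held-out fold collapses; an optional
  halt-free horse emulates the horse that never halted.
* **Locations.** One ride is drawn per horse (bouts, variants, jitters,
  phases), and all four location streams render that same ride — four
  sensors worn simultaneously — differing only in coupling gain and added
  rider-motion noise: knee (1.0, 0.01 g) ≥ arm (0.85, 0.03) > backbone
  (0.70, 0.06) ≥ chest (0.60, 0.08), mirroring the finding that the knee,
  nearest the horse's centre of mass, couples best.
* **Determinism.** All draws come from seeds derived by CRC32 from
  (cohort seed, horse, location, role), so a cohort is bit-reproducible and
  per-session output does not depend on generation order.

What the generator does **not** emulate: rider-horse coupled dynamics,
gait-transition artefacts, sensor drift or clipping, orientation changes,
gyroscope channels. Passing tests on synthetic cohorts therefore demonstrate
the pipeline's correctness and the qualitative study conclusions, not field
performance on real recordings.

## Preprocessing

* **Pure windows.** Samples are labelled by superclass (half-open interval
  convention; the study leaves boundary handling unstated) and grouped into
  maximal single-superclass runs; a run of *m* samples yields
  `floor((m − L)/step) + 1` windows of length `L`, none if `m < L`. Windows
  never cross a bout boundary, so each carries exactly one label.
  `overlap_fraction` defaults to 0 (non-overlapping windows) to avoid
  train/validation leakage through shared samples.
* **Decimation.** 50 Hz streams are resampled to 25/10/5 Hz by keeping every
  k-th sample from index 0 — no interpolation or anti-alias filtering, which
  is why only divisors of 50 are admitted. The synthetic harmonics extend to
  about 5.1 Hz, above the 2.5 Hz Nyquist limit of the 5 Hz rate, so the
  lowest rate aliases the upper harmonics — part of what makes small rates
  harder, as observed in the study design.
* **Scaling.** Per channel, pooled over all training samples: subtract the
  median, divide by the IQR (linear-interpolation quantiles; a constant
  channel keeps divisor 1). The scaler is fitted on the training split only
  and applied unchanged to validation data.

## Architectures

All eight models map a scaled (L, 3) window to 4 logits and train with
softmax cross-entropy and Adam on an in-package numpy engine (explicit
backpropagation; seeded initialisation, shuffling and dropout). Where the
roster fixes sizes they are honoured exactly (MLP 128/64; CNN 8 filters,
28 hidden; dilated CNN 7 filters, 42 hidden; spatial-dropout CNN 120
filters, kernel 15, 5% channel dropout, LSTM 256, dense 512; LSTMs 2 × 4
and 2 × 32 cells; conv-LSTM 8 filters, (1,1) kernel and stride, dropout
0.5, dense 64). Unstated kernel sizes default to 3; dilated variants use
doubling dilation rates; the WaveNet-style network uses 4 gated causal
blocks (kernel 2, dilations 1–8, 16 residual / 32 skip channels) with
residual and skip connections.

The convolutional LSTM uses the standard inertial-window layout: the window
is split into 4 recurrent steps over a (1 × L/4) spatial grid of 3-channel
samples, so (1,1)-kernel gate convolutions act as a position-wise LSTM with
shared weights, and the final hidden state is flattened into the dense head.
(The degenerate alternative — a 1 × 1 spatial grid with L time steps — is a
plain 8-unit LSTM; it trains far less reliably at these data sizes.)

Published trainable-parameter totals for these architectures cannot be
reconstructed from their textual descriptions under standard parameter
formulas (e.g. a 2 × 4-cell LSTM already exceeds the quoted 342), so
parameter counts here are validated against closed forms for our resolved
shapes, not against the quoted totals.

## Training and evaluation protocol

* **Grid.** 8 models × 13 windows × 4 rates × 4 locations = 1664
  configurations, each trained 15 epochs on all horses except a fixed
  validation horse and scored on that horse (accuracy and macro F1, percent,
  2 decimals). Per-configuration seeds derive from the master seed and the
  configuration tuple, so results are independent of sweep order, and a
  failing configuration is flagged rather than aborting the sweep.
* **Selection rules.** General parameters (model, location) maximise the
  *average* accuracy over configurations sharing the value; parameters
  dependent on an already-fixed choice (window or rate given the model)
  maximise the *maximum*. Ties break toward grid order.
* **LOSOCV.** One fold per horse holding at least `min_fraction` (default
  0.07) of all labelled samples; smaller horses are never validated on but
  remain in every training set (the reference study excluded its two
  smallest horses, 4.39% and ~6.4% of samples, from validation only). Fold
  metrics are unweighted means; `mean_accuracy_excluding[h]` re-averages
  without fold h. Macro F1 averages per-class F1 over classes present in
  truth or prediction; with fold-wise unweighted averaging, the reference
  fold table reproduces the reported 89.72% / 98.31% accuracy means and the
  96.21% F1 mean.
* **Optimisation defaults.** Batch size 16 and Adam at 3e-3 (epochs 15,
  dropout 0.5). The scaled-down cohorts have hundreds of windows rather
  than hundreds of thousands, so an epoch is a few dozen optimisation
  steps; at conventional large-data settings (batch 64, 1e-3) every
  architecture underfits within 15 epochs. Both are plain parameters of
  `TrainConfig`.

## Problem sizes

Default synthetic cohort: 5 horses × 4 locations × 600 s sessions at 50 Hz
(50 minutes of riding observed by four sensors). The scaled-down grid used
in tests is 3 models × 3 windows × 2 rates at the knee (18 configurations).
These sizes keep a full run on one CPU in minutes while leaving enough
windows (~450 training windows at 4 s / 25 Hz) for the deep models to train.

## Known limitations

* Held-out-horse accuracy on a 5-horse cohort is inherently seed-sensitive:
  with four training horses, an unlucky draw leaves the held-out horse's
  canter band between the training horses' trot and canter bands, and
  accuracy for that fold can drop 10–20 points — the same phenomenon the
  reference study saw in its dominant-horse fold. Fold means over all
  horses are considerably more stable.
* The spatial-dropout CNN (≈1.2 M parameters, 256-cell LSTM) is two orders
  of magnitude slower to train on the numpy engine than the small models;
  it is excluded from the scaled-down grids for that reason, not on merit.
* Macro-F1 averaging across folds is one of several defensible conventions
  (per-fold macro F1, unweighted over folds); pooled or weighted variants
  give slightly different numbers, and the reference study does not state
  its choice.
* The Welch location comparison is implemented and tested, but its p-values
  on synthetic cohorts carry no information about real sensor placements.
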