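# Methods

This note records the models, conventions, and design decisions behind the
package, in the order data flows through the pipeline.

## Synthetic cohort generator

**What it emulates.**  A clinical resting-ECG archive: 10-s, 12-lead records
stored in WFDB format at 16-bit / 1 µV/LSB, with ages on [0, 95] years, a
left-skewed age distribution (median 62, interquartile range 22), a
patient-level 10-fold split, and per-beat fiducial annotations (P onset,
QRS onset/offset, T offset) bounding the PR, QRS and QT intervals.

**Beat model.**  Each beat is a sum of five Gaussian waves.  Wave centers and
widths derive from three conduction intervals; annotations are placed from
the same intervals, so a mask computed from the annotations removes exactly
the generating feature (lengths agree to one sample, the rounding limit).
Leads are a fixed rank-1 projection of the base waveform (weights in
[−1, 1], one negative lead so polarity-sensitive operations are
distinguishable), plus sinusoidal baseline wander (0.05 mV at 0.3 Hz,
random phase per lead) and white measurement noise (0.02 mV).

**Age dependence.**  Every age-dependent quantity is linear with Gaussian
noise, `q(age) = intercept + slope·age + N(0, sd)`, with defaults

| quantity | intercept | slope / year | noise SD |
| --- | --- | --- | --- |
| heart rate | 78 bpm | −0.08 | 3.9 |
| PR interval | 0.14 s | +0.0004 | 0.007 |
| QRS duration | 0.085 s | +0.0003 | 0.00425 |
| QT interval | 0.36 s | +0.0006 | 0.018 |
| R amplitude | 1.2 mV | −0.004 | 0.06 |
| T amplitude | 0.3 mV | −0.001 | 0.015 |

Directions follow the healthy-aging ECG literature (slowing rate, lengthening
conduction intervals, shrinking amplitudes); magnitudes are deliberately
modest stand-ins (noise SDs are 5 % of the intercepts), strong enough that
age correlates with annotated PR duration at r > 0.5 across a cohort — the
signal the regression networks are asked to recover.

**Age distribution.**  Skew-normal, shape −4, truncated to [0, 95].  Location
and scale were solved once by deterministic quantile matching so the
truncated distribution has median 62.0 and IQR 22.0 exactly (loc 79.6,
scale 26.2).  A plain skew-normal with "nice" location/scale values misses
both targets badly once truncated, which is why the constants look odd.

**What it does not model.**  Pathological rhythms, ectopy, sex or disease
covariates, realistic dipole physics, beat-to-beat morphology variation
within a record.  Passing tests therefore demonstrate that the *pipeline*
(masking arithmetic, fold hygiene, training mechanics, freeze behavior,
complexity accounting) is correct, not that any accuracy number transfers to
clinical recordings.

## Preprocessing conventions

* **Pad-to-grid.**  Model input lengths are the raw sample count zero-padded
  (at the end) to the next multiple of 1,024.  This is the only convention
  consistent with the published operating points: 10 s at 100 Hz → 1,024,
  10 s at 500 Hz → 5,120, 6 s at 500 Hz → 3,072, and +1,024 samples per
  additional 100 Hz.
* Intermediate rates (200–400 Hz) are always interpolated upward from the
  100 Hz signal, never decimated from 500 Hz.  Interpolation is cubic-spline
  by default (`linear` and `fourier` are config options); the 500 Hz
  condition of a synthetic sweep is synthesized natively at 500 Hz.
* Stretch-to-length is interpolation (beat count preserved), not padding.

## Augmentation and corruption

Flip (amplitude negation) and reverse (time reversal) are involutions applied
to a whole batch with one Bernoulli(0.5) draw per batch; both act identically
across leads, preserving cross-lead alignment.  Random crop is applied with
probability 1 and draws one start offset per *record* (integer samples,
uniform over the admissible range; a `crop_per=batch` switch recovers the
weaker one-offset-per-batch reading).  Evaluation of crop-trained models uses
the deterministic first-k-seconds window.

Corruption selects each lead independently with probability 0.25 and zeroes,
per beat, the scheme's fiducial interval — PR `[P_on, QRS_on)`, QRS
`[QRS_on, QRS_off)`, QT `[QRS_on, T_off)`.  The random variant removes a
window of the matched feature's mean length at a uniform onset inside each
beat span, so systematic and random corruption delete equal information and
remain comparable.  The replacement value is 0 mV (the baseline; `hold` and
`noise` fills are config options).  Corruption applies to both training and
evaluation batches of a corruption experiment, with a train-only switch.

## Architectures and calibration

Both networks are explicit layer graphs over a small NumPy layer stack
(conv1d, batch norm, ReLU, max pool, dropout, flatten, linear) with
hand-written backward passes and Adam; activations are stored channels-last
for single-CPU speed.

**AttiaNet.**  Eight temporal blocks (convolution → batch norm → ReLU → max
pool) whose weights are shared across the 12 leads, a spatial block whose
kernel spans all leads' stacked features, and an MLP head ending in one
scalar.  The committed free dimensions are

* temporal filters (16, 16, 32, 32, 64, 64, 64, 64);
* kernel schedule (7, 5, 5, 5, 5, 5, 3, 3) — 7 initial, 5 intermediate, 3 deep;
* pool windows (1, 1, 1, 1, 4, 4, 2, 2), spatial block 12 filters + pool 2
  (net temporal reduction 128);
* head widths (16, 893, 561).

This configuration reproduces all five published per-rate parameter totals
exactly (593,505 / 595,041 / 596,577 / 598,113 / 599,649, slope 1,536 per
1,024 samples) *and* the 1.57 G forward mult-adds at the 5,120-sample input.
Those joint constraints force the late pooling: with uniform pools of 2 the
parameter totals can only be met at a per-sample compute roughly 7× lower
than published.  The bottleneck-then-wide head (16 → 893 → 561) is likewise
forced: the parameter slope pins `(flattened features × first width)` per
sample, and the remaining ~0.5 M parameters must sit in
length-independent layers.

**ResNet1D.**  Initial conv (12→64, kernel 17) + BN/ReLU, then four residual
blocks: main path conv17 → BN → ReLU → dropout → conv17 (second conv strided
×4), skip path maxpool(4) → 1×1 conv, merged before the closing
BN → ReLU → dropout.  Channels 64→128→192→256→320; dropout 0.5 (parameter
counts are unaffected); head widths (16, 600, 300) → 1.  This reproduces all
five published totals exactly (6,940,065 … 7,021,985; slope 20 per sample):
given the fixed trunk, the head is the unique three-hidden-layer solution
with first width 16 at reduction 256.  A head that connects the flattened
features directly to the output unit — the phrasing used in the source
description — is arithmetically incompatible with those totals; the printed
numbers won.

**Fine-tuning freeze.**  `freeze_scope("through_resblock3")` freezes the
initial block, residual blocks 1–3, and the MLP head's hidden layers; the
fourth residual block and the scalar output layer remain trainable, and
frozen batch norms run on stored statistics.  Trainable parameters at the
10-s/400 Hz input: 3,217,901 → 3.22 M, matching the published freeze count;
treating the whole head as trainable would give 3.49 M instead, which is why
the hidden head layers belong to the frozen scope.

**Reduced variants** (`ATTIA_REDUCED`, `RESNET_REDUCED`) are deliberately
small configurations of the same families (4 temporal blocks / 4 thin
residual blocks with kernel 9) used for the desk-scale training studies; the
problem sizes quoted below were chosen so each study completes in minutes on
one CPU.

## Complexity accounting

One *mult-add* = one fused multiply-accumulate, batch size 1, forward pass
only; convolution bias additions, normalization, activations and pooling are
excluded; lead-shared temporal convolutions cost 12× their single-lead
mult-adds while contributing parameters once.  Disk size is decimal MB at
4 bytes (float32) per parameter (593,505 × 4 B = 2.37 MB reproduces the
published AttiaNet figure, confirming the decimal convention).  Batch-norm
scale/shift count as 2 trainable parameters per channel; running statistics
are reported separately as buffers.

Counts are derived purely from layer descriptors (kernel, channels, stride,
feature-map length) and cross-checked in the tests against the instantiated
weight arrays layer by layer.

**Known irreconcilable quantity.**  The published ResNet1D mult-add figure
(143.97 G at the 1,024-sample input) cannot be produced by any per-record
convention: a forward pass reuses each parameter at most `max feature
length` times, so 6.94 M parameters at length 1,024 bound the count by
7.1 G.  The figure is consistent with a batch-96 measurement
(143.97/96 ≈ 1.5 G per record), but that convention would put the AttiaNet
column below the cost of its first convolution alone, so no single
convention reproduces both tables.  The accountant reports the honest
batch-1 value (0.48 G); the published 458× ResNet/Attia ratio inherits the
same inconsistency.

## Training harness

Loss is mean squared error on age; optimizer Adam (lr 10⁻³, β = 0.9/0.999,
ε = 10⁻⁸ — only the learning rate is part of the published protocol);
batch size 96; 200 epochs with the rate cut ×10 after every 80 epochs
(10⁻³ → 10⁻⁴ at epoch 81 → 10⁻⁵ at 161).  For test fold *f*, fold
(*f*+1) mod 10 is the holdout validation set and the remaining eight folds
train; the published protocol names a holdout validation set without
defining it, so this rotation is explicit and configurable.  Weights are
checkpointed whenever validation MSE strictly improves and restored before
test evaluation; reported cross-validation metrics are unweighted means over
folds.  All randomness (batch order, augmentation, corruption, subset
draws, weight init) flows from one seed through spawned, logged streams, so
any run repeats bit-identically.

## Transfer protocol

The cross-population shift is modeled by perturbing every age→morphology
slope by ±20 % and redrawing the lead projection — a controllable analog of
population-level waveform variability.  One network is pretrained on the
source population; for each subset size *n*, *n* target training records are
drawn uniformly without replacement (independent draws per size; a `nested`
flag exists) and the fine-tuned arm (freeze above) is paired with a
scratch-trained arm on the identical subset and identical target test fold.
Zero-shot evaluation (pretrained weights untouched) quantifies the raw gap;
only orderings are asserted, not values.  At desk scale (3,000 records per
population, reduced ResNet, 12 epochs, smallest subset 125) the orderings
are decisive: zero-shot ≫ scratch-on-full-target, and fine-tuning beats
scratch training at the smallest subset in 10/10 seeds.

## Numerical and degenerate-input choices

* float32 throughout the networks; batch-norm batch statistics accumulate in
  float64 before casting.
* Max-pool backward routes the subgradient by exact float comparison with
  the stored maximum; ties (essentially only post-ReLU zeros) split the
  gradient, which the following ReLU backward zeroes anyway.
* Same-padding keeps conv output length = ⌈input/stride⌉ so the grid
  arithmetic stays exact.
* Interval draws that violate positivity/order constraints are redrawn
  (bounded retries); a record shorter than one full P-to-T-offset beat span
  yields an empty annotation list, which masking rejects explicitly.
* `pad_to_grid` rejects empty signals; builders reject inputs off the
  1,024 grid or shorter than the stacked pooling reduction.

## Limitations

* The NumPy harness targets desk-scale studies; full 200-epoch, 20k-record
  runs are out of its intended range.
* The synthetic cohort's rank-1 lead projection makes leads more redundant
  than real ECGs, so per-lead corruption is more forgiving here than in
  clinical data.
* Published headline errors on the clinical archive (test MSE ≈ 102 at
  500 Hz, MAE ≈ 7.8 y) require the real cohort and GPU-scale training; the
  harness supports the protocol but no claim is made to reproduce those
  values.
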