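# Methods

This note records the scientific and numerical choices behind `seizlite`:
what is modelled, which parameters matter, and where the design was
genuinely open.

## Harmonized record model

All inputs are reduced to one unit: a single-channel trace of 4097 samples
at 173.61 Hz with a label in {normal, interictal, ictal}. The two supported
source layouts are single-channel ASCII records already in that shape
(subsets A/B → normal, C/D → interictal, E → ictal) and multi-channel EDF
at 256 Hz with seizure-interval annotations.

Multi-channel harmonization order is channel-average → resample →
class-extract → chunk. Averaging first is the cheaper order (one resample
instead of one per channel) and matches the natural reading of the
procedure; no filtering is applied beyond the resampler's anti-aliasing
low-pass. Resampling uses `scipy.signal.resample_poly` on a
`limit_denominator(1000)` rational approximation of the rate ratio: the
exact ratio 17361/25600 is coprime, and a literal polyphase at that ratio
would need a ~500k-tap filter for no measurable accuracy gain. The output
is trimmed/edge-padded by at most one sample to meet the exact length
contract `round(n·fs_out/fs_in)`.

Time is in seconds, intervals are half-open `[start, end)`, sample indices
0-based. Interictal extraction takes the strict complement of the annotated
seizures (margin 0) by default; `margin_s` widens the exclusion zone for
users who want a guard band around seizures. Chunking discards the trailing
remainder rather than padding, so every record is genuinely observed
signal.

## Synthetic EEG generator

The generator exists to exercise the pipeline without the real recordings;
it emulates textbook EEG phenomenology, not physiology:

* **normal** — unit-SD broadband Gaussian noise + a 10 Hz sinusoid of
  amplitude 1.5 (posterior alpha rhythm), random phase;
* **interictal** — the normal recipe + biphasic ~70 ms transients
  (derivative-of-Gaussian, peak amplitude 8× the noise SD, random polarity)
  arriving as a Poisson process at 2.0 events/s. The rate is deliberately
  at the high end of interictal discharge frequency so that essentially
  every analysis window longer than ~1.5 s contains at least one event
  (P(no event) ≈ e^−2.95 ≈ 5%); windows without a spike are by construction
  indistinguishable from normal background, which would cap achievable
  accuracy regardless of the classifier;
* **ictal** — a 3 Hz sinusoid of amplitude 5 with phase-locked harmonics at
  6 and 9 Hz (amplitudes 2.0 and 1.0; a spike-and-wave-like discharge)
  + unit noise. The amplitude guarantees var(ictal) > var(normal) and a
  periodogram peak in the 2–4 Hz band, against 8–12 Hz for normal.

Amplitudes are unitless "µV-like"; no calibration is attempted. Per-record
seeds are spawned with numpy's `SeedSequence`, a counter-based scheme stable
across platforms, so a dataset is a pure function of one integer seed.

What passing tests on this data do **not** show: robustness to artifacts
(EMG, eye blinks, electrode pops), inter-subject variability, non-stationary
background, or realistic ictal evolution. The synthetic classes are
separable by design; cross-validated accuracy on them validates plumbing
and optimization, not clinical performance.

The EDF writer is a minimal standards-conformant implementation (16-bit
samples, 1 s data records, integer rates, physical range set symmetrically
from the data); reading goes through `mne`, which doubles as an independent
cross-check in the round-trip tests. The quantization error bound is one
digital step, `(phys_max − phys_min)/65535`. Seizure annotations are a
plain-text sidecar (`start_s<TAB>end_s` per line).

## Augmentation

Window segmentation yields `floor((l − w)/s) + 1` windows at offsets
0, s, 2s, …; the sweep grid crosses w ∈ {128, 256, 512, 1024} with
s ∈ {32, 64}.

SMOTE is implemented from its defining interpolation. Two quantities that
are sometimes conflated are kept separate: the *neighbour count* k_nn
(default 5, the standard choice in the SMOTE literature) and the *sampling
amount*, the majority/minority count ratio. Each minority reference is
visited round-robin; the integer part of the ratio sets guaranteed draws
per reference and the fractional part becomes the probability of one extra
draw; the result is then trimmed (newest synthetic samples first) to land
exactly on the majority count. Neighbour search is chunked brute-force
Euclidean distance with a stable argsort, so distance ties break toward the
lower index deterministically. Synthetic segments carry a `smote:` prefix
and a fractional offset in their provenance and a `synthetic_flag`.

At the published 200/352/106 class mix, equalization adds
(3·352 − 658)/658 = 398/658 ≈ 60.49% more samples for any fixed
window/stride, since segmentation multiplies every class count by the same
per-record window count.

In replication mode SMOTE runs on the full segment set *before* the
cross-validation split. This leaks information across folds twice over
(sibling windows of one record, and synthetic samples interpolated across
the split); it is kept as the default because it reproduces the published
protocol. `fit(split_by_record=True, smote_in_fold=...)` provides the
leakage-safe alternative: folds grouped by parent record and SMOTE fitted
inside each training fold only. On data with strong within-record
correlation the leakage-safe estimate is expected to be lower and more
honest.

## Network

Three valid (unpadded) strided Conv–BN–ReLU blocks, kernels 5/3/3 and
strides 3/2/2; stride replaces pooling, and filter counts are
non-increasing (enforced). The reference widths are 19/19/13 filters with a
BiLSTM of 19 hidden units per direction and a dense softmax over the
flattened BiLSTM output sequence. These widths are the unique
valid-padding, flatten-readout configuration consistent with both published
size figures at window 256 (9,371 trainable parameters; 0.139M FLOPs, see
below); the full-sequence readout is also what makes the parameter count
grow with window size, which a final-step readout would not.

* Shape chain at window 256: 256 → 84 → 41 → 20 time steps.
* Parameter accounting: conv `k·c_in·c_out + c_out` plus 2·c_out for the
  trainable BN scale/shift (running statistics are buffers, not
  parameters); LSTM per direction `4·((F + H)·H + H)`; dense `in·out + out`.
  The analytic total equals the instantiated network's variable list by
  construction and by test.
* Initialization: Glorot-uniform, zero biases, seeded. BN ε = 1e-3,
  running-stat momentum 0.9.
* Inference ties at the softmax argmax break toward the lower class index.

The implementation is numpy end to end — batched im2col convolution, fused
[i, f, o, g] LSTM gate matrices, explicit BPTT — with gradients verified
against central finite differences and the fast layers tested against
nested-loop oracles and the literal single-step gate equations.

### FLOP conventions

`count_flops` reports per-layer multiply-accumulates and derives a FLOP
figure under a named convention:

* `mac` (default): 1 MAC = 1 FLOP over all layers, plus the LSTM's
  per-element gate nonlinearities and state updates (9H per step per
  direction) — the most complete count, 0.174M for the reference model;
* `mac2`: 2 FLOPs per MAC;
* `static-graph`: 2 FLOPs per MAC over conv + dense only. This reproduces
  how graph profilers report models whose recurrent loop is dynamic and
  therefore not traced — the common situation when a framework profiler is
  pointed at a CNN-LSTM — and is the convention under which the reference
  model measures 138,966 ≈ 0.139M FLOPs. The headline figure is reported
  under this convention and always labelled with it.

## Training and evaluation

Adam with learning rate 2e-5, β₁ 0.9, β₂ 0.999, ε 1e-8, no decay, no
amsgrad, 1000 epochs and 10 folds replicates the published protocol;
`TrainConfig.smoke()` (learning rate 1e-3, batch 128, few epochs) is the
desk-scale setting used by the tests. Batch size defaults to 64 where not
otherwise set; it is never specified by the protocol. Segments are
z-scored per segment (zero-variance segments map to zeros) before training;
cross-entropy clamps the true-class probability at 1e-12. A NaN loss aborts
with diagnostics. Two runs with the same seed are bit-identical under
single-threaded numpy.

Folds are seeded random partitions (`sklearn` KFold); stratified and
grouped-by-record variants are available but off by default, matching the
plain 9:1 protocol. Metrics from the 3×3 confusion matrix: accuracy is
overall (trace/total); sensitivity TP/(TP+FN), specificity TN/(FP+TN) and
precision TP/(TP+FP) are computed per class one-vs-rest and macro-averaged
— the published values are single numbers for a 3-class task, and
macro-averaged one-vs-rest is the standard reduction consistent with the
binary definitions. Zero-denominator classes contribute 0 and are flagged.
Fold aggregation is the arithmetic mean.

The sixteen-cell sweep (window × step × SMOTE) reports sample counts,
parameters, MACs and optionally timed CV metrics per cell, with per-cell
failures isolated. Rows are keyed by explicit (window, step, smote)
coordinates; the id column is only this package's enumeration order, since
the published model numbering is internally inconsistent.

## Problem sizes used by the test suite

The smoke acceptance run uses 60 synthetic records per class, window 256 /
stride 32 (21,780 segments), the reduced-width model, 5 epochs and 10
folds, run twice to confirm seeded reproducibility; the SMOTE arithmetic
check uses 512-sample records at the full 200/352/106 class mix. These
sizes were chosen as the smallest that exercise every code path at
statistically comfortable margins (the smoke run's accuracy criterion is
0.95 against a typical ~0.97).

## Known limitations

* The real-data headline results require the actual public recordings and a
  1000-epoch run; the pipeline supports that experiment but nothing here
  asserts those numbers.
* The exact counting convention behind the published FLOP figure is not
  stated anywhere authoritative; the static-graph convention above is a
  reconstruction, documented and reported with its label.
* numpy training is single-threaded and CPU-bound; at full scale (127k
  segments × 1000 epochs) it is orders of magnitude slower than a GPU
  framework. The architecture, not the trainer, is the point.
* SMOTE neighbour search is O(n²) per minority class; fine at desk scale,
  slow but correct at full replication scale.
* The minimal EDF writer supports integer sampling rates and whole-second
  signals only.
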