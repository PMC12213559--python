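# Methods

This note documents the models and procedures implemented in `dscnet`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not establish.

## Problem setting

The package targets binary classification of multichannel resting-state EEG
at the segment level: each input is a `C × 1 × T` array (channels × a
singleton height axis × time samples), each segment belongs to a subject,
and each subject carries one binary label (e.g. patient vs. control).  The
singleton height axis makes a segment a one-row image, so all convolutions
are `1 × k` temporal kernels.  Evaluation is subject-independent by
default: no subject contributes segments to both the training and the test
side.

## Preprocessing chain

Raw recordings (typically 1,000 Hz) pass through, in order:

1. **Notch filter** — 2nd-order IIR notch at 50 Hz, quality factor 30,
   applied forward-backward (`filtfilt`) for zero phase.  Attenuation at
   the notch frequency exceeds 20 dB; tones ≥ 5 Hz away are essentially
   untouched (< 1 dB).
2. **Band-pass** — 4th-order Butterworth, 0.5–64 Hz, forward-backward.
   Removes drift and high-frequency noise; 10 Hz passes within 1 dB.
3. **Resampling** — polyphase resampling at the exact rational ratio
   (16/125 for 1,000 → 128 Hz), with the built-in anti-alias filter.  The
   output length is `round(N · target/source)`.
4. **Re-referencing** — subtraction of the per-sample mean of the chosen
   reference electrodes (e.g. A1/A2).  The reference channels become
   linearly dependent afterwards and are dropped by default
   (`drop_refs=False` keeps them).
5. **Segmentation** — fixed-length windows (`T = 256` samples ≙ 2 s at
   128 Hz by default, non-overlapping); the trailing remainder is dropped.
   Segment length and stride are free parameters: nothing in the method
   requires a specific window, and overlap can be used to augment small
   datasets at the cost of correlated segments.
6. **Optional ICA stage** — artifact removal by decomposing with FastICA,
   zeroing caller-selected components, and reconstructing.  The package
   deliberately wraps an established ICA implementation rather than
   re-deriving one, and ships no automatic artifact detector.

The filters are linear and zero-phase, so the chain commutes with scaling
and addition up to numerical tolerance — a property the tests check
directly.

### Standardization

Standardization is per time point, fitted on the training split only (to
avoid leakage; fitting on everything is a one-line change).  For each
training segment the cross-channel mean and standard deviation are computed
at every time point; the per-segment curves are averaged over segments to
give global `μ(t)` and `σ(t)`; each value is then transformed as
`(x − μ(t)) / max(σ(t), ε)` with `ε = 1e−8` so constant (degenerate) inputs
stay finite.  A consequence of this dialect: refitting on the standardized
training set returns exactly `μ ≡ 0` and `σ ≡ 1`.  A pooled per-time-point
dialect (`mode="global"`) is available, since the averaged-curves reading
is one of two defensible interpretations of a dataset-level per-time-point
recipe.

## Architecture

### Stage 1 — hybrid representation

Three stacked same-padded `1×3` convolutions (each followed by batch
normalization and GELU) map the `C` input channels to `embed_width`; a
parallel `1×1` convolution skip path is added to form a residual block.
The hybrid representation concatenates this residual output with a
`1×1`-projected copy of the raw input along the channel axis, giving
`2 × embed_width` channels.  Projecting the raw copy (rather than
concatenating it unprojected) keeps both halves the same width regardless
of `C`; the unprojected dialect is available as `embed_raw_copy=True`.

### Stage 2 — multi-angle rounds

Each round (two by default, independent weights per round) computes:

```
h   = DSC(x)                        # local view
out = maxpool( DAFM(h) + CoT(h) )   # global + static/dynamic views
```

* **DSC** — depthwise separable convolution: per-channel `1×3`
  convolution, then `1×1` pointwise mixing to `stage2_width` channels.
  The ablation variant `conv_type="sc"` replaces it with a standard `1×3`
  convolution of identical input/output widths.
* **DAFM** — directional adaptive feature modulation.  The input is split
  into `n_levels` equal channel groups.  Level 0 gets a `1×3` depthwise
  convolution at full resolution.  Level `i ≥ 1` is max-pooled along time
  by `2^i` (capped at `T`), convolved depthwise, and restored to length `T`
  by nearest-neighbor repetition; when `T` is not divisible by the factor
  the up-sampled signal is right-padded by edge replication.  The levels
  are concatenated, fused by a `1×1` convolution, and the GELU of the fused
  map multiplies the input elementwise.  Down-sampling uses max pooling
  (average pooling is a config dialect); pooling is temporal only, which is
  the operator's point — the channel/electrode axis is never decimated.
* **CoT** — contextual attention.  A grouped `1×k` convolution (k = 3,
  4 groups by default) produces the static context `K1`.  The channel
  concatenation `[K1, x]` passes through two `1×1` convolutions (widths
  `2C → 2C/4 → C·k`, GELU between them; the factor-4 bottleneck follows
  the usual contextual-attention reduction) to give per-position,
  per-channel logits over each length-`k` temporal neighborhood.  These are
  softmax-normalized over the neighborhood and applied to the unfolded
  `1×1`-convolved value map `V`, yielding the dynamic context `K2`.  The
  block returns `K1 + K2`.
* Max pooling by 2 (configurable) halves the time axis each round.

Setting `use_dafm=False`, `use_cot=False`, `use_embedding=False`,
`n_levels=4`, or `rounds ∈ {1,3}` produces the ablation lattice; all
variants preserve the `(·, 1, ·)` layout and the output contract.

### Stage 3 — classifier

Global average pooling over time, a `1×1` convolution to
`classifier_hidden` with GELU, and a `1×1` convolution to the class scores.
Prediction is the argmax; ties break toward the lower class index.

### Widths and initialization

Layer widths are open parameters; the defaults (`embed_width=16`,
`stage2_width=32`, `classifier_hidden=64`) are proportioned like compact
EEG CNNs and small enough for CPU training.  Kernels are initialized
fan-in-scaled normal with **unit gain** (`std = sqrt(1/fan_in)`), biases
zero.  Unit rather than ReLU gain is deliberate: the DAFM gate multiplies
`GELU(conv(·))` into its input, so activation variance compounds roughly
quadratically per round, and a `sqrt(2)` gain produces logits of order
several hundred at initialization; unit gain keeps initial logits O(1) and
the initial cross-entropy near `ln 2`.

## Compute engine

The package carries a compact reverse-mode automatic differentiation engine
over numpy arrays (`dscnet.autodiff`).  Convolutions are lowered to `k`
shifted batched matrix products (BLAS); pooling, nearest-neighbor
up-sampling, unfolding, softmax and GELU are dedicated primitives with
closed-form gradients.  Training uses float32; gradient correctness is
established in float64 by central finite differences on the full model
(max relative error < 1e−3 at step 1e−4, and ~1e−9 in practice).

## Training and evaluation protocol

* **Splits.**  `subject_wise` (default): 80% of subjects per class
  (floored, stratified, seeded shuffle) go wholly to training.
  `per_subject_segments`: 80% of every subject's segments go to training —
  a leakier protocol kept because per-subject 80/20 allocation and strict
  subject independence are both common readings of an 80/20-per-subject
  description; every end-to-end claim here uses the strict mode.  Subject
  disjointness is asserted on every subject-wise split.
* **Optimizer.**  Adam, learning rate 1e−3, batch 32, 30 epochs,
  cross-entropy; plain SGD available.  All randomness (init, shuffling)
  derives from `TrainConfig.seed`; training is bit-reproducible on a single
  thread.  A non-finite loss raises `TrainingDivergedError`.
* **Metrics.**  Accuracy, precision, recall and F1 from confusion counts,
  per class and aggregated.  The headline numbers use support-weighted
  averaging (whose arithmetic signature — precision tracking accuracy —
  matches how such tables are usually reported); macro and per-class values
  are always included.  Zero denominators yield 0.  Metrics are computed at
  segment level; `aggregate="subject_vote"` switches to per-subject
  majority voting.

## Synthetic benchmark

`dscnet.synthetic` simulates the eyes-closed resting regime the classifier
targets: per-channel 1/f-shaped Gaussian background noise (unit RMS, flat
below 1 Hz), plus one shared band-limited oscillation (white noise
band-passed into the target band, alpha 8–12 Hz by default) mixed into all
channels with fixed per-subject weights `U(0.5, 1.5)`.  Class 1 carries
`power_ratio` times the class-0 oscillation band power; a log-normal
(σ = 0.1) per-subject amplitude multiplier makes subjects non-identical so
subject-wise generalization is a real test.  Optional 50 Hz line noise and
a 0.25 Hz drift exercise the preprocessing chain.  With unit-RMS
oscillation against the pink background, the alpha band is
oscillation-dominated, so the measured Welch band-power ratio tracks
`power_ratio` closely (≈1.9 measured at a nominal 2.0).

What it does **not** emulate: ocular/muscle artifacts, event-related
potentials, stimulus protocols, non-stationarity, or realistic electrode
covariance.  Passing the end-to-end test therefore shows the pipeline can
recover a known band-power class difference without subject leakage — not
that it reaches any particular accuracy on clinical data.

## Problem sizes used by the shipped checks

The end-to-end check trains on 20 subjects/class × 50 segments (C=8,
T=256, 128 Hz) with the default training configuration: with
`power_ratio=2` the model reaches ≥ 90% subject-wise test accuracy, and
with `power_ratio=1` it stays at chance (the same model memorizes its
training subjects — training accuracy 100% — which is exactly why the
subject-wise protocol matters).  The no-signal calibration uses 8
subjects/class × 12 segments over 8 seeds; the ablation grid trains each
variant 2 epochs on the same small cohort.  These sizes are the package's
own benchmark choices and are trivially scaled up through `SyntheticSpec`.

## Known limitations

* Single-threaded numpy training is orders of magnitude slower than a GPU
  framework; the defaults are sized for small cohorts.
* Batch normalization uses per-batch statistics with running-average
  inference buffers; very small batches give noisy estimates.
* The UCI-dialect reader is deliberately strict (exact filtering rules,
  explicit parse errors) and parses one trial per stream; corpus-level
  iteration is left to the caller.
* Binary classification only; the classifier head generalizes to more
  classes but the metrics module is deliberately two-class.
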