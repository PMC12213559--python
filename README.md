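# dscnet

Multi-angle convolutional classification of multichannel resting-state EEG,
for researchers who need a compact, fully inspectable, CPU-only pipeline
from raw recordings to subject-independent evaluation — e.g. for screening
studies where each subject carries one binary label (patient vs. control)
and leakage-free evaluation is the whole game.

## The model

A segment is a `C × 1 × T` array (channels × 1 × time).  DSCnet processes
it in three stages:

1. **Hybrid representation.**  Three `1×3` convolutions (BN + GELU after
   each) with a `1×1` skip path form a residual embedding; its output is
   concatenated along the channel axis with a `1×1`-projected copy of the
   raw input.
2. **Multi-angle rounds** (two, independent weights).  Each round applies a
   depthwise separable convolution (local view), then two parallel
   branches whose outputs are summed and max-pooled along time:
   * **DAFM** — split the channels into `n_levels = 2` groups
     `[X₀, X₁]`; `X̂₀ = DWConv₁ₓ₃(X₀)`;
     `X̂₁ = ↑(DWConv₁ₓ₃(↓₂(X₁)))` with temporal-only pooling and
     nearest-neighbor up-sampling; fuse
     `X̂ = Conv₁ₓ₁([X̂₀, X̂₁])` and gate the input:
     `X̄ = GELU(X̂) ⊙ X`.
   * **CoT attention** — static context `K₁` from a grouped `1×k`
     convolution; attention over each k-neighborhood from two stacked
     `1×1` convolutions on `[K₁, X]` (softmax over the neighborhood),
     applied to a `1×1`-convolved value map to give the dynamic context
     `K₂`; output `Y = K₁ + K₂`.
3. **Classifier.**  Global average pooling over time and two `1×1`
   convolutions; argmax gives the label.

Evaluation reports Accuracy = (TP+TN)/(TP+TN+FP+FN),
Precision = TP/(TP+FP), Recall = TP/(TP+FN), F1 = 2PR/(P+R), per class and
support-weighted.  Splits are **subject-wise** by default: train and test
subject sets are provably disjoint.

Everything — including the reverse-mode autodiff engine the training loop
runs on — is plain numpy/scipy; see `docs/methods.md` for the full account
of the design choices.

## Worked example

```python
import dscnet

spec = dscnet.SyntheticSpec(n_subjects_per_class=10, segments_per_subject=20,
                            n_channels=8, sampling_rate=128.0, segment_length=256,
                            power_ratio=2.0, seed=0)
data = dscnet.generate_dataset(spec)                 # (400, 8, 1, 256) segments
plan = dscnet.make_split(data, "subject_wise", seed=0)
train_set, test_set = data.subset(plan.train_indices), data.subset(plan.test_indices)

stats = dscnet.fit_standardization(train_set)        # per-time-point mu/sigma
cfg = dscnet.ModelConfig(in_channels=8)              # 18,386 parameters
store, hist = dscnet.train(cfg, dscnet.standardize(train_set, stats),
                           dscnet.TrainConfig(epochs=10, seed=0))
rep = dscnet.evaluate(store, cfg, dscnet.standardize(test_set, stats))
print(dscnet.metrics_table({"DSCnet": rep}).to_string(index=False))
```

Output:

```
Methods  Accuracy (%)  Precision (%)  Recall (%)  F1-score (%)
 DSCnet         71.25          72.99       71.25          70.7
```

The synthetic class-1 subjects carry twice the 8–12 Hz band power of
class-0 subjects, with per-subject amplitude jitter.  71% here means the
model recovered that contrast on four subjects it never saw; with this few
held-out subjects the estimate is lumpy (each subject is 12.5 percentage
points).  At the benchmark size the suite uses — 20 subjects/class × 50
segments — the same pipeline reaches ≥ 90%, and with `power_ratio=1` (no
signal) it stays at chance, confirming the subject-wise protocol leaks
nothing.

The same flow is available from the shell:

```sh
dscnet simulate --out data.h5
dscnet train --data data.h5 --out model.h5
dscnet eval --ckpt model.h5 --data data.h5 --report report.json
dscnet ablate --grid tables4to8 --data data.h5 --out ablation/
dscnet model summary
```

`dscnet ablate` trains the full ablation lattice — embedding on/off,
standard vs. depthwise-separable convolution, DAFM off / 2 levels /
4 levels, CoT off, one/two/three rounds — under one split and seed and
writes the four-metric percentage table.

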