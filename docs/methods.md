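# Methods

`cacpnet` implements a lightweight plant-leaf-disease classifier built from
three parts: an 18-layer residual backbone, an efficient channel-attention
module with dual global pooling, and a structured channel-pruning procedure
driven by norm-based channel importance and per-block local compression
ratios. This note records the model, the choices that were genuinely open,
and what the desk-scale experiments do and do not show.

## Backbone

The backbone is the canonical 18-layer residual design: a 7×7/2 stem
convolution with batch normalization and ReLU, a 3×3/2 max pool, four
stages of basic blocks (two 3×3 conv+BN layers, identity shortcut, a 1×1
conv+BN projection when the width or stride changes), global average
pooling, and a linear head. All convolutions are bias-free; batch
normalization supplies the affine terms. Widths, block counts, strides,
head size and attention settings live in an `ArchSpec`, which is the single
source of truth: pruning rewrites the spec, and pruned models are built
from their spec rather than realized as masks. Checkpoints are `.npz`
archives that always carry an `ArchSpec` JSON sidecar, so a pruned model
reloads without shape inference.

With the default widths (64/128/256/512, two blocks per stage) and a
5-class head, exhaustive parameter enumeration gives 11,179,077 trainable
parameters (≈11.18 M); a 38-class head gives ≈11.196 M. The profiler, the
model builder, and an independent per-layer enumeration oracle in the test
suite agree exactly.

Because no deep-learning framework is part of the dependency footprint, the
package carries a compact reverse-mode autodiff core on numpy
(`cacpnet.nn`): im2col + BLAS-GEMM convolution, fused batch-norm
forward/backward, max/average pooling, the 1D cross-channel convolution,
and SGD with classical momentum and coupled L2 weight decay. Every op's
analytic gradient is tested against central differences.

## Channel attention

For a feature map `x` with `C` channels the module computes a per-channel
descriptor

    G(x) = G_avg(x) + G_max(x),

the sum of the spatial mean and the spatial maximum. The mean keeps global
context; the max preserves evidence from small lesions that average pooling
would wash out. The descriptor is mixed across neighboring channels with a
single shared 1D convolution of odd size `k` — the band-matrix form of
cross-channel interaction, with no dimensionality reduction and no bias —
and passed through a sigmoid:

    ω = σ(Conv1D_k(G(x))),   out[c] = ω_c · x[c].

The kernel size adapts to the channel count through the standard mapping
`t = floor((log2 C + b)/γ)` (γ=2, b=1), rounded up to the next odd number
and clamped to `[1, C]`: C=64 → k=3, C=128…512 → k=5. The mapping between
`k` and `C` is only specified abstractly in the source method; the γ=2, b=1
convention is adopted because the module is explicitly ECA-derived.

Placement: one module after every 3×3 convolution's batch-norm output and
before its rectifier — the stem's 7×7 conv included, 1×1 projection
shortcuts excluded. The default architecture has 17 attachment points and
a total overhead of Σk = 75 parameters, which is why the printed
complexity of the attended model is identical to the baseline at
three-decimal precision. Descriptors are summed *before* the 1D
convolution (one shared kernel), not convolved per branch and then summed;
the 1D convolution uses zero padding of (k−1)/2. Kernels initialize from
U(−1/√k, 1/√k), seeded.

## Channel pruning

Channel importance for a conv layer with weight tensor `(C_out, C_in, H, W)`
is the per-output-channel norm of its filter — L1 (sum of absolute values)
by default, L2 optional. (The source method's formula prints a
sum-of-squares-under-root, i.e. an L2 form, while naming the strategy
"L1-norm" throughout; we default to the name and expose the formula's
variant as `norm_kind="l2"`.) The number of channels removed from a layer
with `n` outputs at local compression ratio `R ∈ [0,1)` is

    P = floor(R · n),  capped at n − 1,

so at least one channel always survives; rounding is not stated in the
source and floor is used. The default schedule assigns one ratio per basic
block, shallow to deep: `R = [0, 0, 0.1, 0.1, 0.2, 0.2, 0.3, 0.3]` —
shallow layers are more sensitive to pruning, so their ratios are smaller.
Both convs of a block are pruned at the block's ratio.

Residual wiring imposes a structural constraint: an identity shortcut adds
a block's input to its output, so every block-output conv in a stage — and
the stage's projection shortcut, and the stem whenever stage 1 is entered
through an identity — must keep the *same* surviving channel indices. The
plan therefore selects, per coupling group, a single shared survivor set by
ranking the summed importances of all member convs (block conv2s, the
entry projection, the stem where coupled) and keeping the top
`width − P` channels, ties broken toward lower indices. This index sharing
is exactly how the shortcut stays consistent: the shortcut path drops
`P_r = O_r − O_conv2` channels so its output matches the pruned conv.
Each block's conv1 keeps its own top-`width − P` set ranked by conv1's own
importance. When the (equal-pair) default schedule is applied to the
default architecture the stage widths become [64, 116, 205, 359].

Applying a plan builds a fresh network from the rewritten spec and copies
surviving weight slices: conv output rows and input columns, BN affine
parameters and running statistics, and the head's input columns. Attention
kernel sizes are recomputed from the new widths; the shared 1D kernel is
channel-count independent, so it transfers unchanged unless `k` itself
changed (then it is freshly, seeded, initialized). Importance is computed
on the trained attended model, and the pruned model is retrained
(same hyperparameters, configurable epoch count).

### Achieved vs reference pruned totals

Under this literal per-block mapping the pruned 5-class architecture
profiles at 1.399 GMACs, 6.192 M parameters and 23.6 MiB at 224×224 —
a 22.9% FLOPs and 44.6% parameter reduction. The reference tabulation for
the same schedule reports 1.267 GFLOPs, 4.699 M and 18.0 MiB (30.35% /
57.97%), which implies a more aggressive ratio-to-layer mapping than the
stated schedule pins down (e.g. compounding block ratios within a stage).
The package emits both achieved and reference values rather than
recalibrating the mapping; the pruning property suite (identity-plan
equality, zeroed-channel equivalence, brute-force ranking agreement,
closed-form parameter match) is the binding correctness check.

## Complexity accounting

Two counting conventions are implemented. `mac` counts one
multiply-accumulate per kernel tap — `k²·C_in·h_out·w_out·C_out` per conv —
matching the common profiling tools for this family; `paper` counts two
floating-point ops per MAC (the factor-2 form). The conv parameter closed
form is `C_out(C_in k² + 1)` with bias, `C_out C_in k²` without; backbone
convs are bias-free and BN contributes 2C affine parameters (plus 2C
persistent buffers counted in serialized size, 4 bytes per value,
reported in MiB = 2²⁰ bytes). Elementwise work (BN normalization, ReLU,
pooling) is excluded by default and available behind
`include_elementwise=True` (two ops per normalized element); it is the
residual between tool outputs — conv+linear MACs give 1.814 G for the
baseline where the reference prints 1.819. The profiler is verified
against a hook oracle that records real activation shapes during a
forward pass and recomputes the totals per layer (agreement required to
0.1%).

## Synthetic data

The generator emulates the five-class peanut layout: a green elliptical
leaf (jittered center, axes, orientation, shade, radial shading) over a
noise-textured soil background, with class-specific lesions — rust (RD)
scatters many small orange specks over the blade; scorch (SD) browns the
outer margin with a smooth blend; SD+RD applies both; leaf spot (LSD)
draws 2–5 large dark lesions with lighter halos. Defaults: 5 classes,
300 images per class (matching the reference per-class count; the
desk-scale pipeline uses 200), 64 px for experiments with 224 px
available. All randomness derives from `SeedSequence(seed, class, index)`,
so a config is byte-reproducible and distinct seeds give distinct images.

What this emulates: visually separable disease phenotypes with realistic
within-class geometry/color variation. What it does not emulate: field
photography (backgrounds, occlusion, illumination changes, multiple
leaves, scale variation), disease-severity gradations, or inter-class
ambiguity at the level of real rust/scorch mixtures. A high desk-scale
accuracy therefore validates the *pipeline mechanics* — that training,
pruning and retraining preserve a learnable signal — not field-level
recognition performance.

Splitting is stratified 4:1 (test = round(n/5) per class, seeded); with
300 images per class over 5 classes this reproduces the reference 1200
train / 300 test proportions. Amplification maps each training image to
itself plus rot90/rot180/rot270 and a horizontal flip — exactly ×5,
matching the reference count (its transform list names five operations,
which would give ×6; the vertical flip sits behind a flag). The test set
is never amplified. Standardization resizes bilinearly, scales to [0,1],
and normalizes per channel with training-split statistics (plain scaling
available via `scale_only`).

## Training and evaluation

The training recipe follows the reference setup: SGD, batch size 32,
learning rate 5e-4, weight decay 0.001, cross-entropy loss; momentum (0.9)
and the constant learning rate are unstated there and configurable here.
Epoch presets of 200/400 mirror the reference datasets; the desk-scale
pipeline preset trains 3 epochs on the ×5-amplified training split and
retrains the pruned model for 2 (at 64 px, 200 images/class this runs in
roughly ten minutes on one CPU core and reached 0.98 pruned test accuracy
in the packaged configuration). Accuracy is top-1 overall; per-class
precision/recall/F1 use one-vs-rest counts with macro averages;
zero-denominator metrics report 0. ROC curves and AUC are one-vs-rest via
scikit-learn; a class with single-valued labels has no defined AUC and
raises (NaN inside batch evaluation). Grad-CAM weights a recorded block
activation by the spatial mean of the class-logit gradient, rectifies,
bilinearly upsamples and min–max normalizes, with a constant-map guard;
the default target layer is the last stage's final block.

## Numerical notes and limitations

* Importance ties break toward lower channel indices (stable argsort);
  all stochastic steps (init, shuffling, attention kernels) are seeded.
* BN running statistics update with torch-style unbiased variance and
  momentum 0.1; eval mode uses the buffers.
* The zeroed-channel equivalence oracle holds for attention-free paths:
  with attention enabled, removing exactly-zero channels re-aligns the 1D
  band kernel's channel neighborhoods, so functional equality after
  pruning is only exact without attention (or with k=1).
* The backbone trains in float32; gradient tests run in float64.
* Inference-time, throughput and GPU-memory behavior are out of scope;
  the complexity report covers FLOPs, parameters and serialized size only.
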