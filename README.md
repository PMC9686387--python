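# cacpnet

Channel **a**ttention + **c**hannel **p**runing for lightweight plant
leaf-disease classifiers.

Deep classifiers identify leaf diseases well but are too heavy for the
edge devices used in precision agriculture. This package implements a
compact recipe around an 18-layer residual network (ResNet-18):

1. **Improved efficient channel attention.** Each feature map channel is
   compressed to a descriptor `G(x) = G_avg(x) + G_max(x)` — global average
   pooling keeps context, global max pooling keeps small lesion evidence —
   then a shared size-`k` 1D convolution (the band-matrix form of local
   cross-channel interaction, `k` adapted to the channel count) and a
   sigmoid produce gates `ω = σ(Conv1D_k(G(x)))` that rescale the channels.
   One module sits after every 3×3 convolution; the total overhead is
   Σk = 75 parameters, invisible at printed precision.
2. **Structured channel pruning.** After training, output channels are
   ranked by the L1 norm of their filters and each basic block removes
   `P = floor(R·C_out)` channels under a local compression-ratio schedule
   `R = [0, 0, 0.1, 0.1, 0.2, 0.2, 0.3, 0.3]` (shallow → deep). Residual
   shortcuts stay consistent by index sharing: all block outputs in a
   stage keep one survivor set, and the shortcut path drops
   `P_r = O_r − O_conv2` channels to match. The pruned architecture is a
   first-class spec — rebuilt, weight-sliced, and retrained.
3. **Complexity profiling.** Closed-form FLOPs
   (`2·k²·C_in·h_out·w_out·C_out`, or half under the MAC convention),
   parameters (`C_out(C_in·k² + 1)` with bias), and serialized size, per
   layer and in total.

A seeded synthetic leaf-disease generator (healthy, scorch, rust,
scorch+rust, leaf-spot) makes the whole pipeline runnable at desk scale
with no downloads, and a small numpy autograd core removes any
deep-learning-framework dependency.

## Worked example

Profile the 5-class baseline, then prune it:

```python
import numpy as np
from cacpnet import peanut_spec, build_model, profile
from cacpnet.pruning import DEFAULT_RATIOS, make_pruning_plan, apply_plan

net = build_model(peanut_spec(attention=True), seed=0)
base = profile(net, convention="mac")
print(f"baseline: {base.gflops:.3f} GFLOPs  {base.params_m:.3f} M  {base.size_mib:.1f} MiB")

plan = make_pruning_plan(net, DEFAULT_RATIOS, norm_kind="l1")
pruned = apply_plan(net, plan, seed=0)
after = profile(pruned, convention="mac")
print(f"pruned widths: {plan.spec.stage_widths}")
print(f"pruned:   {after.gflops:.3f} GFLOPs  {after.params_m:.3f} M  {after.size_mib:.1f} MiB")
```

prints

```
baseline: 1.814 GFLOPs  11.179 M  42.7 MiB
pruned widths: [64, 116, 205, 359]
pruned:   1.399 GFLOPs  6.192 M  23.6 MiB
```

The baseline numbers agree with the commonly tabulated ResNet-18 figures
(1.819 GFLOPs / 11.180 M at three decimals once elementwise ops are
included; see `docs/methods.md` for the counting conventions). The pruned
totals are the result of the literal per-block ratio mapping; the methods
note discusses how they relate to previously reported totals for the same
schedule.

End to end on synthetic data (generates 5×200 images at 64 px, inserts
attention, trains, prunes, retrains, and reports):

```bash
cacpnet pipeline --out runs/demo --seed 7
```

finishing with a `summary.json` that contains the complexity of both
models, the percentage reductions, and the pruned model's test accuracy
(≥ 0.9 on the synthetic classes with the default desk preset). Other
subcommands: `synth`, `train`, `prune`, `retrain`, `profile`, `evaluate`,
`gradcam` — see `cacpnet --help`.

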