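"""Improved efficient channel attention (ECA-style) with dual global pooling.

The module compresses each channel of a feature map to a single descriptor
by *summing* global average pooling and global max pooling — the average
retains global context while the max preserves small, localized lesion
evidence — then mixes descriptors across neighboring channels with a
size-``k`` 1D convolution (the band-matrix form of cross-channel
interaction, no dimensionality reduction) and gates the channels with a
sigmoid. ``k`` adapts to the channel count via the standard ECA mapping.

Functional forms here operate on plain arrays (single map ``(C,H,W)`` or a
batch ``(N,C,H,W)``); :class:`EcaAttention` is the trainable layer used
inside the backbone.
"""

from __future__ import annotations

import math

import numpy as np

from .nn import Module, Parameter, Tensor, ops

__all__ = [
    "kernel_size_from_channels",
    "global_descriptor",
    "attention_weights",
    "apply_attention",
    "EcaAttention",
    "attention_sites",
    "attention_param_overhead",
    "attach_attention",
]


def kernel_size_from_channels(channels: int, gamma: int = 2, b: int = 1) -> int:
    """Adaptive 1D kernel size k from channel count C.

    t = floor((log2 C + b) / gamma), rounded up to the next odd number,
    clamped to [1, C] (next lower odd when C is even). With the defaults
    (gamma=2, b=1): C=64 -> 3, C=128..512 -> 5.
    """
    if channels < 1:
        raise ValueError(f"channel count must be >= 1, got {channels}")
    t = int(math.floor((math.log2(channels) + b) / gamma))
    k = t if t % 2 == 1 else t + 1
    k = max(k, 1)
    if k > channels:
        k = channels if channels % 2 == 1 else channels - 1
        k = max(k, 1)
    return k


def _as_batch(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x)
    if x.ndim == 3:
        return x[None], True
    if x.ndim == 4:
        return x, False
    raise ValueError(f"feature map must be (C,H,W) or (N,C,H,W), got shape {x.shape}")


def global_descriptor(x: np.ndarray) -> np.ndarray:
    """Per-channel mean + max over the spatial extent.

    Returns shape ``(C,)`` for a single map, ``(N,C)`` for a batch.
    """
    xb, single = _as_batch(x)
    if xb.shape[2] == 0 or xb.shape[3] == 0:
        raise ValueError("feature map has empty spatial extent")
    g = xb.mean(axis=(2, 3)) + xb.max(axis=(2, 3))
    return g[0] if single else g


def attention_weights(g: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """sigmoid(Conv1D_k(g)) with zero padding; output length equals len(g)."""
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 1:
        raise ValueError(f"kernel must be 1-D, got shape {kernel.shape}")
    k = kernel.shape[0]
    if k % 2 == 0:
        raise ValueError(f"kernel size must be odd, got {k}")
    g = np.asarray(g, dtype=float)
    single = g.ndim == 1
    gb = g[None] if single else g
    c = gb.shape[1]
    pad = (k - 1) // 2
    gp = np.pad(gb, ((0, 0), (pad, pad)))
    z = np.zeros_like(gb)
    for j in range(k):
        z += kernel[j] * gp[:, j : j + c]
    omega = 1.0 / (1.0 + np.exp(-z))
    return omega[0] if single else omega


def apply_attention(x: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Gate each channel: out[c] = omega[c] * x[c]; shape unchanged."""
    xb, single = _as_batch(x)
    omega = np.asarray(omega)
    ob = omega[None] if omega.ndim == 1 else omega
    if ob.shape != xb.shape[:2]:
        raise ValueError(f"attention weights {omega.shape} do not match channels {xb.shape[:2]}")
    out = xb * ob[:, :, None, None]
    return out[0] if single else out


class EcaAttention(Module):
    """Trainable channel-attention layer (shared 1D kernel, no bias)."""

    def __init__(self, channels: int, gamma: int = 2, b: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.channels = channels
        self.k = kernel_size_from_channels(channels, gamma, b)
        rng = rng or np.random.default_rng()
        bound = 1.0 / math.sqrt(self.k)
        self.weight = Parameter(rng.uniform(-bound, bound, size=self.k).astype(np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        g = ops.add(ops.global_avg_pool(x), ops.global_max_pool(x))
        w = ops.sigmoid(ops.conv1d_channels(g, self.weight))
        return ops.scale_channels(x, w)


def attention_sites(spec) -> list[int]:
    """Channel counts at every attachment point: the stem's 7x7 conv plus
    both 3x3 convs of every basic block (projection shortcuts excluded)."""
    sites = [spec.stem_channels]
    for s in range(len(spec.stage_widths)):
        for blk in range(spec.blocks_per_stage[s]):
            sites.append(spec.block_inner_width(s, blk))
            sites.append(spec.stage_widths[s])
    return sites


def attention_param_overhead(spec) -> int:
    """Exact parameter cost of attaching attention: the sum of kernel sizes."""
    return sum(kernel_size_from_channels(c, spec.attention_gamma, spec.attention_b)
               for c in attention_sites(spec))


def attach_attention(network, spec=None, rng: np.random.Generator | None = None):
    """Attach one attention module after each 3x3 conv's batch norm (stem
    included), in place; existing weights are untouched. Returns the network."""
    from .backbone import ResNet  # local import to avoid a cycle

    if not isinstance(network, ResNet):
        raise TypeError("attach_attention expects a ResNet backbone")
    spec = spec or network.spec
    rng = rng or np.random.default_rng()
    network.attach_attention_modules(gamma=spec.attention_gamma, b=spec.attention_b, rng=rng)
    network.spec = network.spec.with_updates(attention_enabled=True,
                                             attention_gamma=spec.attention_gamma,
                                             attention_b=spec.attention_b)
    return network
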