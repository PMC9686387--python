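"""Differentiable ops used by the backbone and attention modules.

Each op computes its output eagerly and, when any input requires grad,
attaches a fused backward closure. Convolution is im2col + BLAS matmul;
col2im is the 9-slice (k*k-slice) scatter-add, which is far faster than
``np.add.at`` for the small kernels used here.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "conv2d",
    "batchnorm2d",
    "relu",
    "sigmoid",
    "add",
    "maxpool2d",
    "global_avg_pool",
    "global_max_pool",
    "scale_channels",
    "conv1d_channels",
    "linear",
    "cross_entropy_with_logits",
]


def _out_size(h: int, k: int, stride: int, pad: int) -> int:
    return (h + 2 * pad - k) // stride + 1


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, ho: int, wo: int) -> np.ndarray:
    """(N,C,Hp,Wp) padded input -> (N, C*kh*kw, ho*wo) column matrix."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh * kw, ho, wo), dtype=xp.dtype)
    idx = 0
    for i in range(kh):
        for j in range(kw):
            cols[:, :, idx] = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
            idx += 1
    return cols.reshape(n, c * kh * kw, ho * wo)


def _col2im(gcols: np.ndarray, xp_shape, kh: int, kw: int, stride: int, ho: int, wo: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add columns back onto the padded image."""
    n, c = xp_shape[0], xp_shape[1]
    g = gcols.reshape(n, c, kh * kw, ho, wo)
    gxp = np.zeros(xp_shape, dtype=gcols.dtype)
    idx = 0
    for i in range(kh):
        for j in range(kw):
            gxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += g[:, :, idx]
            idx += 1
    return gxp


def conv2d(x: Tensor, weight: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """2D cross-correlation, no bias. x: (N,C,H,W); weight: (Co,Ci,kh,kw)."""
    n, ci, h, w = x.shape
    co, ci_w, kh, kw = weight.shape
    if ci != ci_w:
        raise ValueError(f"conv2d: input has {ci} channels, weight expects {ci_w}")
    ho, wo = _out_size(h, kh, stride, padding), _out_size(w, kw, stride, padding)
    l = ho * wo
    ckk = ci * kh * kw
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    # (CKK, N*L) layout turns the batch into one large GEMM
    cols = np.ascontiguousarray(
        _im2col(xp, kh, kw, stride, ho, wo).transpose(1, 0, 2)
    ).reshape(ckk, n * l)
    wm = weight.data.reshape(co, ckk)
    out_data = np.ascontiguousarray((wm @ cols).reshape(co, n, l).transpose(1, 0, 2)).reshape(
        n, co, ho, wo
    )
    req = x.requires_grad or weight.requires_grad
    out = Tensor(out_data, requires_grad=req, _prev=(x, weight))
    if req:

        def _backward(gout):
            g = np.ascontiguousarray(gout.reshape(n, co, l).transpose(1, 0, 2)).reshape(co, n * l)
            if weight.requires_grad:
                weight.accumulate_grad((g @ cols.T).reshape(weight.shape))
            if x.requires_grad:
                gcols = (wm.T @ g).reshape(ckk, n, l).transpose(1, 0, 2)
                gxp = _col2im(gcols, xp.shape, kh, kw, stride, ho, wo)
                if padding:
                    gxp = gxp[:, :, padding:-padding, padding:-padding]
                x.accumulate_grad(gxp)

        out._backward = _backward
    return out


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (N,H,W).

    In training mode normalizes with batch statistics and updates the running
    buffers in place (unbiased variance, torch-style); in eval mode uses the
    running buffers.
    """
    n, c, h, w = x.shape
    m = n * h * w
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        unbiased = var * (m / max(m - 1, 1))
        running_var *= 1.0 - momentum
        running_var += momentum * unbiased
    else:
        mean, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * invstd[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    req = x.requires_grad or gamma.requires_grad or beta.requires_grad
    out = Tensor(out_data.astype(x.dtype, copy=False), requires_grad=req, _prev=(x, gamma, beta))
    if req:

        def _backward(gout):
            if beta.requires_grad:
                beta.accumulate_grad(gout.sum(axis=(0, 2, 3)))
            gsum = gout.sum(axis=(0, 2, 3))
            gxhat_sum = (gout * xhat).sum(axis=(0, 2, 3))
            if gamma.requires_grad:
                gamma.accumulate_grad(gxhat_sum)
            if x.requires_grad:
                gi = gamma.data[None, :, None, None] * invstd[None, :, None, None]
                if training:
                    gx = gi * (
                        gout
                        - gsum[None, :, None, None] / m
                        - xhat * gxhat_sum[None, :, None, None] / m
                    )
                else:
                    gx = gi * gout
                x.accumulate_grad(gx)

        out._backward = _backward
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0), requires_grad=x.requires_grad, _prev=(x,))
    if x.requires_grad:

        def _backward(gout):
            x.accumulate_grad(gout * mask)

        out._backward = _backward
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60.0, 60.0)))
    out = Tensor(s, requires_grad=x.requires_grad, _prev=(x,))
    if x.requires_grad:

        def _backward(gout):
            x.accumulate_grad(gout * s * (1.0 - s))

        out._backward = _backward
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError(f"add: shape mismatch {a.shape} vs {b.shape}")
    out = Tensor(a.data + b.data, requires_grad=a.requires_grad or b.requires_grad, _prev=(a, b))
    if out.requires_grad:

        def _backward(gout):
            if a.requires_grad:
                a.accumulate_grad(gout)
            if b.requires_grad:
                b.accumulate_grad(gout)

        out._backward = _backward
    return out


def maxpool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    n, c, h, w = x.shape
    ho, wo = _out_size(h, kernel, stride, padding), _out_size(w, kernel, stride, padding)
    neg = np.finfo(x.data.dtype).min if np.issubdtype(x.data.dtype, np.floating) else np.iinfo(x.data.dtype).min
    xp = np.pad(
        x.data,
        ((0, 0), (0, 0), (padding, padding), (padding, padding)),
        constant_values=neg,
    )
    stacked = np.empty((kernel * kernel, n, c, ho, wo), dtype=x.data.dtype)
    idx = 0
    for i in range(kernel):
        for j in range(kernel):
            stacked[idx] = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
            idx += 1
    arg = stacked.argmax(axis=0)
    out_data = np.take_along_axis(stacked, arg[None], axis=0)[0]
    out = Tensor(out_data, requires_grad=x.requires_grad, _prev=(x,))
    if x.requires_grad:

        def _backward(gout):
            gxp = np.zeros_like(xp)
            idx2 = 0
            for i in range(kernel):
                for j in range(kernel):
                    gxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += gout * (arg == idx2)
                    idx2 += 1
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x.accumulate_grad(gxp)

        out._backward = _backward
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C) spatial mean."""
    n, c, h, w = x.shape
    out = Tensor(x.data.mean(axis=(2, 3)), requires_grad=x.requires_grad, _prev=(x,))
    if x.requires_grad:

        def _backward(gout):
            x.accumulate_grad(np.broadcast_to(gout[:, :, None, None] / (h * w), x.shape))

        out._backward = _backward
    return out


def global_max_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C) spatial max (first-occurrence argmax in backward)."""
    n, c, h, w = x.shape
    flat = x.data.reshape(n, c, h * w)
    arg = flat.argmax(axis=2)
    out = Tensor(np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0], requires_grad=x.requires_grad, _prev=(x,))
    if x.requires_grad:

        def _backward(gout):
            gx = np.zeros((n, c, h * w), dtype=gout.dtype)
            np.put_along_axis(gx, arg[:, :, None], gout[:, :, None], axis=2)
            x.accumulate_grad(gx.reshape(x.shape))

        out._backward = _backward
    return out


def scale_channels(x: Tensor, s: Tensor) -> Tensor:
    """Gate a feature map per channel: out[n,c] = s[n,c] * x[n,c,:,:]."""
    if s.shape != x.shape[:2]:
        raise ValueError(f"scale_channels: scales {s.shape} do not match channels {x.shape[:2]}")
    out = Tensor(x.data * s.data[:, :, None, None], requires_grad=x.requires_grad or s.requires_grad, _prev=(x, s))
    if out.requires_grad:

        def _backward(gout):
            if x.requires_grad:
                x.accumulate_grad(gout * s.data[:, :, None, None])
            if s.requires_grad:
                s.accumulate_grad((gout * x.data).sum(axis=(2, 3)))

        out._backward = _backward
    return out


def conv1d_channels(g: Tensor, weight: Tensor) -> Tensor:
    """Same-length 1D cross-channel convolution with zero padding, no bias.

    g: (N,C) per-channel descriptors; weight: (k,) with k odd.
    """
    (k,) = weight.shape
    if k % 2 == 0:
        raise ValueError(f"conv1d_channels: kernel size must be odd, got {k}")
    n, c = g.shape
    pad = (k - 1) // 2
    gp = np.pad(g.data, ((0, 0), (pad, pad)))
    out_data = np.zeros((n, c), dtype=g.data.dtype)
    for j in range(k):
        out_data += weight.data[j] * gp[:, j : j + c]
    out = Tensor(out_data, requires_grad=g.requires_grad or weight.requires_grad, _prev=(g, weight))
    if out.requires_grad:

        def _backward(gout):
            if weight.requires_grad:
                gw = np.array([(gout * gp[:, j : j + c]).sum() for j in range(k)], dtype=weight.data.dtype)
                weight.accumulate_grad(gw)
            if g.requires_grad:
                ggp = np.zeros_like(gp)
                for j in range(k):
                    ggp[:, j : j + c] += weight.data[j] * gout
                g.accumulate_grad(ggp[:, pad : pad + c])

        out._backward = _backward
    return out


def linear(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """x: (N,Ci); weight: (Co,Ci); bias: (Co,)."""
    out_data = x.data @ weight.data.T + bias.data
    req = x.requires_grad or weight.requires_grad or bias.requires_grad
    out = Tensor(out_data, requires_grad=req, _prev=(x, weight, bias))
    if req:

        def _backward(gout):
            if weight.requires_grad:
                weight.accumulate_grad(gout.T @ x.data)
            if bias.requires_grad:
                bias.accumulate_grad(gout.sum(axis=0))
            if x.requires_grad:
                x.accumulate_grad(gout @ weight.data)

        out._backward = _backward
    return out


def cross_entropy_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy. logits: (N,K); labels: int array (N,)."""
    n = logits.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    nll = -np.log(np.maximum(probs[np.arange(n), labels], 1e-30))
    out = Tensor(nll.mean(), requires_grad=logits.requires_grad, _prev=(logits,))
    if logits.requires_grad:

        def _backward(gout):
            g = probs.copy()
            g[np.arange(n), labels] -= 1.0
            logits.accumulate_grad(gout * g / n)

        out._backward = _backward
    return out


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    """Plain (non-differentiable) softmax on raw logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)
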