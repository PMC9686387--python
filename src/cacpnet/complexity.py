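"""Closed-form FLOPs / parameter / size accounting for backbone architectures.

Two counting conventions are exposed:

* ``mac`` (default): one multiply-accumulate per kernel tap — the convention
  used by the common profiling tools for this architecture family.
* ``paper``: two floating-point ops per multiply-accumulate, i.e.
  FLOPs = 2 * k^2 * C_in * h_out * w_out * C_out for a conv layer.

Elementwise work (batch-norm normalization, ReLU, pooling) is excluded by
default; ``include_elementwise=True`` adds two ops per normalized element,
which accounts for most of the residual between published tool outputs.
Serialized size assumes 32-bit floats over parameters plus persistent
batch-norm buffers.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field

from .archspec import ArchSpec
from .attention import kernel_size_from_channels

__all__ = ["conv_flops", "conv_params", "profile", "ComplexityReport", "reduction_percent"]

CONVENTIONS = ("paper", "mac")


def _check_positive(**kw) -> None:
    for name, v in kw.items():
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")


def conv_flops(k: int, c_in: int, c_out: int, h_out: int, w_out: int,
               convention: str = "paper") -> int:
    """Conv-layer FLOPs: 2*k^2*C_in*h_out*w_out*C_out (paper) or half (mac)."""
    _check_positive(k=k, c_in=c_in, c_out=c_out, h_out=h_out, w_out=w_out)
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    macs = k * k * c_in * h_out * w_out * c_out
    return 2 * macs if convention == "paper" else macs


def conv_params(k: int, c_in: int, c_out: int, with_bias: bool = True) -> int:
    """Conv-layer parameters: C_out*(C_in*k^2 + 1) with bias, else C_out*C_in*k^2."""
    _check_positive(k=k, c_in=c_in, c_out=c_out)
    return c_out * (c_in * k * k + (1 if with_bias else 0))


def _conv_out(h: int, k: int, stride: int, pad: int) -> int:
    return (h + 2 * pad - k) // stride + 1


@dataclass
class ComplexityReport:
    convention: str
    input_size: int
    flops: int
    params: int
    buffers: int
    rows: list[dict] = field(default_factory=list)

    @property
    def gflops(self) -> float:
        return self.flops / 1e9

    @property
    def params_m(self) -> float:
        return self.params / 1e6

    @property
    def size_mib(self) -> float:
        return 4.0 * (self.params + self.buffers) / 2**20

    def summary(self) -> dict:
        return {
            "convention": self.convention,
            "input_size": self.input_size,
            "gflops": round(self.gflops, 3),
            "params_m": round(self.params_m, 3),
            "size_mib": round(self.size_mib, 1),
            "flops": self.flops,
            "params": self.params,
            "buffers": self.buffers,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps({**self.summary(), "layers": self.rows}, indent=indent)

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=["name", "kind", "k", "c_in", "c_out",
                                                 "h_out", "w_out", "flops", "params"])
        writer.writeheader()
        writer.writerows(self.rows)
        return buf.getvalue()


def _layer_rows(spec: ArchSpec, input_size: int, convention: str,
                include_elementwise: bool) -> list[dict]:
    rows: list[dict] = []

    def conv_row(name, k, cin, cout, h, w, stride=1, pad=None):
        if pad is None:
            pad = (k - 1) // 2
        ho, wo = _conv_out(h, k, stride, pad), _conv_out(w, k, stride, pad)
        rows.append({
            "name": name, "kind": "conv", "k": k, "c_in": cin, "c_out": cout,
            "h_out": ho, "w_out": wo,
            "flops": conv_flops(k, cin, cout, ho, wo, convention),
            "params": conv_params(k, cin, cout, with_bias=False),
        })
        return ho, wo

    def bn_row(name, c, h, w):
        fl = 2 * c * h * w if include_elementwise else 0
        rows.append({"name": name, "kind": "bn", "k": 0, "c_in": c, "c_out": c,
                     "h_out": h, "w_out": w, "flops": fl, "params": 2 * c})

    def attn_row(name, c, h, w):
        k = kernel_size_from_channels(c, spec.attention_gamma, spec.attention_b)
        macs = k * c
        rows.append({"name": name, "kind": "attention", "k": k, "c_in": c, "c_out": c,
                     "h_out": h, "w_out": w,
                     "flops": 2 * macs if convention == "paper" else macs,
                     "params": k})

    h = w = input_size
    h, w = conv_row("stem.conv", 7, 3, spec.stem_channels, h, w, stride=2)
    bn_row("stem.bn", spec.stem_channels, h, w)
    if spec.attention_enabled:
        attn_row("stem.eca", spec.stem_channels, h, w)
    # 3x3/2 max pool, padding 1
    h, w = _conv_out(h, 3, 2, 1), _conv_out(w, 3, 2, 1)

    in_width = spec.stem_channels
    for s, (width, blocks, stride) in enumerate(
        zip(spec.stage_widths, spec.blocks_per_stage, spec.stage_strides)
    ):
        for b in range(blocks):
            blk_stride = stride if b == 0 else 1
            inner = spec.block_inner_width(s, b)
            tag = f"stage{s + 1}.block{b + 1}"
            hin, win = h, w
            h, w = conv_row(f"{tag}.conv1", 3, in_width, inner, h, w, stride=blk_stride)
            bn_row(f"{tag}.bn1", inner, h, w)
            if spec.attention_enabled:
                attn_row(f"{tag}.eca1", inner, h, w)
            conv_row(f"{tag}.conv2", 3, inner, width, h, w)
            bn_row(f"{tag}.bn2", width, h, w)
            if spec.attention_enabled:
                attn_row(f"{tag}.eca2", width, h, w)
            if b == 0 and (blk_stride != 1 or in_width != width):
                conv_row(f"{tag}.downsample.conv", 1, in_width, width, hin, win,
                         stride=blk_stride, pad=0)
                bn_row(f"{tag}.downsample.bn", width, h, w)
            in_width = width

    head_in = spec.stage_widths[-1]
    macs = head_in * spec.num_classes
    fl = (2 * macs if convention == "paper" else macs) + spec.num_classes
    rows.append({"name": "head", "kind": "linear", "k": 1, "c_in": head_in,
                 "c_out": spec.num_classes, "h_out": 1, "w_out": 1,
                 "flops": fl, "params": head_in * spec.num_classes + spec.num_classes})
    return rows


def profile(spec_or_network, input_size: int | None = None, convention: str = "mac",
            include_elementwise: bool = False) -> ComplexityReport:
    """Account FLOPs, parameters and serialized size for an architecture.

    Accepts an :class:`ArchSpec` or a built network (its spec is used).
    """
    spec = spec_or_network if isinstance(spec_or_network, ArchSpec) else spec_or_network.spec
    spec.validate()
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    size = input_size or spec.input_size
    if size < 32:
        raise ValueError(f"input_size must be >= 32, got {size}")
    rows = _layer_rows(spec, size, convention, include_elementwise)
    flops = sum(r["flops"] for r in rows)
    params = sum(r["params"] for r in rows)
    buffers = sum(2 * r["c_out"] for r in rows if r["kind"] == "bn")
    return ComplexityReport(convention=convention, input_size=size, flops=flops,
                            params=params, buffers=buffers, rows=rows)


def reduction_percent(before: float, after: float) -> float:
    """100 * (1 - after/before)."""
    if before <= 0:
        raise ValueError("baseline quantity must be positive")
    return 100.0 * (1.0 - after / before)
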