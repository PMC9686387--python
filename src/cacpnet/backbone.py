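"""The 18-layer residual backbone, built from an :class:`ArchSpec`.

Layout: 7x7/2 stem conv + BN + ReLU + 3x3/2 max pool, four stages of basic
blocks (two 3x3 conv+BN each, identity shortcut, 1x1 conv+BN projection when
width or stride changes), global average pooling and a linear head. Channel
widths come entirely from the spec, so pruned variants build and reload
without shape inference. Checkpoints are ``.npz`` weight archives with a
JSON ArchSpec sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .archspec import ArchSpec, parse_spec, serialize_spec
from .attention import EcaAttention
from .nn import BatchNorm2d, Conv2d, Linear, Module, Tensor, ops

__all__ = ["BasicBlock", "ResNet", "build_model", "save_checkpoint", "load_checkpoint"]


class BasicBlock(Module):
    def __init__(self, in_width: int, inner_width: int, out_width: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(in_width, inner_width, 3, stride=stride, padding=1, rng=rng)
        self.bn1 = BatchNorm2d(inner_width)
        self.conv2 = Conv2d(inner_width, out_width, 3, stride=1, padding=1, rng=rng)
        self.bn2 = BatchNorm2d(out_width)
        self.eca1: EcaAttention | None = None
        self.eca2: EcaAttention | None = None
        if stride != 1 or in_width != out_width:
            self.downsample_conv = Conv2d(in_width, out_width, 1, stride=stride, rng=rng)
            self.downsample_bn = BatchNorm2d(out_width)
        else:
            self.downsample_conv = None
            self.downsample_bn = None

    @property
    def has_projection(self) -> bool:
        return self.downsample_conv is not None

    def __call__(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x))
        if self.eca1 is not None:
            out = self.eca1(out)
        out = ops.relu(out)
        out = self.bn2(self.conv2(out))
        if self.eca2 is not None:
            out = self.eca2(out)
        if self.has_projection:
            identity = self.downsample_bn(self.downsample_conv(x))
        else:
            identity = x
        return ops.relu(ops.add(out, identity))


class ResNet(Module):
    def __init__(self, spec: ArchSpec, rng: np.random.Generator | None = None):
        super().__init__()
        spec.validate()
        self.spec = spec
        rng = rng or np.random.default_rng()
        self.stem_conv = Conv2d(3, spec.stem_channels, 7, stride=2, padding=3, rng=rng)
        self.stem_bn = BatchNorm2d(spec.stem_channels)
        self.stem_eca: EcaAttention | None = None
        self.stages: list[list[BasicBlock]] = []
        in_width = spec.stem_channels
        for s, (width, blocks, stride) in enumerate(
            zip(spec.stage_widths, spec.blocks_per_stage, spec.stage_strides)
        ):
            stage = []
            for b in range(blocks):
                stage.append(
                    BasicBlock(in_width, spec.block_inner_width(s, b), width,
                               stride if b == 0 else 1, rng)
                )
                in_width = width
            self.stages.append(stage)
        self.head = Linear(spec.stage_widths[-1], spec.num_classes, rng=rng)
        if spec.attention_enabled:
            self.attach_attention_modules(spec.attention_gamma, spec.attention_b, rng)

    # list-of-lists stages need explicit traversal support
    def named_children(self):
        yield from super().named_children()
        for s, stage in enumerate(self.stages):
            for b, block in enumerate(stage):
                yield f"stages.{s}.{b}", block

    def attach_attention_modules(self, gamma: int = 2, b: int = 1,
                                 rng: np.random.Generator | None = None) -> None:
        """One module per 3x3 conv (stem + both convs of each block)."""
        rng = rng or np.random.default_rng()
        self.stem_eca = EcaAttention(self.spec.stem_channels, gamma, b, rng)
        for stage in self.stages:
            for block in stage:
                block.eca1 = EcaAttention(block.conv1.out_channels, gamma, b, rng)
                block.eca2 = EcaAttention(block.conv2.out_channels, gamma, b, rng)

    def attention_modules(self) -> list[EcaAttention]:
        mods = [self.stem_eca] if self.stem_eca is not None else []
        for stage in self.stages:
            for block in stage:
                mods += [m for m in (block.eca1, block.eca2) if m is not None]
        return mods

    def activation_names(self) -> list[str]:
        names = ["stem"]
        for s, stage in enumerate(self.stages):
            for b in range(len(stage)):
                names.append(f"stage{s + 1}.block{b + 1}")
        return names

    def __call__(self, x, record: dict | None = None) -> Tensor:
        """Forward pass. ``x``: float array (N,3,H,W) or Tensor.

        ``record`` (optional dict) captures named block-output activation
        tensors for class-activation mapping.
        """
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        out = self.stem_bn(self.stem_conv(x))
        if self.stem_eca is not None:
            out = self.stem_eca(out)
        out = ops.relu(out)
        if record is not None:
            record["stem"] = out
        out = ops.maxpool2d(out, kernel=3, stride=2, padding=1)
        for s, stage in enumerate(self.stages):
            for b, block in enumerate(stage):
                out = block(out)
                if record is not None:
                    record[f"stage{s + 1}.block{b + 1}"] = out
        pooled = ops.global_avg_pool(out)
        return self.head(pooled)

    def predict_logits(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Inference-mode logits, batched, no graph construction."""
        was_training = self.training
        self.eval()
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(self(x[i : i + batch_size]).data)
        if was_training:
            self.train()
        return np.concatenate(outs, axis=0)


def build_model(spec: ArchSpec, rng: np.random.Generator | None = None,
                seed: int | None = None) -> ResNet:
    """Build a trainable backbone from a validated spec."""
    if rng is None:
        rng = np.random.default_rng(seed)
    return ResNet(spec, rng)


def save_checkpoint(network: ResNet, path: str | Path) -> None:
    """Write weights as .npz plus the ArchSpec JSON sidecar (<path>.spec.json)."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        np.savez(fh, **network.state_dict())
    Path(str(path) + ".spec.json").write_text(serialize_spec(network.spec))


def load_checkpoint(path: str | Path) -> ResNet:
    """Rebuild a network from a checkpoint and its mandatory spec sidecar."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    sidecar = Path(str(path) + ".spec.json")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"checkpoint {path} has no ArchSpec sidecar; expected {sidecar}. "
            "Supply the spec JSON written at save time."
        )
    spec = parse_spec(sidecar.read_text())
    net = build_model(spec, seed=0)
    with np.load(path) as npz:
        net.load_state_dict(dict(npz))
    return net
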