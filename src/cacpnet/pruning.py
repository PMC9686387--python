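"""Norm-based structured channel pruning with residual index sharing.

Output channels of each conv layer are ranked by the norm of their filter
(L1 by default: the sum of absolute weights over C_in x H x W; L2 optional),
and the lowest-ranked P = floor(R * C_out) channels are removed, where R is
the per-block local compression ratio (shallow blocks get smaller ratios).

Inside a residual stage, identity shortcuts add block inputs to block
outputs, so every block-output conv in a stage — and the stage's projection
shortcut, and the stem when stage 1 is entered through an identity — must
keep the *same* surviving channel indices. That shared-index constraint is
how shortcut "parameter sharing" is realized: the shortcut path drops
exactly O_r - O_conv2 channels so its output matches the pruned conv.
The survivor sets rewrite the :class:`ArchSpec`; applying a plan builds a
fresh network of the pruned shape and copies the surviving weight slices.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .archspec import ArchSpec
from .attention import kernel_size_from_channels
from .backbone import ResNet, build_model

__all__ = [
    "ImportanceVector",
    "RatioSchedule",
    "PruningPlan",
    "channel_importance",
    "prune_count",
    "residual_prune_count",
    "make_pruning_plan",
    "apply_plan",
    "DEFAULT_RATIOS",
]

NORM_KINDS = ("l1", "l2")

# Local compression ratios, one per basic block shallow -> deep.
DEFAULT_RATIOS = [0.0, 0.0, 0.1, 0.1, 0.2, 0.2, 0.3, 0.3]


@dataclass
class ImportanceVector:
    scores: np.ndarray
    norm_kind: str

    def ranking(self) -> np.ndarray:
        """Channel indices, most important first; ties -> lower index first."""
        return np.argsort(-self.scores, kind="stable")

    def top_keep(self, n_keep: int) -> list[int]:
        return sorted(int(i) for i in self.ranking()[:n_keep])


@dataclass
class RatioSchedule:
    ratios: list[float] = field(default_factory=lambda: list(DEFAULT_RATIOS))

    def __post_init__(self):
        for i, r in enumerate(self.ratios):
            if not (0.0 <= r < 1.0):
                raise ValueError(f"compression ratio {i} must be in [0,1), got {r}")

    def __len__(self):
        return len(self.ratios)

    def for_block(self, global_block_index: int) -> float:
        return self.ratios[global_block_index]


def channel_importance(weights: np.ndarray, norm_kind: str = "l1") -> ImportanceVector:
    """Reduce a (C_out, C_in, H, W) weight tensor to one score per output channel."""
    weights = np.asarray(weights)
    if weights.ndim != 4:
        raise ValueError(f"conv weight tensor must be 4-D, got shape {weights.shape}")
    if norm_kind not in NORM_KINDS:
        raise ValueError(f"norm_kind must be one of {NORM_KINDS}, got {norm_kind!r}")
    flat = weights.reshape(weights.shape[0], -1).astype(np.float64)
    if norm_kind == "l1":
        scores = np.abs(flat).sum(axis=1)
    else:
        scores = np.sqrt((flat**2).sum(axis=1))
    return ImportanceVector(scores=scores, norm_kind=norm_kind)


def prune_count(ratio: float, n_out: int) -> int:
    """P = floor(R * C_out), capped so at least one channel survives."""
    if not (0.0 <= ratio < 1.0):
        raise ValueError(f"compression ratio must be in [0,1), got {ratio}")
    if n_out < 1:
        raise ValueError(f"channel count must be >= 1, got {n_out}")
    return min(int(math.floor(ratio * n_out)), n_out - 1)


def residual_prune_count(o_r: int, o_conv2: int) -> int:
    """Channels dropped from the shortcut path: P_r = O_r - O_conv2."""
    if o_conv2 < 1:
        raise ValueError(f"pruned conv output must be >= 1, got {o_conv2}")
    if o_conv2 > o_r:
        raise ValueError(f"pruned conv output {o_conv2} exceeds shortcut width {o_r}")
    return o_r - o_conv2


@dataclass
class PruningPlan:
    original_spec: ArchSpec
    spec: ArchSpec                      # resulting (pruned) architecture
    stem_keep: list[int]
    stage_keep: list[list[int]]         # shared output survivors per stage
    inner_keep: list[list[list[int]]]   # conv1 survivors per stage, per block
    schedule: RatioSchedule
    norm_kind: str

    def validate(self) -> None:
        for s, keep in enumerate(self.stage_keep):
            if not keep:
                raise ValueError(f"stage {s} survivor set is empty")
            if keep != sorted(set(keep)):
                raise ValueError(f"stage {s} survivor set must be strictly increasing")
            if keep[-1] >= self.original_spec.stage_widths[s]:
                raise ValueError(f"stage {s} survivor index out of range")
            if len(keep) != self.spec.stage_widths[s]:
                raise ValueError(f"stage {s} width inconsistent with survivor set")

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "norm_kind": self.norm_kind,
                "schedule": self.schedule.ratios,
                "stem_keep": self.stem_keep,
                "stage_keep": self.stage_keep,
                "inner_keep": self.inner_keep,
                "original_spec": self.original_spec.to_dict(),
                "spec": self.spec.to_dict(),
            },
            indent=indent,
        )

    @classmethod
    def from_json(cls, text: str) -> "PruningPlan":
        d = json.loads(text)
        return cls(
            original_spec=ArchSpec.from_dict(d["original_spec"]),
            spec=ArchSpec.from_dict(d["spec"]),
            stem_keep=d["stem_keep"],
            stage_keep=d["stage_keep"],
            inner_keep=d["inner_keep"],
            schedule=RatioSchedule(d["schedule"]),
            norm_kind=d["norm_kind"],
        )


def _coupling_groups(spec: ArchSpec) -> list[dict]:
    """Partition {stem, stages} into groups that must share survivor indices.

    A stage entered through an identity shortcut is welded to whatever
    produced its input; a projection shortcut decouples it.
    """
    groups = [{"stem": True, "stages": []}]
    for s in range(len(spec.stage_widths)):
        if spec.block_uses_projection(s, 0):
            groups.append({"stem": False, "stages": [s]})
        else:
            groups[-1]["stages"].append(s)
    return groups


def make_pruning_plan(network: ResNet, schedule: RatioSchedule | list[float],
                      norm_kind: str = "l1", spec: ArchSpec | None = None) -> PruningPlan:
    """Rank channels of the (trained) network and build the survivor-set plan."""
    if isinstance(schedule, (list, tuple)):
        schedule = RatioSchedule(list(schedule))
    if norm_kind not in NORM_KINDS:
        raise ValueError(f"norm_kind must be one of {NORM_KINDS}, got {norm_kind!r}")
    spec = spec or network.spec
    if len(schedule) != spec.total_blocks:
        raise ValueError(
            f"schedule has {len(schedule)} ratios but the network has {spec.total_blocks} basic blocks"
        )

    n_stages = len(spec.stage_widths)
    block_offset = np.cumsum([0] + spec.blocks_per_stage[:-1]).tolist()

    stem_keep = list(range(spec.stem_channels))
    stage_keep: list[list[int]] = [None] * n_stages  # type: ignore[list-item]

    for group in _coupling_groups(spec):
        stages = group["stages"]
        if not stages:
            continue  # stem-only group: nothing prunes the stem
        width = spec.stage_widths[stages[-1]]
        ratios = [schedule.for_block(block_offset[s] + b)
                  for s in stages for b in range(spec.blocks_per_stage[s])]
        r_group = max(ratios)
        scores = np.zeros(width)
        if group["stem"]:
            scores += channel_importance(network.stem_conv.weight.data, norm_kind).scores
        for s in stages:
            for b, block in enumerate(network.stages[s]):
                scores += channel_importance(block.conv2.weight.data, norm_kind).scores
                if block.has_projection:
                    scores += channel_importance(block.downsample_conv.weight.data, norm_kind).scores
        keep = ImportanceVector(scores, norm_kind).top_keep(width - prune_count(r_group, width))
        for s in stages:
            stage_keep[s] = keep
        if group["stem"]:
            stem_keep = keep

    inner_keep: list[list[list[int]]] = []
    for s in range(n_stages):
        stage_sets = []
        for b, block in enumerate(network.stages[s]):
            r = schedule.for_block(block_offset[s] + b)
            n_out = block.conv1.out_channels
            imp = channel_importance(block.conv1.weight.data, norm_kind)
            stage_sets.append(imp.top_keep(n_out - prune_count(r, n_out)))
        inner_keep.append(stage_sets)

    new_spec = spec.with_updates(
        stem_channels=len(stem_keep),
        stage_widths=[len(k) for k in stage_keep],
        inner_widths=[[len(b) for b in stage] for stage in inner_keep],
    )
    plan = PruningPlan(
        original_spec=spec, spec=new_spec, stem_keep=stem_keep,
        stage_keep=stage_keep, inner_keep=inner_keep,
        schedule=schedule, norm_kind=norm_kind,
    )
    plan.validate()
    return plan


def _slice_bn(dst, src, keep: list[int]) -> None:
    dst.weight.data = src.weight.data[keep].copy()
    dst.bias.data = src.bias.data[keep].copy()
    dst.running_mean[...] = src.running_mean[keep]
    dst.running_var[...] = src.running_var[keep]


def apply_plan(network: ResNet, plan: PruningPlan,
               rng: np.random.Generator | None = None, seed: int = 0) -> ResNet:
    """Build the pruned network and transfer surviving weight slices.

    Conv weights keep surviving output rows and input columns; batch-norm
    affine parameters and running statistics are sliced to the survivors;
    the head keeps the final stage's surviving input columns. Attention
    kernel sizes are recomputed from the new widths — the shared 1D kernel
    is channel-count independent, so it is carried over unchanged unless k
    itself changed, in which case it is freshly (seeded) initialized.
    """
    if plan.original_spec.to_dict() != network.spec.to_dict():
        raise ValueError("pruning plan was built for a different architecture")
    plan.validate()
    rng = rng or np.random.default_rng(seed)
    pruned = build_model(plan.spec, rng=rng)

    pruned.stem_conv.weight.data = network.stem_conv.weight.data[plan.stem_keep].copy()
    _slice_bn(pruned.stem_bn, network.stem_bn, plan.stem_keep)

    in_keep = plan.stem_keep
    for s, (old_stage, new_stage) in enumerate(zip(network.stages, pruned.stages)):
        out_keep = plan.stage_keep[s]
        for b, (old, new) in enumerate(zip(old_stage, new_stage)):
            mid_keep = plan.inner_keep[s][b]
            new.conv1.weight.data = old.conv1.weight.data[np.ix_(mid_keep, in_keep)].copy()
            _slice_bn(new.bn1, old.bn1, mid_keep)
            new.conv2.weight.data = old.conv2.weight.data[np.ix_(out_keep, mid_keep)].copy()
            _slice_bn(new.bn2, old.bn2, out_keep)
            if old.has_projection:
                new.downsample_conv.weight.data = (
                    old.downsample_conv.weight.data[np.ix_(out_keep, in_keep)].copy()
                )
                _slice_bn(new.downsample_bn, old.downsample_bn, out_keep)
            in_keep = out_keep

    head_keep = plan.stage_keep[-1]
    pruned.head.weight.data = network.head.weight.data[:, head_keep].copy()
    pruned.head.bias.data = network.head.bias.data.copy()

    _transfer_attention(network, pruned)
    return pruned


def _transfer_attention(old_net: ResNet, new_net: ResNet) -> None:
    """Carry 1D attention kernels over wherever the recomputed k is unchanged."""
    for old, new in zip(old_net.attention_modules(), new_net.attention_modules()):
        if old is not None and new is not None and old.k == new.k:
            new.weight.data = old.weight.data.copy()
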