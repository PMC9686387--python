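"""Portable architecture description for the 18-layer residual backbone.

An :class:`ArchSpec` is the single source of truth for a (possibly pruned)
network: per-stage output widths, per-block inner widths, strides, block
counts, head size and attention settings. Pruning rewrites the spec; the
profiler and the model builder both consume it, so pruned variants are
first-class architectures rather than masked ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

__all__ = ["ArchSpec", "serialize_spec", "parse_spec", "SpecError", "peanut_spec", "plantvillage_spec"]

NUM_STAGES = 4


class SpecError(ValueError):
    """Raised when an ArchSpec (or its serialized form) is invalid."""


@dataclass
class ArchSpec:
    num_classes: int
    stem_channels: int = 64
    stage_widths: list[int] = field(default_factory=lambda: [64, 128, 256, 512])
    blocks_per_stage: list[int] = field(default_factory=lambda: [2, 2, 2, 2])
    stage_strides: list[int] = field(default_factory=lambda: [1, 2, 2, 2])
    input_size: int = 224
    attention_enabled: bool = False
    attention_gamma: int = 2
    attention_b: int = 1
    # conv1 output width of each basic block (stage-major); None means
    # "equal to the stage width", which holds for unpruned models.
    inner_widths: list[list[int]] | None = None

    def __post_init__(self):
        self.validate()

    # -- validation --------------------------------------------------------------
    def validate(self) -> None:
        if not isinstance(self.num_classes, int) or self.num_classes < 1:
            raise SpecError(f"num_classes must be a positive int, got {self.num_classes!r}")
        if self.stem_channels < 1:
            raise SpecError(f"stem_channels must be >= 1, got {self.stem_channels}")
        for name, lst in (
            ("stage_widths", self.stage_widths),
            ("blocks_per_stage", self.blocks_per_stage),
            ("stage_strides", self.stage_strides),
        ):
            if len(lst) != NUM_STAGES:
                raise SpecError(f"{name} must have {NUM_STAGES} entries, got {len(lst)}")
        if any(w < 1 for w in self.stage_widths):
            raise SpecError(f"stage_widths must all be >= 1, got {self.stage_widths}")
        if any(b < 1 for b in self.blocks_per_stage):
            raise SpecError(f"blocks_per_stage must all be >= 1, got {self.blocks_per_stage}")
        if any(s < 1 for s in self.stage_strides):
            raise SpecError(f"stage_strides must all be >= 1, got {self.stage_strides}")
        if self.input_size < 32:
            raise SpecError(f"input_size must be >= 32, got {self.input_size}")
        if self.inner_widths is not None:
            if len(self.inner_widths) != NUM_STAGES:
                raise SpecError("inner_widths must have one list per stage")
            for s, (blocks, ws) in enumerate(zip(self.blocks_per_stage, self.inner_widths)):
                if len(ws) != blocks:
                    raise SpecError(f"inner_widths[{s}] must have {blocks} entries, got {len(ws)}")
                if any(w < 1 for w in ws):
                    raise SpecError(f"inner_widths[{s}] must all be >= 1, got {ws}")

    # -- derived geometry --------------------------------------------------------
    def block_inner_width(self, stage: int, block: int) -> int:
        if self.inner_widths is None:
            return self.stage_widths[stage]
        return self.inner_widths[stage][block]

    @property
    def total_blocks(self) -> int:
        return sum(self.blocks_per_stage)

    def stage_input_width(self, stage: int) -> int:
        return self.stem_channels if stage == 0 else self.stage_widths[stage - 1]

    def block_uses_projection(self, stage: int, block: int) -> bool:
        """Projection shortcut when the block changes width or stride."""
        if block > 0:
            return False
        return self.stage_strides[stage] != 1 or self.stage_input_width(stage) != self.stage_widths[stage]

    def with_updates(self, **kw) -> "ArchSpec":
        return dataclasses.replace(self, **kw)

    # -- serialization -----------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchSpec":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SpecError(f"unknown ArchSpec fields: {sorted(unknown)}")
        required = {"num_classes"}
        missing = required - set(d)
        if missing:
            raise SpecError(f"missing required ArchSpec field(s): {sorted(missing)}")
        return cls(**d)

    @classmethod
    def from_json(cls, text: str) -> "ArchSpec":
        try:
            d = json.loads(text)
        except json.JSONDecodeError as e:
            raise SpecError(f"malformed ArchSpec JSON at line {e.lineno}, column {e.colno}: {e.msg}") from e
        if not isinstance(d, dict):
            raise SpecError("ArchSpec JSON must be an object")
        return cls.from_dict(d)


def serialize_spec(spec: ArchSpec) -> str:
    return spec.to_json()


def parse_spec(text: str) -> ArchSpec:
    return ArchSpec.from_json(text)


def peanut_spec(attention: bool = False) -> ArchSpec:
    """Default 5-class preset (the peanut leaf disease layout)."""
    return ArchSpec(num_classes=5, attention_enabled=attention)


def plantvillage_spec(attention: bool = False) -> ArchSpec:
    """38-class preset (the PlantVillage layout)."""
    return ArchSpec(num_classes=38, attention_enabled=attention)
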