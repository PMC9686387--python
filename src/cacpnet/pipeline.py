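"""End-to-end orchestration: insert attention -> train -> prune -> retrain.

A :class:`RunConfig` (YAML-serializable) declares the data source, the
architecture/hyperparameter overrides, the compression-ratio schedule and
all seeds; :func:`run_pipeline` executes the flow and leaves auditable
artifacts in the output directory:

* ``attended.npz`` (+ spec sidecar) — the trained attention model
* ``pruning_plan.json`` — survivor index sets, schedule, norms
* ``pruned.npz`` (+ sidecar) — the retrained compressed model
* ``complexity_before.json`` / ``complexity_after.json``
* ``eval_attended.json`` / ``eval_pruned.json``
* ``summary.json`` — headline numbers incl. percentage reductions

Every stage draws its seed from the config, so a run is replayable from
its logged summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .archspec import ArchSpec
from .attention import attach_attention
from .backbone import build_model, save_checkpoint
from .complexity import profile, reduction_percent
from .data import (
    SynthConfig,
    amplify,
    generate_synthetic_dataset,
    load_image_folder,
    load_standardize,
    split_dataset,
)
from .pruning import DEFAULT_RATIOS, apply_plan, make_pruning_plan
from .train_eval import Hyperparams, evaluate, train

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "runs/pipeline"
    data_root: str | None = None        # ImageFolder root; None -> synthetic data
    synth: SynthConfig = field(default_factory=lambda: SynthConfig(n_per_class=200))
    image_size: int = 64
    amplify_train: bool = True
    epochs: int = 3
    retrain_epochs: int | None = 2      # None: same as epochs
    batch_size: int = 32
    learning_rate: float = 5e-4
    momentum: float = 0.9
    weight_decay: float = 1e-3
    ratios: list[float] = field(default_factory=lambda: list(DEFAULT_RATIOS))
    norm_kind: str = "l1"
    convention: str = "mac"
    seed: int = 0

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["synth"] = dataclasses.asdict(self.synth)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        if "synth" in d and d["synth"] is not None:
            d["synth"] = SynthConfig(**d["synth"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def stage_seed(self, stage: str) -> int:
        offsets = {"synth": 0, "split": 1, "init": 2, "attach": 3, "train": 4,
                   "apply": 5, "retrain": 6}
        return (self.seed * 16 + offsets[stage]) % (2**31 - 1)


def _resolve_data(cfg: RunConfig):
    if cfg.data_root:
        log.info("loading images from %s", cfg.data_root)
        return load_image_folder(cfg.data_root)
    synth = dataclasses.replace(cfg.synth, seed=cfg.stage_seed("synth"),
                                image_size=cfg.image_size)
    log.info("generating synthetic dataset: %d classes x %d images at %dpx",
             len(synth.classes), synth.n_per_class, synth.image_size)
    return generate_synthetic_dataset(synth)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the attend -> train -> prune -> retrain flow; returns the summary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("resolved config:\n%s", cfg.to_yaml())
    (out / "config.yaml").write_text(cfg.to_yaml())

    stage = "data"
    try:
        dataset = _resolve_data(cfg)
        train_set, test_set = split_dataset(dataset, seed=cfg.stage_seed("split"))
        n_train_raw = len(train_set)
        if cfg.amplify_train:
            train_set = amplify(train_set)
        train_tensors = load_standardize(train_set, size=cfg.image_size)
        test_tensors = load_standardize(test_set, size=cfg.image_size,
                                        mean=train_tensors.mean, std=train_tensors.std)

        stage = "build"
        spec = ArchSpec(num_classes=len(dataset.classes), input_size=cfg.image_size)
        network = build_model(spec, seed=cfg.stage_seed("init"))

        stage = "attach-attention"
        attach_attention(network, rng=np.random.default_rng(cfg.stage_seed("attach")))
        report_before = profile(network.spec, convention=cfg.convention)
        (out / "complexity_before.json").write_text(report_before.to_json())

        stage = "train"
        hp = Hyperparams(epochs=cfg.epochs, batch_size=cfg.batch_size,
                         learning_rate=cfg.learning_rate, momentum=cfg.momentum,
                         weight_decay=cfg.weight_decay, seed=cfg.stage_seed("train"))
        history = train(network, train_tensors.x, train_tensors.y, hp)
        log.info("training done: final loss %.4f, train acc %.3f",
                 history["loss"][-1], history["accuracy"][-1])
        save_checkpoint(network, out / "attended.npz")
        (out / "history_train.json").write_text(json.dumps(history))
        eval_attended = evaluate(network, test_tensors.x, test_tensors.y,
                                 class_names=dataset.classes)
        (out / "eval_attended.json").write_text(eval_attended.to_json())

        stage = "prune"
        plan = make_pruning_plan(network, cfg.ratios, norm_kind=cfg.norm_kind)
        (out / "pruning_plan.json").write_text(plan.to_json())
        pruned = apply_plan(network, plan, seed=cfg.stage_seed("apply"))
        report_after = profile(pruned.spec, convention=cfg.convention)
        (out / "complexity_after.json").write_text(report_after.to_json())

        stage = "retrain"
        hp_retrain = dataclasses.replace(hp, epochs=cfg.retrain_epochs or cfg.epochs,
                                         seed=cfg.stage_seed("retrain"))
        history_retrain = train(pruned, train_tensors.x, train_tensors.y, hp_retrain)
        save_checkpoint(pruned, out / "pruned.npz")
        (out / "history_retrain.json").write_text(json.dumps(history_retrain))

        stage = "evaluate"
        eval_pruned = evaluate(pruned, test_tensors.x, test_tensors.y,
                               class_names=dataset.classes)
        (out / "eval_pruned.json").write_text(eval_pruned.to_json())
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    summary = {
        "seed": cfg.seed,
        "stage_seeds": {s: cfg.stage_seed(s)
                        for s in ("synth", "split", "init", "attach", "train", "apply", "retrain")},
        "classes": dataset.classes,
        "n_train_raw": n_train_raw,
        "n_train": len(train_tensors),
        "n_test": len(test_tensors),
        "pruned_stage_widths": plan.spec.stage_widths,
        "complexity_before": report_before.summary(),
        "complexity_after": report_after.summary(),
        "reduction_percent": {
            "flops": reduction_percent(report_before.flops, report_after.flops),
            "params": reduction_percent(report_before.params, report_after.params),
            "size": reduction_percent(report_before.size_mib, report_after.size_mib),
        },
        "accuracy_attended": eval_attended.accuracy,
        "accuracy_pruned": eval_pruned.accuracy,
        "macro_f1_pruned": eval_pruned.macro_f1,
        "final_train_loss": history_retrain["loss"][-1],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    log.info("pipeline summary: %s", json.dumps(summary["reduction_percent"]))
    return summary
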