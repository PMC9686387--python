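"""Training loop, classification metrics and Grad-CAM heatmaps.

Training follows the reference recipe: mini-batch SGD (momentum 0.9),
batch size 32, learning rate 5e-4, weight decay 0.001, cross-entropy loss.
Evaluation reports top-1 accuracy, one-vs-rest confusion counts per class
with precision/recall/F1 (macro-averaged summaries), and per-class ROC/AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .backbone import ResNet
from .nn import SGD, Tensor, ops

__all__ = [
    "Hyperparams",
    "EvalReport",
    "train",
    "evaluate",
    "roc_auc",
    "gradcam",
    "accuracy_from_counts",
    "precision_from_counts",
    "recall_from_counts",
    "f1_score",
]


@dataclass
class Hyperparams:
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 5e-4
    momentum: float = 0.9
    weight_decay: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        for name in ("batch_size",):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("learning_rate", "momentum", "weight_decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @classmethod
    def plantvillage_preset(cls, **overrides) -> "Hyperparams":
        return cls(**{"epochs": 200, **overrides})

    @classmethod
    def peanut_preset(cls, **overrides) -> "Hyperparams":
        return cls(**{"epochs": 400, **overrides})


def train(network: ResNet, x: np.ndarray, y: np.ndarray, hp: Hyperparams) -> dict:
    """Train in place; returns history {'loss': [...], 'accuracy': [...]} per epoch.

    Data order is shuffled by a generator seeded from ``hp.seed``, so two
    runs with identical seeds and initial weights coincide.
    """
    y = np.asarray(y)
    if y.size and int(y.max()) >= network.spec.num_classes:
        raise ValueError(
            f"labels contain class {int(y.max())} but the head has {network.spec.num_classes} outputs"
        )
    rng = np.random.default_rng(hp.seed)
    opt = SGD(network.parameters(), lr=hp.learning_rate, momentum=hp.momentum,
              weight_decay=hp.weight_decay)
    n = len(x)
    history: dict[str, list[float]] = {"loss": [], "accuracy": []}
    network.train()
    for _ in range(hp.epochs):
        perm = rng.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, hp.batch_size):
            idx = perm[i : i + hp.batch_size]
            xb = np.ascontiguousarray(x[idx], dtype=np.float32)
            logits = network(xb)
            loss = ops.cross_entropy_with_logits(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            correct += int((logits.data.argmax(axis=1) == y[idx]).sum())
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(correct / n)
    return history


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def accuracy_from_counts(tp: int, tn: int, fp: int, fn: int) -> float:
    return (tp + tn) / (tp + fp + tn + fn)


def precision_from_counts(tp: int, fp: int) -> float:
    return tp / (tp + fp) if tp + fp else 0.0


def recall_from_counts(tp: int, fn: int) -> float:
    return tp / (tp + fn) if tp + fn else 0.0


def f1_score(precision: float, recall: float) -> float:
    return 2 * precision * recall / (precision + recall) if precision + recall else 0.0


@dataclass
class EvalReport:
    classes: list[str]
    confusion: np.ndarray            # rows: true class, cols: predicted
    accuracy: float
    per_class: list[dict]            # tp/tn/fp/fn/precision/recall/f1/auc per class
    macro_precision: float
    macro_recall: float
    macro_f1: float
    roc: list[dict] = field(default_factory=list)   # per class: fpr/tpr lists

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "classes": self.classes,
                "accuracy": self.accuracy,
                "macro_precision": self.macro_precision,
                "macro_recall": self.macro_recall,
                "macro_f1": self.macro_f1,
                "confusion": self.confusion.tolist(),
                "per_class": self.per_class,
                "roc": self.roc,
            },
            indent=indent,
        )


def roc_auc(scores: np.ndarray, labels: np.ndarray, num_classes: int | None = None):
    """One-vs-rest ROC per class from per-class scores (logits or probabilities).

    Returns a list of (fpr, tpr, auc) triples. A class with no positive or
    no negative examples has an undefined ROC and raises.
    """
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    k = num_classes or scores.shape[1]
    out = []
    for c in range(k):
        pos = labels == c
        if pos.all() or not pos.any():
            raise ValueError(f"AUC undefined for class {c}: labels are single-class")
        fpr, tpr, _ = _sk_roc_curve(pos.astype(int), scores[:, c])
        out.append((fpr, tpr, float(_sk_auc(fpr, tpr))))
    return out


def evaluate(network: ResNet, x: np.ndarray, y: np.ndarray,
             class_names: list[str] | None = None, with_roc: bool = True) -> EvalReport:
    """Argmax predictions, one-vs-rest counts, macro summary, per-class AUC."""
    if len(x) == 0:
        raise ValueError("cannot evaluate on an empty set")
    y = np.asarray(y)
    k = network.spec.num_classes
    classes = class_names or [str(i) for i in range(k)]
    logits = network.predict_logits(x)
    preds = logits.argmax(axis=1)

    confusion = np.zeros((k, k), dtype=np.int64)
    np.add.at(confusion, (y, preds), 1)
    n = len(y)
    accuracy = float(np.trace(confusion)) / n

    probs = ops.softmax_probs(logits)
    per_class, precs, recs, f1s, roc_rows = [], [], [], [], []
    for c in range(k):
        tp = int(confusion[c, c])
        fp = int(confusion[:, c].sum() - tp)
        fn = int(confusion[c, :].sum() - tp)
        tn = n - tp - fp - fn
        p = precision_from_counts(tp, fp)
        r = recall_from_counts(tp, fn)
        f1 = f1_score(p, r)
        entry = {"class": classes[c], "tp": tp, "tn": tn, "fp": fp, "fn": fn,
                 "precision": p, "recall": r, "f1": f1,
                 "accuracy_ovr": accuracy_from_counts(tp, tn, fp, fn)}
        if with_roc:
            pos = y == c
            if pos.any() and not pos.all():
                fpr, tpr, _ = _sk_roc_curve(pos.astype(int), probs[:, c])
                entry["auc"] = float(_sk_auc(fpr, tpr))
                roc_rows.append({"class": classes[c], "fpr": fpr.tolist(), "tpr": tpr.tolist()})
            else:
                entry["auc"] = float("nan")
        per_class.append(entry)
        precs.append(p)
        recs.append(r)
        f1s.append(f1)
    return EvalReport(
        classes=classes, confusion=confusion, accuracy=accuracy, per_class=per_class,
        macro_precision=float(np.mean(precs)), macro_recall=float(np.mean(recs)),
        macro_f1=float(np.mean(f1s)), roc=roc_rows,
    )


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------


def gradcam(network: ResNet, image: np.ndarray, target_class: int,
            layer: str | None = None) -> np.ndarray:
    """Gradient-weighted class activation map, normalized to [0,1].

    ``image``: (3,H,W) standardized input. ``layer`` names a recorded block
    output (default: the final block of the last stage). The map is the
    rectified, gradient-weighted sum of that layer's activation channels,
    bilinearly upsampled to the input's spatial size.
    """
    valid = network.activation_names()
    if layer is None:
        layer = valid[-1]
    if layer not in valid:
        raise ValueError(f"unknown layer {layer!r}; valid layers: {valid}")
    was_training = network.training
    network.eval()
    try:
        record: dict[str, Tensor] = {}
        logits = network(np.asarray(image, dtype=np.float32)[None], record=record)
        if not 0 <= target_class < logits.shape[1]:
            raise ValueError(f"target_class {target_class} out of range")
        seed = np.zeros_like(logits.data)
        seed[0, target_class] = 1.0
        logits.backward(seed)
    finally:
        if was_training:
            network.train()
    act = record[layer].data[0]      # (C,h,w)
    grad = record[layer].grad[0]
    weights = grad.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * act).sum(axis=0), 0.0)
    h, w = image.shape[1], image.shape[2]
    cam = ndimage.zoom(cam, (h / cam.shape[0], w / cam.shape[1]), order=1)
    lo, hi = cam.min(), cam.max()
    if hi - lo < 1e-12:
        return np.zeros((h, w))
    return (cam - lo) / (hi - lo)
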