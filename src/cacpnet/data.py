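"""Leaf-disease image data: synthetic generator, folder IO, splitting,
rotation/flip amplification and standardization.

The generator emulates the five peanut leaf categories — healthy (HL),
scorch (SD), rust (RD), scorch+rust (SD+RD) and leaf spot (LSD) — as a
green elliptical leaf over a textured soil background with class-specific
lesions: rust puts many small orange specks on the blade, scorch browns
the leaf margin, leaf spot draws a few large dark circles with lighter
halos. Geometry and color are jittered per image; everything is driven by
one seed, so a config reproduces its images byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "CLASS_NAMES",
    "SynthConfig",
    "LabeledImageSet",
    "TensorDataset",
    "generate_synthetic_dataset",
    "split_dataset",
    "amplify",
    "load_image_folder",
    "load_standardize",
]

log = logging.getLogger(__name__)

CLASS_NAMES = ["HL", "SD", "RD", "SD+RD", "LSD"]


@dataclass
class SynthConfig:
    classes: list[str] = field(default_factory=lambda: list(CLASS_NAMES))
    n_per_class: int = 300
    image_size: int = 64
    seed: int = 0
    rust_speck_density: float = 12.0   # specks per (16 px)^2 of leaf bounding box
    rust_speck_radius: float = 1.8     # px at 64-px resolution, scaled with size
    spot_count_range: tuple[int, int] = (2, 5)
    spot_radius_frac: tuple[float, float] = (0.07, 0.12)  # of image size
    scorch_depth: float = 0.30         # fraction of the leaf radius that browns
    color_jitter: float = 18.0         # uint8 units

    def __post_init__(self):
        self.classes = list(self.classes)
        self.spot_count_range = tuple(self.spot_count_range)
        self.spot_radius_frac = tuple(self.spot_radius_frac)
        unknown = set(self.classes) - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown class(es) {sorted(unknown)}; valid: {CLASS_NAMES}")
        if self.n_per_class < 1:
            raise ValueError(f"n_per_class must be >= 1, got {self.n_per_class}")
        if self.image_size < 32:
            raise ValueError(f"image_size must be >= 32, got {self.image_size}")


@dataclass
class LabeledImageSet:
    images: np.ndarray          # (N, H, W, 3) uint8
    labels: list[str]
    classes: list[str]
    split: str | None = None    # "train" / "test" / None

    def __post_init__(self):
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels differ in length")
        bad = set(self.labels) - set(self.classes)
        if bad:
            raise ValueError(f"labels outside class list: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def label_indices(self) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.classes)}
        return np.array([lut[l] for l in self.labels], dtype=np.int64)

    def class_counts(self) -> dict[str, int]:
        return {c: self.labels.count(c) for c in self.classes}

    def save_to_folder(self, root: str | Path) -> list[tuple[str, str]]:
        """Write ImageFolder layout root/<class>/<i>.png; returns the manifest."""
        root = Path(root)
        manifest = []
        counters = {c: 0 for c in self.classes}
        for img, label in zip(self.images, self.labels):
            d = root / label
            d.mkdir(parents=True, exist_ok=True)
            path = d / f"{counters[label]:05d}.png"
            Image.fromarray(img).save(path)
            counters[label] += 1
            manifest.append((str(path), label))
        return manifest


@dataclass
class TensorDataset:
    """Network-ready images: (N, 3, S, S) float32, standardized."""

    x: np.ndarray
    y: np.ndarray               # int class indices
    classes: list[str]
    mean: np.ndarray            # per-channel, on the [0,1] scale
    std: np.ndarray

    def __len__(self) -> int:
        return len(self.x)

    def denormalize(self) -> np.ndarray:
        """Invert standardization back to [0,1]-scaled images."""
        return self.x * self.std[None, :, None, None] + self.mean[None, :, None, None]


# ---------------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------------


def _leaf_geometry(rng: np.random.Generator, s: int):
    cx = s / 2 + rng.uniform(-0.04, 0.04) * s
    cy = s / 2 + rng.uniform(-0.04, 0.04) * s
    ax = rng.uniform(0.34, 0.42) * s
    ay = rng.uniform(0.24, 0.32) * s
    theta = rng.uniform(0, np.pi)
    return cx, cy, ax, ay, theta


def _leaf_rho(s: int, cx, cy, ax, ay, theta) -> np.ndarray:
    """Normalized elliptical radius per pixel (<=1 inside the leaf)."""
    yy, xx = np.mgrid[0:s, 0:s]
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return np.sqrt((u / ax) ** 2 + (v / ay) ** 2)


def _render_leaf_image(rng: np.random.Generator, cfg: SynthConfig, label: str) -> np.ndarray:
    s = cfg.image_size
    j = cfg.color_jitter

    # textured soil-like background
    bg = np.array([126.0, 104.0, 78.0]) + rng.uniform(-j, j, 3)
    img = bg[None, None, :] + rng.normal(0, 10, size=(s, s, 3))

    cx, cy, ax, ay, theta = _leaf_geometry(rng, s)
    rho = _leaf_rho(s, cx, cy, ax, ay, theta)
    leaf = rho <= 1.0

    green = np.array([52.0, 138.0, 54.0]) + rng.uniform(-j, j, 3)
    shading = 1.0 - 0.25 * rho[..., None]  # brighter center, darker rim
    leaf_px = green[None, None, :] * shading + rng.normal(0, 6, size=(s, s, 3))
    img = np.where(leaf[..., None], leaf_px, img)

    if label in ("SD", "SD+RD"):
        # scorch: brown the outer margin of the blade
        depth = cfg.scorch_depth * rng.uniform(0.8, 1.2)
        margin = leaf & (rho > 1.0 - depth)
        brown = np.array([118.0, 74.0, 28.0]) + rng.uniform(-j, j, 3)
        blend = np.clip((rho - (1.0 - depth)) / depth, 0, 1)[..., None]
        img = np.where(margin[..., None], (1 - 0.85 * blend) * img + 0.85 * blend * brown, img)

    if label in ("RD", "SD+RD"):
        # rust: many small orange specks scattered on the blade
        n_specks = max(3, rng.poisson(cfg.rust_speck_density * (2 * ax) * (2 * ay) / 256.0))
        r_speck = cfg.rust_speck_radius * s / 64.0
        yy, xx = np.mgrid[0:s, 0:s]
        for _ in range(n_specks):
            rr = np.sqrt(rng.uniform(0, 0.9))
            phi = rng.uniform(0, 2 * np.pi)
            u, v = rr * ax * np.cos(phi), rr * ay * np.sin(phi)
            px = cx + u * np.cos(theta) - v * np.sin(theta)
            py = cy + u * np.sin(theta) + v * np.cos(theta)
            rad = r_speck * rng.uniform(0.7, 1.5)
            disk = (xx - px) ** 2 + (yy - py) ** 2 <= rad**2
            orange = np.array([214.0, 128.0, 26.0]) + rng.uniform(-j, j, 3)
            img = np.where((disk & leaf)[..., None], orange[None, None, :], img)

    if label == "LSD":
        # leaf spot: a few large dark lesions with lighter halos
        n_spots = rng.integers(cfg.spot_count_range[0], cfg.spot_count_range[1] + 1)
        yy, xx = np.mgrid[0:s, 0:s]
        for _ in range(n_spots):
            rr = np.sqrt(rng.uniform(0, 0.55))
            phi = rng.uniform(0, 2 * np.pi)
            u, v = rr * ax * np.cos(phi), rr * ay * np.sin(phi)
            px = cx + u * np.cos(theta) - v * np.sin(theta)
            py = cy + u * np.sin(theta) + v * np.cos(theta)
            rad = rng.uniform(*cfg.spot_radius_frac) * s
            d2 = (xx - px) ** 2 + (yy - py) ** 2
            halo = (d2 <= (1.45 * rad) ** 2) & leaf
            core = (d2 <= rad**2) & leaf
            tan = np.array([196.0, 172.0, 118.0]) + rng.uniform(-j, j, 3)
            dark = np.array([92.0, 58.0, 30.0]) + rng.uniform(-j, j, 3)
            img = np.where(halo[..., None], tan[None, None, :], img)
            img = np.where(core[..., None], dark[None, None, :], img)

    return np.clip(img, 0, 255).astype(np.uint8)


def generate_synthetic_dataset(cfg: SynthConfig) -> LabeledImageSet:
    """Render ``n_per_class`` images per configured class, deterministically."""
    images, labels = [], []
    for ci, cls in enumerate(cfg.classes):
        for i in range(cfg.n_per_class):
            rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, ci, i]))
            images.append(_render_leaf_image(rng, cfg, cls))
            labels.append(cls)
    return LabeledImageSet(images=np.stack(images), labels=labels, classes=list(cfg.classes))


def lesion_mask(cfg: SynthConfig, class_name: str, index: int) -> np.ndarray:
    """Boolean mask of lesioned pixels for a generated image (same RNG stream).

    Used to check that class-activation maps concentrate on the lesions.
    """
    ci = cfg.classes.index(class_name)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, ci, index]))
    base = _render_leaf_image(rng, cfg, class_name)
    rng2 = np.random.default_rng(np.random.SeedSequence([cfg.seed, ci, index]))
    healthy = _render_leaf_image(rng2, cfg, "HL")
    return np.any(np.abs(base.astype(int) - healthy.astype(int)) > 30, axis=2)


# ---------------------------------------------------------------------------
# split / amplification / loading
# ---------------------------------------------------------------------------


def split_dataset(dataset: LabeledImageSet, seed: int = 0) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Stratified 4:1 train/test split; test takes round(n/5) per class."""
    rng = np.random.default_rng(seed)
    labels = np.array(dataset.labels)
    train_idx, test_idx = [], []
    for cls in dataset.classes:
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 5:
            raise ValueError(f"class {cls!r} has {len(idx)} records; need >= 5 for a 4:1 split")
        idx = rng.permutation(idx)
        n_test = int(round(len(idx) / 5))
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    train_idx, test_idx = sorted(train_idx), sorted(test_idx)

    def subset(ix, tag):
        return LabeledImageSet(
            images=dataset.images[ix],
            labels=[dataset.labels[i] for i in ix],
            classes=list(dataset.classes),
            split=tag,
        )

    return subset(train_idx, "train"), subset(test_idx, "test")


def amplify(train: LabeledImageSet, include_vertical_flip: bool = False) -> LabeledImageSet:
    """Rotation/flip amplification of a *training* set.

    Each image yields itself plus rot90/rot180/rot270 and a horizontal flip
    (x5); ``include_vertical_flip`` adds the vertical flip (x6).
    """
    if train.split == "test":
        raise ValueError("amplification must never touch the test set")
    out_images, out_labels = [], []
    for img, label in zip(train.images, train.labels):
        variants = [
            img,
            np.rot90(img, 1, axes=(0, 1)),
            np.rot90(img, 2, axes=(0, 1)),
            np.rot90(img, 3, axes=(0, 1)),
            img[:, ::-1],  # horizontal flip
        ]
        if include_vertical_flip:
            variants.append(img[::-1, :])
        out_images.extend(v.copy() for v in variants)
        out_labels.extend([label] * len(variants))
    return LabeledImageSet(images=np.stack(out_images), labels=out_labels,
                           classes=list(train.classes), split=train.split)


def load_image_folder(root: str | Path) -> LabeledImageSet:
    """Read an ImageFolder layout (root/<class>/*.png|jpg|jpeg).

    Undecodable files are skipped with a logged warning; an empty class
    directory is an error. Images may have heterogeneous sizes here;
    :func:`load_standardize` unifies them.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    classes = sorted(d.name for d in root.iterdir() if d.is_dir())
    if not classes:
        raise ValueError(f"no class subdirectories under {root}")
    images, labels = [], []
    for cls in classes:
        files = sorted(p for p in (root / cls).iterdir()
                       if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
        loaded = 0
        for p in files:
            try:
                with Image.open(p) as im:
                    images.append(np.asarray(im.convert("RGB")))
                loaded += 1
            except Exception as e:  # undecodable file
                log.warning("skipping undecodable image %s: %s", p, e)
        if loaded == 0:
            raise ValueError(f"class directory {root / cls} contains no decodable images")
        labels.extend([cls] * loaded)
    if len({im.shape for im in images}) == 1:
        images = np.stack(images)
    else:
        images = np.array(images, dtype=object)
    return LabeledImageSet(images=images, labels=labels, classes=classes)


def load_standardize(
    path_or_set: str | Path | LabeledImageSet,
    size: int = 224,
    mean: np.ndarray | None = None,
    std: np.ndarray | None = None,
    scale_only: bool = False,
) -> TensorDataset:
    """Resize to ``size`` (bilinear), scale to [0,1], standardize per channel.

    Channel mean/std default to statistics of the given set (pass the
    training split's ``mean``/``std`` when standardizing a test split);
    ``scale_only`` keeps plain [0,1] scaling.
    """
    dataset = path_or_set if isinstance(path_or_set, LabeledImageSet) else load_image_folder(path_or_set)
    resized = []
    for img in dataset.images:
        img = np.asarray(img)
        if img.shape[:2] != (size, size):
            img = np.asarray(Image.fromarray(img).resize((size, size), Image.BILINEAR))
        resized.append(img)
    x = np.stack(resized).astype(np.float32) / 255.0          # (N,H,W,3) in [0,1]
    x = x.transpose(0, 3, 1, 2)                               # (N,3,H,W)
    if scale_only:
        mean = np.zeros(3, dtype=np.float32)
        std = np.ones(3, dtype=np.float32)
    else:
        if mean is None:
            mean = x.mean(axis=(0, 2, 3))
        if std is None:
            std = x.std(axis=(0, 2, 3)) + 1e-8
        mean = np.asarray(mean, dtype=np.float32)
        std = np.asarray(std, dtype=np.float32)
    x = (x - mean[None, :, None, None]) / std[None, :, None, None]
    return TensorDataset(x=x, y=dataset.label_indices, classes=list(dataset.classes),
                         mean=mean, std=std)
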