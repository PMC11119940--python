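"""Image ingestion, preprocessing, splitting, and a synthetic long-tailed
pest-image generator.

The preprocessing contract: the shorter image side is resized to the crop
size (256 at full scale) preserving aspect ratio; training draws random
crops of that size, evaluation uses the deterministic center crop.

The synthetic generator renders, per class, a distinctive parametric motif —
a shape family plus a color band plus a stripe texture — at randomised
position, scale and rotation over procedurally cluttered backgrounds.  Class
counts follow the power law  n_c = round(max · c^(−exponent)), c = 1..C,
emulating the long-tailed class distribution of field-collected pest
benchmarks.  The counts are computed, not sampled, so the empirical
histogram matches the law exactly, and everything is reproducible from the
seed down to the byte level.
"""

from __future__ import annotations

import colorsys
import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

__all__ = [
    "DatasetManifest", "SplitSpec", "SyntheticSpec",
    "resize_short_side", "crop", "split", "generate_synthetic",
    "save_dataset", "load_manifest", "images_to_batch",
]

_IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
_IMAGENET_STD = np.array([0.229, 0.224, 0.225])


def _round_half_up(x) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5).astype(np.int64)


@dataclass
class DatasetManifest:
    """Records of (image, label); an image is an RGB uint8 array or a path."""

    records: list
    class_names: list = field(default_factory=list)

    def __post_init__(self):
        if self.records and not self.class_names:
            c = max(label for _, label in self.records) + 1
            self.class_names = [f"class_{i}" for i in range(c)]

    def __len__(self):
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([label for _, label in self.records], dtype=np.int64)

    @property
    def num_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        counts = np.zeros(self.num_classes, dtype=np.int64)
        np.add.at(counts, self.labels, 1)
        return counts

    def subset(self, indices) -> "DatasetManifest":
        return DatasetManifest([self.records[i] for i in indices],
                               list(self.class_names))

    def image(self, i) -> np.ndarray:
        img, _ = self.records[i]
        if isinstance(img, np.ndarray):
            return img
        try:
            with Image.open(img) as im:
                return np.asarray(im.convert("RGB"))
        except OSError as exc:
            raise OSError(f"cannot read image {img!r}: {exc}") from exc


@dataclass
class SplitSpec:
    """70% train; the 30% remainder split 30/70 into validation/test."""

    train_fraction: float = 0.7
    remainder_val_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for f in (self.train_fraction, self.remainder_val_fraction):
            if not 0 < f < 1:
                raise ValueError("split fractions must lie in (0, 1)")


def split(manifest: DatasetManifest, spec: SplitSpec | None = None):
    """Partition a manifest into (train, val, test) manifests.

    |train| = floor(train_fraction · n); of the remainder,
    |val| = round-half-up(remainder_val_fraction · remainder) and the rest is
    test.  Shuffling is driven by ``spec.seed``; the three subsets are
    disjoint and exhaustive.
    """
    spec = spec or SplitSpec()
    n = len(manifest)
    if n == 0:
        raise ValueError("cannot split an empty manifest")
    n_train = int(np.floor(spec.train_fraction * n))
    rem = n - n_train
    n_val = int(_round_half_up(spec.remainder_val_fraction * rem))
    n_test = rem - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"split of {n} samples yields an empty subset "
            f"({n_train}/{n_val}/{n_test})")
    order = np.random.default_rng(spec.seed).permutation(n)
    return (manifest.subset(order[:n_train]),
            manifest.subset(order[n_train:n_train + n_val]),
            manifest.subset(order[n_train + n_val:]))


# -- preprocessing ------------------------------------------------------------

def resize_short_side(img, target: int = 256):
    """Resize so the shorter side equals ``target``, preserving aspect ratio
    (bilinear).  Accepts and returns either a PIL image or an RGB array."""
    was_array = isinstance(img, np.ndarray)
    pil = Image.fromarray(img) if was_array else img
    w, h = pil.size
    if min(w, h) < 1:
        raise ValueError("degenerate image")
    if w <= h:
        new_w, new_h = target, int(round(h * target / w))
    else:
        new_w, new_h = int(round(w * target / h)), target
    out = pil.resize((new_w, new_h), Image.BILINEAR)
    return np.asarray(out) if was_array else out


def crop(img, mode: str = "center", seed: int | None = None, size: int = 256,
         rng: np.random.Generator | None = None) -> np.ndarray:
    """Cut a size×size window; ``random`` draws the offset from the seeded
    stream, ``center`` is deterministic.  Images smaller than the window are
    reflection-padded first."""
    if mode not in ("random", "center"):
        raise ValueError(f"unknown crop mode {mode!r}")
    arr = np.asarray(img)
    h, w = arr.shape[:2]
    pad_h, pad_w = max(size - h, 0), max(size - w, 0)
    if pad_h or pad_w:
        pads = ((pad_h // 2, pad_h - pad_h // 2), (pad_w // 2, pad_w - pad_w // 2))
        pads += ((0, 0),) * (arr.ndim - 2)
        arr = np.pad(arr, pads, mode="reflect")
        h, w = arr.shape[:2]
    if mode == "center":
        top, left = (h - size) // 2, (w - size) // 2
    else:
        rng = rng if rng is not None else np.random.default_rng(seed)
        top = int(rng.integers(0, h - size + 1))
        left = int(rng.integers(0, w - size + 1))
    return arr[top:top + size, left:left + size]


# -- synthetic data -----------------------------------------------------------

@dataclass
class SyntheticSpec:
    num_classes: int = 5
    images_per_class_max: int = 60
    imbalance_exponent: float = 1.0
    image_size: int = 64
    motif_size_range: tuple = (0.25, 0.45)   # motif radius, fraction of image
    background_clutter_level: float = 0.5    # 0 = flat background, 1 = busy
    seed: int = 0

    def class_counts(self) -> np.ndarray:
        """n_c = round(max · c^(−exponent)) for c = 1..C (half-up rounding)."""
        if self.num_classes < 1:
            raise ValueError("need at least one class")
        ranks = np.arange(1, self.num_classes + 1, dtype=np.float64)
        return _round_half_up(self.images_per_class_max
                              * ranks ** (-self.imbalance_exponent))


_SHAPES = ("disk", "square", "triangle", "ring", "cross", "diamond",
           "ellipse", "bar")


def _class_style(c: int, num_classes: int) -> dict:
    """Deterministic per-class motif style: shape family + color band."""
    hue = (c / max(num_classes, 1)) % 1.0
    rgb = np.array(colorsys.hsv_to_rgb(hue, 0.85, 0.9))
    return {"shape": _SHAPES[c % len(_SHAPES)], "color": rgb,
            "stripe_period": 3 + (c % 4)}


def _shape_mask(shape: str, size: int, cy, cx, r, angle) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    y = (yy - cy) / r
    x = (xx - cx) / r
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * x + sa * y
    v = -sa * x + ca * y
    if shape == "disk":
        return u * u + v * v <= 1.0
    if shape == "square":
        return np.maximum(np.abs(u), np.abs(v)) <= 0.85
    if shape == "triangle":
        return (v >= -0.7) & (v <= 1.0 - 2.0 * np.abs(u))
    if shape == "ring":
        rr = np.sqrt(u * u + v * v)
        return (rr <= 1.0) & (rr >= 0.55)
    if shape == "cross":
        return ((np.abs(u) <= 0.3) | (np.abs(v) <= 0.3)) \
            & (np.maximum(np.abs(u), np.abs(v)) <= 1.0)
    if shape == "diamond":
        return np.abs(u) + np.abs(v) <= 1.0
    if shape == "ellipse":
        return u * u + (v / 0.5) ** 2 <= 1.0
    if shape == "bar":
        return (np.abs(u) <= 1.0) & (np.abs(v) <= 0.35)
    raise ValueError(shape)


def _background(size: int, clutter: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency color field plus random distractor blobs."""
    coarse = rng.uniform(0.15, 0.6, (4, 4, 3))
    img = np.kron(coarse, np.ones((size // 4 + 1, size // 4 + 1, 1)))[:size, :size]
    n_blobs = int(np.ceil(clutter * 6))
    for _ in range(n_blobs):
        r = rng.uniform(0.05, 0.2) * size
        cy, cx = rng.uniform(0, size, 2)
        tone = rng.uniform(0.1, 0.7, 3)
        mask = _shape_mask("disk", size, cy, cx, r, 0.0)
        img[mask] = 0.6 * img[mask] + 0.4 * tone
    img += rng.normal(0, 0.03 * clutter, img.shape)
    return np.clip(img, 0, 1)


def _render(spec: SyntheticSpec, style: dict, rng: np.random.Generator) -> np.ndarray:
    size = spec.image_size
    img = _background(size, spec.background_clutter_level, rng)
    lo, hi = spec.motif_size_range
    r = rng.uniform(lo, hi) * size
    margin = r * 0.7
    cy = rng.uniform(margin, size - margin)
    cx = rng.uniform(margin, size - margin)
    angle = rng.uniform(0, 2 * np.pi)
    mask = _shape_mask(style["shape"], size, cy, cx, r, angle)
    color = np.clip(style["color"] + rng.normal(0, 0.04, 3), 0, 1)
    # stripe texture along the motif's rotated axis
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    u = np.cos(angle) * (xx - cx) + np.sin(angle) * (yy - cy)
    stripes = 0.85 + 0.15 * np.sin(2 * np.pi * u / style["stripe_period"])
    fill = color[None, None, :] * stripes[..., None]
    img = np.where(mask[..., None], 0.15 * img + 0.85 * fill, img)
    return (np.clip(img, 0, 1) * 255).astype(np.uint8)


def generate_synthetic(spec: SyntheticSpec) -> DatasetManifest:
    """Render the full synthetic dataset described by ``spec``.

    Deterministic: the same spec (including seed) yields byte-identical
    images in the same order.
    """
    if spec.num_classes < 1:
        raise ValueError("need at least one class")
    if spec.image_size < 8:
        raise ValueError("image_size too small")
    counts = spec.class_counts()
    rng = np.random.default_rng(spec.seed)
    records = []
    for c, n in enumerate(counts):
        style = _class_style(c, spec.num_classes)
        for _ in range(int(n)):
            records.append((_render(spec, style, rng), c))
    names = [f"synthetic_{_SHAPES[c % len(_SHAPES)]}_{c}" for c in range(spec.num_classes)]
    return DatasetManifest(records, names)


# -- on-disk layout -----------------------------------------------------------

def save_dataset(manifest: DatasetManifest, out_dir: str) -> str:
    """Write one PNG subdirectory per class plus a path<TAB>label manifest."""
    os.makedirs(out_dir, exist_ok=True)
    lines = []
    per_class = {}
    for i in range(len(manifest)):
        img = manifest.image(i)
        label = manifest.records[i][1]
        cls_dir = os.path.join(out_dir, manifest.class_names[label])
        os.makedirs(cls_dir, exist_ok=True)
        k = per_class.get(label, 0)
        per_class[label] = k + 1
        path = os.path.join(cls_dir, f"{k:05d}.png")
        Image.fromarray(img).save(path)
        lines.append(f"{path}\t{label}")
    tsv = os.path.join(out_dir, "manifest.tsv")
    with open(tsv, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return tsv


def load_manifest(path: str) -> DatasetManifest:
    """Load from a TSV manifest file or a class-per-subdirectory tree."""
    if os.path.isfile(path):
        records = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                img_path, label = line.rsplit("\t", 1)
                records.append((img_path, int(label)))
        return DatasetManifest(records)
    classes = sorted(
        d for d in os.listdir(path) if os.path.isdir(os.path.join(path, d)))
    if not classes:
        raise ValueError(f"no class subdirectories under {path!r}")
    records = []
    for label, cls in enumerate(classes):
        cls_dir = os.path.join(path, cls)
        for name in sorted(os.listdir(cls_dir)):
            if name.lower().endswith((".png", ".jpg", ".jpeg")):
                records.append((os.path.join(cls_dir, name), label))
    return DatasetManifest(records, classes)


def images_to_batch(images, normalize_imagenet: bool = False) -> np.ndarray:
    """Stack HWC uint8/float images into a float NCHW batch in [0, 1]."""
    batch = np.stack([np.asarray(im, dtype=np.float64) for im in images])
    if batch.max() > 1.5:
        batch = batch / 255.0
    batch = batch.transpose(0, 3, 1, 2)
    if normalize_imagenet:
        batch = (batch - _IMAGENET_MEAN[:, None, None]) / _IMAGENET_STD[:, None, None]
    return batch
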