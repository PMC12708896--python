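"""Synthetic leaf-lesion dataset generator and classifier-output simulator.

Real plant-disease corpora (PlantVillage-style) are directories of RGB
leaf photos, one folder per plant-disease class, with no segmentation
ground truth.  This module emulates that layout procedurally: each image
is a superellipse "leaf" with vein lines on a dark backdrop, and each
class paints elliptical lesions with a class-specific color, count and
radius distribution.  Because lesions are painted by the generator, an
exact binary mask comes for free, which is what makes the segmentation
stage trainable and Dice-scorable.

A second simulator fabricates per-classifier probability matrices with
controlled argmax accuracy, so the decision-fusion stage can be
exercised and benchmarked without training any network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage


class ValidationError(ValueError):
    """Raised when a spec violates its invariants; names the offending field."""


# --------------------------------------------------------------------------
# specs


@dataclass
class ClassStyle:
    """Lesion geometry and color for one class."""

    lesion_count_range: tuple[int, int] = (2, 5)
    lesion_radius_range: tuple[float, float] = (4.0, 9.0)
    lesion_color: tuple[float, float, float] = (0.45, 0.30, 0.10)
    lesion_color_sd: float = 0.04
    texture_noise_sd: float = 0.02
    blur_sigma: float = 0.8


@dataclass
class BackgroundStyle:
    leaf_color: tuple[float, float, float] = (0.18, 0.45, 0.16)
    leaf_color_sd: float = 0.03
    vein_count: int = 5
    backdrop_color: tuple[float, float, float] = (0.06, 0.05, 0.04)


@dataclass
class DatasetSpec:
    """Configuration of one synthetic dataset.

    Defaults mirror the structure of the public corpus the pipeline
    targets: 38 classes of 224 x 224 RGB leaf images.
    """

    n_classes: int = 38
    images_per_class: int = 10
    image_size: int = 224
    class_styles: list[ClassStyle] | None = None
    background_style: BackgroundStyle = field(default_factory=BackgroundStyle)
    lighting_jitter: tuple[float, float] = (0.9, 1.1)
    lesion_region: str | None = None   # None (anywhere) or "top_left"
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValidationError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.images_per_class < 1:
            raise ValidationError(
                f"images_per_class must be >= 1, got {self.images_per_class}")
        if self.image_size < 32:
            raise ValidationError(f"image_size must be >= 32, got {self.image_size}")
        if self.class_styles is None:
            self.class_styles = default_class_styles(self.n_classes, self.image_size)
        if len(self.class_styles) != self.n_classes:
            raise ValidationError(
                f"class_styles has {len(self.class_styles)} entries for "
                f"{self.n_classes} classes")
        for k, st in enumerate(self.class_styles):
            lo, hi = st.lesion_count_range
            if lo > hi or lo < 0:
                raise ValidationError(f"class_styles[{k}].lesion_count_range invalid")
            rlo, rhi = st.lesion_radius_range
            if rlo > rhi or rlo <= 0:
                raise ValidationError(f"class_styles[{k}].lesion_radius_range invalid")
            if rhi >= self.image_size / 2:
                raise ValidationError(
                    f"class_styles[{k}].lesion_radius_range exceeds image_size/2")
        lo, hi = self.lighting_jitter
        if lo > hi or lo <= 0:
            raise ValidationError("lighting_jitter interval invalid")
        if self.lesion_region not in (None, "top_left"):
            raise ValidationError(f"unknown lesion_region '{self.lesion_region}'")


def default_class_styles(n_classes: int, image_size: int = 224) -> list[ClassStyle]:
    """Pairwise-separable styles: lesion hues spread around the color wheel,
    radii scaled to the image so small canvases still fit lesions."""
    import colorsys

    scale = image_size / 224.0
    styles = []
    for k in range(n_classes):
        # distinct lesion hues keep the default classes pairwise separable
        # by color alone; the band [0.5, 1.25) mod 1 skips leaf greens so
        # lesions stay visible against the canvas
        hue = (0.5 + 0.75 * k / n_classes) % 1.0
        r, g, b = colorsys.hsv_to_rgb(hue, 0.85, 0.72)
        styles.append(ClassStyle(
            lesion_count_range=(2 + (k % 3), 4 + (k % 3)),
            lesion_radius_range=(max(3.0, (4 + (k % 4)) * scale),
                                 max(4.0, (7 + (k % 4)) * scale)),
            lesion_color=(r, g, b),
        ))
    return styles


@dataclass
class SyntheticSample:
    """One labeled image with its ground-truth lesion mask."""

    image: np.ndarray   # H x W x 3 float in [0, 1]
    mask: np.ndarray    # H x W uint8 in {0, 1}
    label: int


# --------------------------------------------------------------------------
# image synthesis


def _leaf_canvas(size: int, bg: BackgroundStyle, rng: np.random.Generator):
    """Superellipse leaf with veins on a dark backdrop; returns image and
    the boolean leaf region."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cy = cx = (size - 1) / 2.0
    ry = size * rng.uniform(0.38, 0.46)
    rx = size * rng.uniform(0.30, 0.42)
    theta = rng.uniform(-0.5, 0.5)
    ys = (yy - cy) * np.cos(theta) + (xx - cx) * np.sin(theta)
    xs = -(yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
    p = rng.uniform(1.6, 2.4)
    leaf = (np.abs(ys / ry) ** p + np.abs(xs / rx) ** p) <= 1.0

    img = np.empty((size, size, 3))
    img[:] = bg.backdrop_color
    leaf_col = np.clip(
        np.asarray(bg.leaf_color) + rng.normal(0, bg.leaf_color_sd, 3), 0, 1)
    shading = 1.0 + 0.15 * (xs / (rx + 1e-9))
    img[leaf] = leaf_col * shading[leaf, None]

    # veins: darker lines through the leaf midrib and offshoots
    vein = np.abs(xs) < (0.6 + 0.4 * rng.random())
    for i in range(bg.vein_count):
        slope = rng.uniform(-1.2, 1.2)
        off = rng.uniform(-0.8, 0.8) * ry
        vein |= np.abs(xs - slope * (ys - off)) < 0.5
    vein &= leaf
    img[vein] *= 0.75
    return np.clip(img, 0, 1), leaf


def _paint_lesions(img: np.ndarray, leaf: np.ndarray, style: ClassStyle,
                   rng: np.random.Generator, region: str | None = None):
    """Paint elliptical lesions inside the leaf; returns the binary mask."""
    size = img.shape[0]
    mask = np.zeros((size, size), dtype=bool)
    n = int(rng.integers(style.lesion_count_range[0], style.lesion_count_range[1] + 1))
    placeable = leaf
    if region == "top_left":
        # keep whole lesions (not just centers) inside the quadrant
        margin = int(np.ceil(style.lesion_radius_range[1]))
        lim = max(size // 2 - margin, 4)
        box = np.zeros_like(leaf)
        box[:lim, :lim] = True
        if (leaf & box).any():
            placeable = leaf & box
    ys_leaf, xs_leaf = np.nonzero(placeable)
    if len(ys_leaf) == 0 or n == 0:
        return mask.astype(np.uint8)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    for _ in range(n):
        j = int(rng.integers(len(ys_leaf)))
        cy, cx = float(ys_leaf[j]), float(xs_leaf[j])
        a = rng.uniform(*style.lesion_radius_range)
        b = a * rng.uniform(0.6, 1.0)
        th = rng.uniform(0, np.pi)
        yr = (yy - cy) * np.cos(th) + (xx - cx) * np.sin(th)
        xr = -(yy - cy) * np.sin(th) + (xx - cx) * np.cos(th)
        d2 = (yr / a) ** 2 + (xr / b) ** 2
        inside = (d2 <= 1.0) & leaf
        # anti-aliased color blend near the rim, hard mask at d2 <= 1
        soft = np.clip(1.15 - d2, 0, 1.0)
        soft[~leaf] = 0.0
        col = np.clip(np.asarray(style.lesion_color)
                      + rng.normal(0, style.lesion_color_sd, 3), 0, 1)
        w = np.minimum(soft, 1.0)[..., None]
        img[:] = img * (1 - w) + w * col
        mask |= inside
    return mask.astype(np.uint8)


def generate_leaf_dataset(spec: DatasetSpec) -> list[SyntheticSample]:
    """Generate ``n_classes * images_per_class`` labeled samples.

    Deterministic given ``spec.seed``; samples are ordered class-major
    (all of class 0, then class 1, ...).
    """
    rng = np.random.default_rng(spec.seed)
    samples: list[SyntheticSample] = []
    for label in range(spec.n_classes):
        style = spec.class_styles[label]
        for _ in range(spec.images_per_class):
            img, leaf = _leaf_canvas(spec.image_size, spec.background_style, rng)
            mask = _paint_lesions(img, leaf, style, rng, spec.lesion_region)
            if style.texture_noise_sd > 0:
                img += rng.normal(0, style.texture_noise_sd, img.shape)
            if style.blur_sigma > 0:
                img = ndimage.gaussian_filter(img, (style.blur_sigma, style.blur_sigma, 0))
            img *= rng.uniform(*spec.lighting_jitter)
            samples.append(SyntheticSample(
                image=np.clip(img, 0, 1).astype(np.float32),
                mask=mask,
                label=label,
            ))
    return samples


# --------------------------------------------------------------------------
# dataset I/O (PlantVillage-style directory-per-class layout)


def write_dataset(samples: list[SyntheticSample], root_path) -> dict:
    """Write PNGs in a directory-per-class layout plus a JSON manifest.

    Layout: ``root/class_<k>/img_<j>.png`` with masks mirrored under
    ``root/masks/class_<k>/img_<j>.png`` (8-bit, 0/255).
    """
    root = Path(root_path)
    entries = []
    counters: dict[int, int] = {}
    for s in samples:
        j = counters.get(s.label, 0)
        counters[s.label] = j + 1
        rel_img = f"class_{s.label}/img_{j}.png"
        rel_mask = f"masks/class_{s.label}/img_{j}.png"
        img_path = root / rel_img
        mask_path = root / rel_mask
        img_path.parent.mkdir(parents=True, exist_ok=True)
        mask_path.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray((s.image * 255).round().astype(np.uint8)).save(img_path)
        Image.fromarray((s.mask * 255).astype(np.uint8)).save(mask_path)
        entries.append({"image": rel_img, "mask": rel_mask, "label": int(s.label)})
    manifest = {"n_samples": len(entries), "files": entries}
    if entries:
        (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_dataset(root_path) -> list[SyntheticSample]:
    """Load a dataset previously written by :func:`write_dataset`."""
    root = Path(root_path)
    manifest = json.loads((root / "manifest.json").read_text())
    samples = []
    for e in manifest["files"]:
        img = np.asarray(Image.open(root / e["image"]), dtype=np.float32) / 255.0
        mask = (np.asarray(Image.open(root / e["mask"])) > 127).astype(np.uint8)
        samples.append(SyntheticSample(image=img, mask=mask, label=int(e["label"])))
    return samples


# --------------------------------------------------------------------------
# simulated classifier outputs


@dataclass
class ClassifierOutputSpec:
    """Controls the simulator of per-classifier probability matrices."""

    n_classifiers: int
    n_samples: int
    n_classes: int
    target_accuracies: tuple[float, ...]
    concentration: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if len(self.target_accuracies) != self.n_classifiers:
            raise ValidationError(
                "target_accuracies length must equal n_classifiers "
                f"({len(self.target_accuracies)} vs {self.n_classifiers})")
        for a in self.target_accuracies:
            if not 0.0 <= a <= 1.0:
                raise ValidationError(f"target_accuracies entry {a} outside [0, 1]")
        if self.concentration <= 0:
            raise ValidationError("concentration must be positive")
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")


def simulate_classifier_outputs(spec: ClassifierOutputSpec,
                                labels: np.ndarray) -> list[np.ndarray]:
    """One row-stochastic ``n_samples x n_classes`` matrix per classifier.

    For each sample a Bernoulli(target_accuracy) draw decides whether the
    row's argmax is the true label or a uniformly drawn wrong class; row
    shapes come from a Dirichlet peaked at the chosen mode with strength
    ``concentration``.
    """
    labels = np.asarray(labels)
    if len(labels) != spec.n_samples:
        raise ValidationError("labels length must equal n_samples")
    if labels.min() < 0 or labels.max() >= spec.n_classes:
        raise ValidationError("labels out of range for n_classes")
    rng = np.random.default_rng(spec.seed)
    K = spec.n_classes
    out = []
    for acc in spec.target_accuracies:
        correct = rng.random(spec.n_samples) < acc
        offsets = rng.integers(1, K, size=spec.n_samples)
        modes = np.where(correct, labels, (labels + offsets) % K)
        alpha = np.ones(K)
        rows = np.empty((spec.n_samples, K))
        for i in range(spec.n_samples):
            a = alpha.copy()
            a[modes[i]] += spec.concentration
            row = rng.dirichlet(a)
            top = int(row.argmax())
            if top != modes[i]:       # enforce the argmax contract exactly
                row[top], row[modes[i]] = row[modes[i]], row[top]
            rows[i] = row
        out.append(rows)
    return out
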