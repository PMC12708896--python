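"""Resizing, normalization and seedable augmentation transforms.

Images travel as H x W x 3 float arrays in [0, 1]; masks as H x W binary
arrays.  Geometric transforms (rotation, flips, scaling) are applied
identically to image and mask — the mask with nearest-neighbor
interpolation so it stays binary — while photometric transforms
(brightness, contrast, grayscale) never touch the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .synthetic import SyntheticSample, ValidationError

GEOMETRIC_OPS = ("rotate", "horizontal_flip", "vertical_flip", "scale")
PHOTOMETRIC_OPS = ("brightness", "contrast", "grayscale")
KNOWN_OPS = GEOMETRIC_OPS + PHOTOMETRIC_OPS


def _check_image(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError(f"expected H x W x 3 image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float32) / 255.0
    return arr.astype(np.float32)


def resize_and_normalize(image, size: int, mask: np.ndarray | None = None):
    """Bilinear-resize to ``size x size`` with values in [0, 1].

    A paired mask, if given, is resized nearest-neighbor and re-binarized;
    returns ``(image, mask)`` then, else just the image.
    """
    arr = _check_image(image)
    out = _sk_resize(arr, (size, size), order=1, anti_aliasing=False,
                     preserve_range=True).astype(np.float32)
    out = np.clip(out, 0.0, 1.0)
    if mask is None:
        return out
    m = _sk_resize(np.asarray(mask).astype(np.float32), (size, size), order=0,
                   anti_aliasing=False, preserve_range=True)
    return out, (m > 0.5).astype(np.uint8)


@dataclass
class AugmentationPlan:
    """Ordered augmentation recipe with per-op apply probabilities.

    Ranges are intervals the per-call parameters are drawn from; the
    defaults are mild enough to preserve label semantics.
    """

    operations: tuple[str, ...] = ("rotate", "horizontal_flip", "vertical_flip",
                                   "scale", "brightness", "contrast")
    rotation_degrees: tuple[float, float] = (-30.0, 30.0)
    scale_range: tuple[float, float] = (0.8, 1.2)
    brightness_range: tuple[float, float] = (0.8, 1.2)
    contrast_range: tuple[float, float] = (0.8, 1.2)
    apply_probability: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for op in self.operations:
            if op not in KNOWN_OPS:
                raise ValidationError(f"unknown augmentation operation '{op}'")
        for rng_name in ("rotation_degrees", "scale_range",
                         "brightness_range", "contrast_range"):
            lo, hi = getattr(self, rng_name)
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
                raise ValidationError(f"{rng_name} interval invalid: ({lo}, {hi})")
        for op, p in self.apply_probability.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"apply_probability[{op}] = {p} outside [0, 1]")

    def probability(self, op: str) -> float:
        return self.apply_probability.get(op, 0.5)


def _border_median(image: np.ndarray) -> np.ndarray:
    border = np.concatenate([image[0], image[-1], image[:, 0], image[:, -1]])
    return np.median(border, axis=0)


def _rotate(image: np.ndarray, mask: np.ndarray, angle: float):
    """Rotate about the center; exact ``rot90`` for right angles, bilinear
    with background-median fill otherwise; mask always nearest-neighbor."""
    if angle % 90 == 0:
        k = int(angle // 90) % 4
        return np.rot90(image, k, axes=(0, 1)).copy(), np.rot90(mask, k).copy()
    fill = _border_median(image)
    chans = [ndimage.rotate(image[..., c], angle, reshape=False, order=1,
                            cval=float(fill[c]), mode="constant")
             for c in range(3)]
    img = np.clip(np.stack(chans, axis=-1), 0, 1).astype(np.float32)
    m = ndimage.rotate(mask.astype(np.float32), angle, reshape=False, order=0,
                       cval=0.0, mode="constant")
    return img, (m > 0.5).astype(np.uint8)


def _scale(image: np.ndarray, mask: np.ndarray, factor: float):
    """Zoom about the center keeping the canvas size; shrinking pads with
    the border-median color, enlarging center-crops."""
    if factor <= 0:
        raise ValidationError(f"scale factor must be positive, got {factor}")
    h, w = image.shape[:2]
    nh, nw = max(1, int(round(h * factor))), max(1, int(round(w * factor)))
    img = _sk_resize(image, (nh, nw), order=1, anti_aliasing=False,
                     preserve_range=True).astype(np.float32)
    m = (_sk_resize(mask.astype(np.float32), (nh, nw), order=0,
                    preserve_range=True) > 0.5).astype(np.uint8)
    if factor >= 1.0:
        top, left = (nh - h) // 2, (nw - w) // 2
        return img[top:top + h, left:left + w], m[top:top + h, left:left + w]
    fill = _border_median(image)
    out = np.empty_like(image)
    out[:] = fill
    mout = np.zeros_like(mask)
    top, left = (h - nh) // 2, (w - nw) // 2
    out[top:top + nh, left:left + nw] = img
    mout[top:top + nh, left:left + nw] = m
    return out, mout


def grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance replicated across the three channels (keeps model arity)."""
    lum = image @ np.asarray([0.299, 0.587, 0.114], dtype=np.float32)
    return np.repeat(lum[..., None], 3, axis=-1)


def augment(sample: SyntheticSample, plan: AugmentationPlan,
            rng: np.random.Generator | None = None) -> SyntheticSample:
    """Apply the plan's operations in order; returns a new sample.

    Geometric ops co-transform image and mask, photometric ops touch only
    the image, and the label is never changed.  With no explicit ``rng``
    a fresh generator is seeded from ``plan.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(plan.seed)
    img = _check_image(sample.image)
    mask = np.asarray(sample.mask).astype(np.uint8)
    for op in plan.operations:
        if rng.random() >= plan.probability(op):
            continue
        if op == "rotate":
            angle = float(rng.uniform(*plan.rotation_degrees))
            img, mask = _rotate(img, mask, angle)
        elif op == "horizontal_flip":
            img, mask = img[:, ::-1].copy(), mask[:, ::-1].copy()
        elif op == "vertical_flip":
            img, mask = img[::-1].copy(), mask[::-1].copy()
        elif op == "scale":
            img, mask = _scale(img, mask, float(rng.uniform(*plan.scale_range)))
        elif op == "brightness":
            img = img * float(rng.uniform(*plan.brightness_range))
        elif op == "contrast":
            f = float(rng.uniform(*plan.contrast_range))
            img = (img - img.mean()) * f + img.mean()
        elif op == "grayscale":
            img = grayscale(img)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return SyntheticSample(image=img, mask=mask, label=sample.label)


def augment_stream(samples, plan: AugmentationPlan):
    """Deterministic augmented view of a sample sequence (one shared
    generator seeded from the plan)."""
    rng = np.random.default_rng(plan.seed)
    return [augment(s, plan, rng) for s in samples]
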