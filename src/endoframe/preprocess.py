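"""Specular-reflection removal and class-balancing augmentation.

Reflection handling is a three-stage rule: strong pixels (grayscale
strictly above ``STRONG_THRESHOLD``) seed the mask; the mask then grows to
a fixed point over pixels above ``WEAK_THRESHOLD`` that touch it
(8-connectivity); finally the mask is dilated slightly so inpainting does
not sample glare-contaminated boundary pixels.

Augmentation balances class counts: each class C receives
``max(0, floor(1.1 * max_class_count - count(C)))`` generated frames, so
post-augmentation totals differ by at most one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform

from endoframe.frame import Frame, LabeledDataset
from endoframe.inpaint import inpaint

__all__ = [
    "STRONG_THRESHOLD",
    "WEAK_THRESHOLD",
    "AugmentationPlan",
    "to_grayscale",
    "detect_strong",
    "expand_weak",
    "build_mask",
    "remove_reflections",
    "augmentation_quota",
    "apply_manipulation",
    "augment_dataset",
    "MANIPULATIONS",
]

#: Grayscale value above which a pixel is treated as solid reflection.
STRONG_THRESHOLD = 180
#: Grayscale value above which a pixel joins the mask when adjacent to it.
WEAK_THRESHOLD = 130

MANIPULATIONS = ("rotate", "flip", "crop", "resize", "noise")

_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(frame: Frame | np.ndarray) -> np.ndarray:
    """BT.601 luma, rounded half-up, as a HxW uint8 array."""
    px = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    luma = px.astype(np.float64) @ _LUMA
    return np.clip(np.floor(luma + 0.5), 0, 255).astype(np.uint8)


def detect_strong(gray: np.ndarray, threshold: int = STRONG_THRESHOLD) -> np.ndarray:
    """Binary {0,255} mask of pixels with grayscale strictly above threshold."""
    gray = np.asarray(gray)
    return np.where(gray > threshold, 255, 0).astype(np.uint8)


def expand_weak(
    gray: np.ndarray,
    strong: np.ndarray,
    weak_threshold: int = WEAK_THRESHOLD,
) -> np.ndarray:
    """Grow the strong mask to a fixed point over weak pixels.

    A pixel joins the mask when its grayscale exceeds ``weak_threshold``
    and at least one of its 8 neighbours is already masked.  Monotone
    (output is a superset of the input) and idempotent at the fixed point.
    """
    gray = np.asarray(gray)
    strong = np.asarray(strong)
    if gray.shape != strong.shape:
        raise ValueError(f"shape mismatch: gray {gray.shape} vs strong {strong.shape}")
    seed = strong > 0
    if not seed.any():
        return np.zeros_like(gray, dtype=np.uint8)
    candidate = (gray > weak_threshold) | seed
    # fixed point of 8-connected growth constrained to candidate pixels ==
    # connected components of `candidate` that contain a seed
    labels, _ = ndimage.label(candidate, structure=np.ones((3, 3), dtype=int))
    hit = np.unique(labels[seed])
    out = np.isin(labels, hit[hit > 0]) & candidate
    return np.where(out, 255, 0).astype(np.uint8)


def build_mask(
    frame: Frame | np.ndarray,
    dilate_px: int = 1,
    strong_threshold: int = STRONG_THRESHOLD,
    weak_threshold: int = WEAK_THRESHOLD,
) -> np.ndarray:
    """Full reflection mask: strong detection, weak expansion, dilation."""
    if dilate_px < 0:
        raise ValueError("dilate_px must be non-negative")
    gray = to_grayscale(frame)
    mask = expand_weak(gray, detect_strong(gray, strong_threshold), weak_threshold)
    if dilate_px > 0 and mask.any():
        size = 2 * dilate_px + 1
        mask = ndimage.grey_dilation(mask, size=(size, size))
    return mask.astype(np.uint8)


def remove_reflections(
    frame: Frame,
    mask: np.ndarray | None = None,
    method: str = "fmm_telea",
    radius: float = 3.0,
    dilate_px: int = 1,
) -> Frame:
    """Inpaint masked pixels; unmasked pixels are preserved bit-exact."""
    if mask is None:
        mask = build_mask(frame, dilate_px=dilate_px)
    mask = np.asarray(mask)
    if mask.shape != frame.shape:
        raise ValueError("mask shape must match frame shape")
    out = inpaint(frame.pixels, mask, method=method, radius=radius)
    return Frame(out, id=frame.id, label=frame.label, source_id=frame.source_id)


def augmentation_quota(counts: dict[str, int]) -> dict[str, int]:
    """Per-class number of frames to generate so totals come out balanced."""
    if not counts:
        raise ValueError("counts must not be empty")
    if any(c < 1 for c in counts.values()):
        raise ValueError("all class counts must be >= 1")
    biggest = max(counts.values())
    return {
        label: max(0, math.floor(1.1 * biggest - n)) for label, n in counts.items()
    }


@dataclass
class AugmentationPlan:
    """Quota per class, the manipulation palette and the RNG seed."""

    quota: dict[str, int]
    manipulations: tuple[str, ...] = MANIPULATIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.quota.values()):
            raise ValueError("quota values must be non-negative")
        unknown = set(self.manipulations) - set(MANIPULATIONS)
        if unknown:
            raise ValueError(f"unknown manipulations: {sorted(unknown)}")


def _draw_size(rng: np.random.Generator, orig: int) -> int:
    lo, hi = sorted((256, orig))
    return int(rng.integers(lo, hi + 1))


def apply_manipulation(
    frame: Frame, kind: str, rng: np.random.Generator, sigma: float | None = None
) -> Frame:
    """One randomized image manipulation; output stays valid 8-bit RGB.

    ``sigma`` pins the noise standard deviation (drawn from U[2, 10] when
    omitted); zero sigma leaves the frame untouched.
    """
    px = frame.pixels
    h, w = frame.shape
    if kind == "rotate":
        angle = float(rng.uniform(0.0, 360.0))
        out = sktransform.rotate(
            px.astype(np.float64) / 255.0, angle, mode="reflect", order=1
        )
        out = np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)
    elif kind == "flip":
        axis = int(rng.integers(0, 2))
        out = np.flip(px, axis=axis).copy()
    elif kind == "crop":
        th = min(_draw_size(rng, h), h)
        tw = min(_draw_size(rng, w), w)
        y0 = int(rng.integers(0, h - th + 1))
        x0 = int(rng.integers(0, w - tw + 1))
        out = px[y0 : y0 + th, x0 : x0 + tw].copy()
    elif kind == "resize":
        th = _draw_size(rng, h)
        tw = _draw_size(rng, w)
        out = resize_frame(px, (th, tw))
    elif kind == "noise":
        if sigma is None:
            sigma = float(rng.uniform(2.0, 10.0))
        if sigma == 0.0:
            out = px.copy()
        else:
            noise = rng.normal(0.0, sigma, size=px.shape)
            out = np.clip(np.rint(px.astype(np.float64) + noise), 0, 255).astype(np.uint8)
    else:
        raise ValueError(f"unknown manipulation kind: {kind!r}")
    return Frame(out, id=frame.id, label=frame.label, source_id=frame.source_id)


def resize_frame(px: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of an 8-bit raster to (height, width)."""
    if px.shape[:2] == tuple(size):
        return px.copy()
    out = sktransform.resize(
        px.astype(np.float64) / 255.0, size, order=1, anti_aliasing=False
    )
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def augment_dataset(data: LabeledDataset, plan: AugmentationPlan) -> LabeledDataset:
    """Append quota[C] manipulated frames per class C; originals untouched.

    Source frames are chosen round-robin within each class; each generated
    frame is resized back to its source shape so class geometry stays
    uniform, carries a fresh id and records the source frame's id.
    Deterministic for a fixed plan seed.
    """
    by_class: dict[str, list[Frame]] = {}
    for f in data.frames:
        by_class.setdefault(f.label, []).append(f)
    for label in plan.quota:
        if label not in by_class:
            import warnings

            warnings.warn(f"quota for unseen class {label!r} ignored", stacklevel=2)
    out = [f.copy() for f in data.frames]
    rng = np.random.default_rng(plan.seed)
    for label in sorted(by_class):
        quota = plan.quota.get(label)
        if quota is None:
            raise ValueError(f"no quota for class {label!r}")
        sources = by_class[label]
        for k in range(quota):
            src = sources[k % len(sources)]
            kind = plan.manipulations[int(rng.integers(0, len(plan.manipulations)))]
            aug = apply_manipulation(src, kind, rng)
            px = resize_frame(aug.pixels, src.shape)
            out.append(
                Frame(px, id=f"{src.id}_aug{k}", label=label, source_id=src.id)
            )
    return LabeledDataset(out)
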