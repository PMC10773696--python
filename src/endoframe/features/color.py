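"""Colour distribution descriptors: per-channel histograms and the auto
colour correlogram (per-colour probability that a pixel at chessboard
distance k has the same colour)."""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2hsv

__all__ = ["color_histogram", "auto_color_correlogram", "quantize_colors"]


def _as_pixels(frame) -> np.ndarray:
    px = frame.pixels if hasattr(frame, "pixels") else np.asarray(frame)
    return px


def color_histogram(frame, space: str = "RGB", bins_per_channel: int = 64) -> np.ndarray:
    """Concatenated per-channel normalized histograms (each block sums to 1)."""
    if bins_per_channel < 2:
        raise ValueError("bins_per_channel must be >= 2")
    px = _as_pixels(frame)
    if space == "RGB":
        chans = px.astype(np.float64) / 256.0  # in [0, 1)
    elif space == "HSV":
        chans = np.clip(rgb2hsv(px), 0.0, 1.0 - 1e-12)
    else:
        raise ValueError("space must be 'RGB' or 'HSV'")
    blocks = []
    n = px.shape[0] * px.shape[1]
    for c in range(3):
        idx = np.minimum(
            (chans[..., c] * bins_per_channel).astype(int), bins_per_channel - 1
        )
        blocks.append(np.bincount(idx.ravel(), minlength=bins_per_channel) / n)
    return np.concatenate(blocks)


def quantize_colors(px: np.ndarray, levels: int) -> tuple[np.ndarray, int]:
    """Uniform RGB quantization into at least ``levels`` colours.

    Each channel is split into ``ceil(levels ** (1/3))`` equal bins, so the
    actual palette size is the smallest perfect cube >= levels.  Returns
    (index map, palette size).
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    b = int(np.ceil(round(levels ** (1.0 / 3.0), 9)))
    q = np.minimum((px.astype(np.int64) * b) // 256, b - 1)
    idx = (q[..., 0] * b + q[..., 1]) * b + q[..., 2]
    return idx, b**3


def auto_color_correlogram(
    frame, levels: int = 64, distances=(1, 3, 5, 7)
) -> np.ndarray:
    """ACC(c, k) = P(colour(q) == c | colour(p) == c, chessboard d(p,q) == k).

    Pair counting is over ordered pairs with the second pixel inside the
    image; colours never observed yield 0.  Output is laid out colour-major
    per distance: [k0 colours..., k1 colours..., ...].
    """
    px = _as_pixels(frame)
    idx, palette = quantize_colors(px, levels)
    h, w = idx.shape
    out = np.zeros(palette * len(distances))
    for di, k in enumerate(distances):
        same = np.zeros(palette)
        tot = np.zeros(palette)
        # ring of chessboard radius k: max(|dy|, |dx|) == k
        offs = [
            (dy, dx)
            for dy in range(-k, k + 1)
            for dx in range(-k, k + 1)
            if max(abs(dy), abs(dx)) == k
        ]
        for dy, dx in offs:
            y0, y1 = max(0, -dy), min(h, h - dy)
            x0, x1 = max(0, -dx), min(w, w - dx)
            if y0 >= y1 or x0 >= x1:
                continue
            a = idx[y0:y1, x0:x1].ravel()
            b = idx[y0 + dy : y1 + dy, x0 + dx : x1 + dx].ravel()
            np.add.at(tot, a, 1)
            eq = a == b
            np.add.at(same, a[eq], 1)
        nz = tot > 0
        block = np.zeros(palette)
        block[nz] = same[nz] / tot[nz]
        out[di * palette : (di + 1) * palette] = block
    return out
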