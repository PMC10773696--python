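"""Inpainting of masked image regions.

``fmm_telea`` is a fast-marching-method inpainter: pixels are filled in
increasing order of distance from the mask boundary, each as a weighted
average of already-known neighbours inside a circular window, with weights
combining direction (alignment with the marching front normal), geometric
distance and level-set proximity.  ``navier_stokes`` is served by
scikit-image's biharmonic inpainter, a smooth PDE-based fill standing in
for the fluid-dynamics formulation.
"""

from __future__ import annotations

import heapq

import numpy as np
from skimage.restoration import inpaint_biharmonic

__all__ = ["inpaint", "fmm_inpaint"]

_KNOWN, _BAND, _INSIDE = 0, 1, 2
_INF = 1e6


def _solve_eikonal(y: int, x: int, T: np.ndarray, flags: np.ndarray) -> float:
    """One quadratic eikonal update from the known axis-neighbour values."""
    h, w = T.shape
    tx = ty = _INF
    for dy in (-1, 1):
        ny = y + dy
        if 0 <= ny < h and flags[ny, x] != _INSIDE:
            ty = min(ty, T[ny, x])
    for dx in (-1, 1):
        nx = x + dx
        if 0 <= nx < w and flags[y, nx] != _INSIDE:
            tx = min(tx, T[y, nx])
    lo, hi = (tx, ty) if tx < ty else (ty, tx)
    if lo >= _INF:
        return _INF
    if hi - lo >= 1.0:
        return lo + 1.0
    # both neighbours usable: solve (t-lo)^2 + (t-hi)^2 = 1
    s = lo + hi
    d = 2.0 - (hi - lo) ** 2
    return 0.5 * (s + np.sqrt(d))


def fmm_inpaint(image: np.ndarray, mask: np.ndarray, radius: float = 3.0) -> np.ndarray:
    """Telea-style fast-marching inpaint of ``mask`` pixels (per channel).

    ``image`` is HxW or HxWxC uint8; ``mask`` is boolean or {0,255}.
    Unmasked pixels are returned bit-identical.
    """
    mask = np.asarray(mask) > 0
    img = np.asarray(image)
    squeeze = img.ndim == 2
    work = img[..., None].astype(np.float64) if squeeze else img.astype(np.float64)
    h, w = mask.shape

    flags = np.where(mask, _INSIDE, _KNOWN).astype(np.int8)
    T = np.where(mask, _INF, 0.0)

    heap: list[tuple[float, int, int]] = []
    ys, xs = np.nonzero(mask)
    for y, x in zip(ys, xs):
        for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and not mask[ny, nx] and flags[ny, nx] == _KNOWN:
                flags[ny, nx] = _BAND
                heapq.heappush(heap, (0.0, ny, nx))

    r = max(1, int(np.ceil(radius)))
    offs = [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if 0 < dy * dy + dx * dx <= radius * radius
    ]

    def _paint(y: int, x: int) -> None:
        # gradient of T at (y, x) ~ front normal
        gy = (T[min(y + 1, h - 1), x] - T[max(y - 1, 0), x]) * 0.5
        gx = (T[y, min(x + 1, w - 1)] - T[y, max(x - 1, 0)]) * 0.5
        num = np.zeros(work.shape[2])
        den = 0.0
        for dy, dx in offs:
            ny, nx = y + dy, x + dx
            if not (0 <= ny < h and 0 <= nx < w) or flags[ny, nx] == _INSIDE:
                continue
            d2 = dy * dy + dx * dx
            direction = abs(dy * gy + dx * gx) / np.sqrt(d2)
            if direction < 1e-6:
                direction = 1e-6
            dst = 1.0 / d2
            lev = 1.0 / (1.0 + abs(T[ny, nx] - T[y, x]))
            wgt = direction * dst * lev
            num += wgt * work[ny, nx]
            den += wgt
        if den > 0:
            work[y, x] = num / den

    while heap:
        t, y, x = heapq.heappop(heap)
        if flags[y, x] == _KNOWN:
            continue
        flags[y, x] = _KNOWN
        T[y, x] = t
        for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ny, nx = y + dy, x + dx
            if not (0 <= ny < h and 0 <= nx < w) or flags[ny, nx] != _INSIDE:
                continue
            nt = _solve_eikonal(ny, nx, T, flags)
            T[ny, nx] = nt
            _paint(ny, nx)
            flags[ny, nx] = _BAND
            heapq.heappush(heap, (nt, ny, nx))

    out = np.clip(np.rint(work), 0, 255).astype(np.uint8)
    if squeeze:
        out = out[..., 0]
    # bit-exact preservation outside the mask
    out[~mask] = img[~mask]
    return out


def inpaint(image: np.ndarray, mask: np.ndarray, method: str = "fmm_telea",
            radius: float = 3.0) -> np.ndarray:
    """Dispatch to the named inpainting method."""
    mask_b = np.asarray(mask) > 0
    img = np.asarray(image)
    if not mask_b.any():
        return img.copy()
    if method == "fmm_telea":
        return fmm_inpaint(img, mask_b, radius=radius)
    if method == "navier_stokes":
        chan = img.ndim == 3
        filled = inpaint_biharmonic(img, mask_b, channel_axis=2 if chan else None)
        out = np.clip(np.rint(filled * 255.0), 0, 255).astype(np.uint8)
        out[~mask_b] = img[~mask_b]
        return out
    raise ValueError(f"unknown inpainting method: {method!r}")
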