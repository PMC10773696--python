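"""Local binary/ternary patterns and gray-level co-occurrence statistics.

LBP bit convention: 8 samples on a circle of the given radius, starting at
the top-middle neighbour and proceeding clockwise; bit p is set when the
neighbour value is greater than or equal to the centre; the code is
sum(bit_p * 2^p).  Non-integer sample positions are bilinearly
interpolated.  Border pixels within ``radius`` of the edge carry no code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LBPMap",
    "GLCMMatrix",
    "lbp_map",
    "lbp_histogram",
    "ltp_maps",
    "glcm",
    "glcm_all_directions",
    "haralick",
    "HARALICK_NAMES",
]

DIRECTIONS = ("horizontal", "vertical", "diag_up", "diag_down")

HARALICK_NAMES = (
    "eq_sum",  # sum of the normalized matrix (identically 1)
    "angular_second_moment",
    "contrast",
    "correlation",
    "variance",
    "inverse_difference_moment",
    "entropy",
)


@dataclass
class LBPMap:
    codes: np.ndarray  # (H-2r) x (W-2r) ints in [0, 255]
    radius: int


@dataclass
class GLCMMatrix:
    counts: np.ndarray  # levels x levels, symmetric
    levels: int
    distance: int
    direction: str


def _circle_offsets(radius: int) -> np.ndarray:
    """(dy, dx) for 8 neighbours, top-middle first, clockwise.

    Radius 1 uses the 8-connected square ring (exact pixel positions, no
    interpolation); larger radii sample the true circle bilinearly.
    """
    if radius == 1:
        return np.array(
            [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)],
            dtype=float,
        )
    p = np.arange(8)
    theta = 2.0 * np.pi * p / 8.0
    dx = radius * np.sin(theta)
    dy = -radius * np.cos(theta)
    return np.stack([dy, dx], axis=1)


def _sample_bilinear(img: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    fy = ys - y0
    fx = xs - x0
    y1 = np.clip(y0 + 1, 0, img.shape[0] - 1)
    x1 = np.clip(x0 + 1, 0, img.shape[1] - 1)
    y0 = np.clip(y0, 0, img.shape[0] - 1)
    x0 = np.clip(x0, 0, img.shape[1] - 1)
    return (
        img[y0, x0] * (1 - fy) * (1 - fx)
        + img[y0, x1] * (1 - fy) * fx
        + img[y1, x0] * fy * (1 - fx)
        + img[y1, x1] * fy * fx
    )


def _neighbour_stack(gray: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """(8, h', w') neighbour samples and (h', w') centres, borders trimmed."""
    gray = np.asarray(gray, dtype=np.float64)
    h, w = gray.shape
    if h <= 2 * radius or w <= 2 * radius:
        raise ValueError("image too small for the requested radius")
    cy, cx = np.mgrid[radius : h - radius, radius : w - radius]
    centers = gray[radius : h - radius, radius : w - radius]
    offs = _circle_offsets(radius)
    neigh = np.empty((8,) + centers.shape)
    for p in range(8):
        dy, dx = offs[p]
        # snap near-integer offsets so axis-aligned samples hit exact pixels
        if abs(dy - round(dy)) < 1e-9:
            dy = round(dy)
        if abs(dx - round(dx)) < 1e-9:
            dx = round(dx)
        neigh[p] = _sample_bilinear(gray, (cy + dy).astype(float), (cx + dx).astype(float))
    return neigh, centers


def lbp_map(gray: np.ndarray, radius: int) -> LBPMap:
    """Local binary pattern codes; bit set when neighbour >= centre."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    neigh, centers = _neighbour_stack(gray, radius)
    bits = (neigh >= centers[None, :, :] - 1e-9).astype(np.int64)
    weights = (2 ** np.arange(8))[:, None, None]
    codes = (bits * weights).sum(axis=0)
    return LBPMap(codes=codes, radius=radius)


def ltp_maps(gray: np.ndarray, radius: int) -> tuple[LBPMap, LBPMap]:
    """Local ternary patterns split into the upper/lower binary maps.

    Upper bit: neighbour strictly greater than the centre; lower bit:
    strictly smaller; ties contribute to neither map.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    neigh, centers = _neighbour_stack(gray, radius)
    upper_bits = (neigh > centers[None, :, :] + 1e-9).astype(np.int64)
    lower_bits = (neigh < centers[None, :, :] - 1e-9).astype(np.int64)
    weights = (2 ** np.arange(8))[:, None, None]
    upper = (upper_bits * weights).sum(axis=0)
    lower = (lower_bits * weights).sum(axis=0)
    return LBPMap(upper, radius), LBPMap(lower, radius)


def _code_histogram(codes: np.ndarray) -> np.ndarray:
    hist = np.bincount(codes.ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    return hist / total if total > 0 else hist


def lbp_histogram(gray: np.ndarray, radii=(1, 2, 3, 4, 5)) -> np.ndarray:
    """Concatenated 256-bin normalized code histograms, one per radius."""
    if not radii:
        raise ValueError("radii must be non-empty")
    return np.concatenate([_code_histogram(lbp_map(gray, r).codes) for r in radii])


def ltp_histogram(gray: np.ndarray, radii=(1, 2, 3)) -> np.ndarray:
    """Upper+lower LTP histograms per radius (512 bins per radius)."""
    blocks = []
    for r in radii:
        up, lo = ltp_maps(gray, r)
        blocks.append(_code_histogram(up.codes))
        blocks.append(_code_histogram(lo.codes))
    return np.concatenate(blocks)


_OFFSETS = {
    "horizontal": (0, 1),
    "vertical": (1, 0),
    "diag_up": (-1, 1),
    "diag_down": (1, 1),
}


def quantize(gray: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width quantization of 8-bit values to ``levels`` bins."""
    return np.minimum(
        (np.asarray(gray).astype(np.int64) * levels) // 256, levels - 1
    )


def glcm(gray: np.ndarray, levels: int = 8, distance: int = 1,
         direction: str = "horizontal") -> GLCMMatrix:
    """Symmetric co-occurrence counts of quantized intensity pairs."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if direction not in _OFFSETS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    q = quantize(gray, levels)
    dy, dx = _OFFSETS[direction]
    dy, dx = dy * distance, dx * distance
    h, w = q.shape
    counts = np.zeros((levels, levels), dtype=np.int64)
    y0, y1 = max(0, -dy), min(h, h - dy)
    x0, x1 = max(0, -dx), min(w, w - dx)
    if y0 >= y1 or x0 >= x1:
        warnings.warn("distance exceeds image extent; empty GLCM", stacklevel=2)
        return GLCMMatrix(counts, levels, distance, direction)
    a = q[y0:y1, x0:x1].ravel()
    b = q[y0 + dy : y1 + dy, x0 + dx : x1 + dx].ravel()
    np.add.at(counts, (a, b), 1)
    counts = counts + counts.T  # count both pair orders
    return GLCMMatrix(counts, levels, distance, direction)


def glcm_all_directions(gray: np.ndarray, levels: int = 8, distance: int = 1):
    return [glcm(gray, levels, distance, d) for d in DIRECTIONS]


def haralick(m: GLCMMatrix) -> np.ndarray:
    """Summary statistics of one normalized co-occurrence matrix.

    Returns, in order: the normalization sum (identically 1), angular
    second moment, contrast, correlation, variance, inverse difference
    moment and entropy.
    """
    total = m.counts.sum()
    if total == 0:
        raise ValueError("cannot compute statistics of a zero-count matrix")
    p = m.counts.astype(np.float64) / total
    i = np.arange(m.levels, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    mu_i = (ii * p).sum()
    mu_j = (jj * p).sum()
    var_i = (((ii - mu_i) ** 2) * p).sum()
    var_j = (((jj - mu_j) ** 2) * p).sum()
    asm = (p**2).sum()
    contrast = (((ii - jj) ** 2) * p).sum()
    if var_i > 0 and var_j > 0:
        correlation = (((ii - mu_i) * (jj - mu_j)) * p).sum() / np.sqrt(var_i * var_j)
    else:
        correlation = 0.0
    idm = (p / (1.0 + (ii - jj) ** 2)).sum()
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return np.array([p.sum(), asm, contrast, correlation, var_i, idm, entropy])


def haralick_vector(gray: np.ndarray, levels: int = 8, distance: int = 1) -> np.ndarray:
    """Statistics averaged over the four directions (length 7)."""
    mats = glcm_all_directions(gray, levels, distance)
    return np.mean([haralick(m) for m in mats], axis=0)


def glcm_vector(gray: np.ndarray, levels: int = 8, distance: int = 1) -> np.ndarray:
    """Flattened direction-averaged normalized GLCM (length levels**2)."""
    mats = glcm_all_directions(gray, levels, distance)
    out = np.zeros((levels, levels))
    for m in mats:
        total = m.counts.sum()
        if total > 0:
            out += m.counts / total
    return (out / len(mats)).ravel()
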