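"""Compact global image descriptors in the style of the classic image
retrieval literature: MPEG-7 colour layout and edge histogram, Tamura's six
texture statistics, CEDD/FCTH/JCD colour-texture histograms, Gabor
filter-bank energies and PHOG pyramid gradient histograms.

The reference implementations of several of these exist only in Java;
the versions here follow each descriptor's published structure (grid
layout, bin semantics, dimensionality) with simplified fuzzy-membership
rules, and their dimensionalities are frozen regression constants:

========================  ====
color_layout                12
edge_histogram              80
tamura                       6
cedd                       144
fcth                       192
jcd                        168
gabor                       48
phog                       168
========================  ====
"""

from __future__ import annotations

import numpy as np
from scipy.fft import dctn
from scipy.signal import fftconvolve
from skimage.color import rgb2hsv
from skimage.filters import gabor_kernel

__all__ = ["lire_descriptor", "LIRE_DIMS"]

LIRE_DIMS = {
    "color_layout": 12,
    "edge_histogram": 80,
    "tamura": 6,
    "cedd": 144,
    "fcth": 192,
    "jcd": 168,
    "gabor": 48,
    "phog": 168,
}


def _pixels(frame) -> np.ndarray:
    return frame.pixels if hasattr(frame, "pixels") else np.asarray(frame)


def _gray(px: np.ndarray) -> np.ndarray:
    return px.astype(np.float64) @ np.array([0.299, 0.587, 0.114])


def _block_mean(px: np.ndarray, grid: tuple[int, int]) -> np.ndarray:
    """Average-pool an image onto a (gh, gw) grid (last cells absorb the
    remainder)."""
    h, w = px.shape[:2]
    gh, gw = grid
    ys = np.linspace(0, h, gh + 1).astype(int)
    xs = np.linspace(0, w, gw + 1).astype(int)
    out_shape = (gh, gw) + px.shape[2:]
    out = np.zeros(out_shape)
    for i in range(gh):
        for j in range(gw):
            cell = px[ys[i] : max(ys[i + 1], ys[i] + 1), xs[j] : max(xs[j + 1], xs[j] + 1)]
            out[i, j] = cell.mean(axis=(0, 1))
    return out


# ---------------------------------------------------------------- colour layout

_ZIGZAG8 = sorted(
    ((i, j) for i in range(8) for j in range(8)),
    key=lambda ij: (ij[0] + ij[1], ij[1] if (ij[0] + ij[1]) % 2 else ij[0]),
)


def _color_layout(px: np.ndarray) -> np.ndarray:
    """8x8 block means -> YCbCr -> 2D DCT -> zigzag; 6 Y + 3 Cb + 3 Cr."""
    small = _block_mean(px.astype(np.float64), (8, 8))
    r, g, b = small[..., 0], small[..., 1], small[..., 2]
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cb = -0.168736 * r - 0.331264 * g + 0.5 * b + 128.0
    cr = 0.5 * r - 0.418688 * g - 0.081312 * b + 128.0
    coeffs = []
    for chan, keep in ((y, 6), (cb, 3), (cr, 3)):
        d = dctn(chan, norm="ortho")
        zz = np.array([d[i, j] for i, j in _ZIGZAG8])
        coeffs.append(zz[:keep])
    return np.concatenate(coeffs)


# ---------------------------------------------------------------- edge histogram

# 2x2 sub-block filter coefficients: vertical, horizontal, 45, 135, non-directional
_EDGE_FILTERS = np.array(
    [
        [1.0, -1.0, 1.0, -1.0],
        [1.0, 1.0, -1.0, -1.0],
        [np.sqrt(2.0), 0.0, 0.0, -np.sqrt(2.0)],
        [0.0, np.sqrt(2.0), -np.sqrt(2.0), 0.0],
        [2.0, -2.0, -2.0, 2.0],
    ]
)
_EDGE_THRESHOLD = 11.0


def _edge_type(block: np.ndarray) -> int:
    """-1 = no edge, else index of the dominant 2x2 filter response."""
    sub = _block_mean(block, (2, 2)).ravel()  # a b / c d
    resp = np.abs(_EDGE_FILTERS @ sub)
    k = int(np.argmax(resp))
    return k if resp[k] > _EDGE_THRESHOLD else -1


def _edge_histogram(px: np.ndarray) -> np.ndarray:
    """MPEG-7 style: 4x4 subimages x 5 edge types, each subimage tiled into
    4x4 macro-blocks; 80 bins, normalized per subimage."""
    gray = _gray(px)
    h, w = gray.shape
    out = np.zeros(80)
    ys = np.linspace(0, h, 5).astype(int)
    xs = np.linspace(0, w, 5).astype(int)
    for si in range(4):
        for sj in range(4):
            sub = gray[ys[si] : ys[si + 1], xs[sj] : xs[sj + 1]]
            bys = np.linspace(0, sub.shape[0], 5).astype(int)
            bxs = np.linspace(0, sub.shape[1], 5).astype(int)
            n_blocks = 0
            counts = np.zeros(5)
            for bi in range(4):
                for bj in range(4):
                    blk = sub[bys[bi] : bys[bi + 1], bxs[bj] : bxs[bj + 1]]
                    if blk.size < 4:
                        continue
                    n_blocks += 1
                    t = _edge_type(blk)
                    if t >= 0:
                        counts[t] += 1
            if n_blocks:
                counts /= n_blocks
            out[(si * 4 + sj) * 5 : (si * 4 + sj) * 5 + 5] = counts
    return out


# ---------------------------------------------------------------- tamura

def _integral(img: np.ndarray) -> np.ndarray:
    return np.pad(img, ((1, 0), (1, 0))).cumsum(0).cumsum(1)


def _window_mean(ii: np.ndarray, y: np.ndarray, x: np.ndarray, k: int) -> np.ndarray:
    """Mean over the 2^k x 2^k window centred near each (y, x)."""
    half = 2 ** (k - 1)
    h, w = ii.shape[0] - 1, ii.shape[1] - 1
    y0 = np.clip(y - half, 0, h)
    y1 = np.clip(y + half, 0, h)
    x0 = np.clip(x - half, 0, w)
    x1 = np.clip(x + half, 0, w)
    area = (y1 - y0) * (x1 - x0)
    s = ii[y1, x1] - ii[y0, x1] - ii[y1, x0] + ii[y0, x0]
    return s / np.maximum(area, 1)


def _tamura_coarseness(gray: np.ndarray) -> float:
    h, w = gray.shape
    kmax = max(1, min(5, int(np.log2(min(h, w))) - 1))
    ii = _integral(gray)
    yy, xx = np.mgrid[0:h, 0:w]
    best_e = np.full((h, w), -1.0)
    best_k = np.ones((h, w))
    for k in range(1, kmax + 1):
        step = 2 ** (k - 1)
        eh = np.abs(
            _window_mean(ii, yy, np.clip(xx + step, 0, w), k)
            - _window_mean(ii, yy, np.clip(xx - step, 0, w), k)
        )
        ev = np.abs(
            _window_mean(ii, np.clip(yy + step, 0, h), xx, k)
            - _window_mean(ii, np.clip(yy - step, 0, h), xx, k)
        )
        e = np.maximum(eh, ev)
        upd = e > best_e
        best_e[upd] = e[upd]
        best_k[upd] = k
    return float((2.0**best_k).mean() / 2.0**kmax)  # normalized to (0, 1]


def _tamura_contrast(gray: np.ndarray) -> float:
    sigma = gray.std()
    if sigma == 0:
        return 0.0
    mu4 = ((gray - gray.mean()) ** 4).mean()
    kurt = mu4 / sigma**4
    return float(sigma / kurt**0.25 / 128.0)


def _gradients(gray: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gy, gx = np.gradient(gray)
    mag = np.hypot(gx, gy)
    theta = np.mod(np.arctan2(gy, gx), np.pi)  # orientation in [0, pi)
    return mag, theta


def _tamura_directionality(gray: np.ndarray) -> float:
    mag, theta = _gradients(gray)
    strong = mag > 12.0
    if strong.sum() < 8:
        return 0.0
    # mean resultant length of doubled angles: 1 for a single direction
    z = np.exp(2j * theta[strong])
    return float(np.abs(z.mean()))


def _tamura_linelikeness(gray: np.ndarray, d: int = 4) -> float:
    mag, theta = _gradients(gray)
    strong = mag > 12.0
    h, w = gray.shape
    ys, xs = np.nonzero(strong)
    if ys.size == 0:
        return 0.0
    ny = np.clip(ys + np.rint(d * np.sin(theta[ys, xs])).astype(int), 0, h - 1)
    nx = np.clip(xs + np.rint(d * np.cos(theta[ys, xs])).astype(int), 0, w - 1)
    co = np.cos(2.0 * (theta[ys, xs] - theta[ny, nx]))
    return float((co.mean() + 1.0) / 2.0)


def _tamura(px: np.ndarray) -> np.ndarray:
    gray = _gray(px)
    h, w = gray.shape
    crs = _tamura_coarseness(gray)
    con = _tamura_contrast(gray)
    dirn = _tamura_directionality(gray)
    lin = _tamura_linelikeness(gray)
    # regularity: 1 - spread of the first three statistics over quadrants
    parts = []
    for qy in (slice(0, h // 2), slice(h // 2, h)):
        for qx in (slice(0, w // 2), slice(w // 2, w)):
            q = gray[qy, qx]
            parts.append(
                (
                    _tamura_coarseness(q),
                    _tamura_contrast(q),
                    _tamura_directionality(q),
                )
            )
    spread = np.asarray(parts).std(axis=0).sum()
    reg = float(np.clip(1.0 - spread, 0.0, 1.0))
    rough = crs + con
    return np.array([crs, con, dirn, lin, reg, rough])


# ---------------------------------------------------------------- cedd / fcth / jcd

def _fuzzy24(hsv: np.ndarray) -> int:
    """24-colour palette: 3 achromatic + 7 hues x 3 brightness zones."""
    hue, s, v = hsv
    if s < 0.12:
        if v < 0.28:
            return 0  # black
        return 1 if v < 0.78 else 2  # gray / white
    hue_deg = hue * 360.0
    bounds = (20.0, 50.0, 80.0, 160.0, 260.0, 310.0, 340.0)  # r o y g b m r
    hb = 0
    for k, b in enumerate(bounds):
        if hue_deg < b:
            hb = k
            break
    else:
        hb = 0  # wraps back to red
    vz = 0 if v < 0.4 else (1 if v < 0.75 else 2)
    return 3 + hb * 3 + vz


def _block_grid(px: np.ndarray, target: int = 24) -> tuple[np.ndarray, np.ndarray]:
    """(grid of mean-RGB blocks, grid of block arrays flattened index)."""
    h, w = px.shape[:2]
    g = min(target, h // 2, w // 2)
    g = max(g, 1)
    return np.linspace(0, h, g + 1).astype(int), np.linspace(0, w, g + 1).astype(int)


def _cedd(px: np.ndarray) -> np.ndarray:
    """6 texture classes (non-edge + 5 MPEG-7 edge types) x 24 colours."""
    gray = _gray(px)
    hsv = rgb2hsv(px)
    ys, xs = _block_grid(px)
    hist = np.zeros(144)
    for i in range(len(ys) - 1):
        for j in range(len(xs) - 1):
            blk = gray[ys[i] : ys[i + 1], xs[j] : xs[j + 1]]
            if blk.size < 4:
                continue
            t = _edge_type(blk) + 1  # 0 = non-edge
            mean_hsv = hsv[ys[i] : ys[i + 1], xs[j] : xs[j + 1]].mean(axis=(0, 1))
            c = _fuzzy24(mean_hsv)
            hist[t * 24 + c] += 1.0
    s = hist.sum()
    return hist / s if s else hist


def _fcth(px: np.ndarray) -> np.ndarray:
    """8 texture classes (thresholded Haar band energies) x 24 colours."""
    gray = _gray(px)
    hsv = rgb2hsv(px)
    ys, xs = _block_grid(px)
    hist = np.zeros(192)
    for i in range(len(ys) - 1):
        for j in range(len(xs) - 1):
            blk = gray[ys[i] : ys[i + 1], xs[j] : xs[j + 1]]
            if blk.size < 4:
                continue
            q = _block_mean(blk, (2, 2)).ravel()  # a b / c d
            lh = abs(q[0] + q[1] - q[2] - q[3]) / 2.0
            hl = abs(q[0] - q[1] + q[2] - q[3]) / 2.0
            hh = abs(q[0] - q[1] - q[2] + q[3]) / 2.0
            t = (int(lh > 7.0) << 2) | (int(hl > 7.0) << 1) | int(hh > 7.0)
            mean_hsv = hsv[ys[i] : ys[i + 1], xs[j] : xs[j + 1]].mean(axis=(0, 1))
            c = _fuzzy24(mean_hsv)
            hist[t * 24 + c] += 1.0
    s = hist.sum()
    return hist / s if s else hist


def _jcd(px: np.ndarray) -> np.ndarray:
    """Joint compaction of CEDD and FCTH onto 7 texture areas x 24 colours."""
    cedd = _cedd(px).reshape(6, 24)
    fcth = _fcth(px).reshape(8, 24)
    joint = np.zeros((7, 24))
    joint[:6] = cedd
    joint[6] = fcth[1:].sum(axis=0)  # energy-bearing FCTH rows
    joint[0] = (cedd[0] + fcth[0]) / 2.0  # both descriptors' smooth area
    s = joint.sum()
    return (joint / s if s else joint).ravel()


# ---------------------------------------------------------------- gabor

_GABOR_FREQS = (0.1, 0.2, 0.3, 0.4)
_GABOR_THETAS = tuple(np.pi * k / 6 for k in range(6))


def _gabor(px: np.ndarray) -> np.ndarray:
    gray = _gray(px) / 255.0
    gray = gray - gray.mean()
    feats = []
    for f in _GABOR_FREQS:
        for th in _GABOR_THETAS:
            kern = gabor_kernel(frequency=f, theta=th)
            resp = fftconvolve(gray, np.real(kern), mode="valid")
            resp_i = fftconvolve(gray, np.imag(kern), mode="valid")
            mag = np.hypot(resp, resp_i) if resp.size else np.zeros(1)
            feats.extend([mag.mean(), mag.std()])
    return np.asarray(feats)


# ---------------------------------------------------------------- phog

def _phog(px: np.ndarray, bins: int = 8, levels: int = 2) -> np.ndarray:
    gray = _gray(px)
    mag, theta = _gradients(gray)
    bin_idx = np.minimum((theta / np.pi * bins).astype(int), bins - 1)
    h, w = gray.shape
    out = []
    for lv in range(levels + 1):
        g = 2**lv
        ys = np.linspace(0, h, g + 1).astype(int)
        xs = np.linspace(0, w, g + 1).astype(int)
        level_block = np.zeros(g * g * bins)
        for i in range(g):
            for j in range(g):
                m = mag[ys[i] : ys[i + 1], xs[j] : xs[j + 1]].ravel()
                b = bin_idx[ys[i] : ys[i + 1], xs[j] : xs[j + 1]].ravel()
                cell = np.bincount(b, weights=m, minlength=bins)
                level_block[(i * g + j) * bins : (i * g + j + 1) * bins] = cell
        s = level_block.sum()
        out.append(level_block / s if s else level_block)
    return np.concatenate(out)


_DISPATCH = {
    "color_layout": _color_layout,
    "edge_histogram": _edge_histogram,
    "tamura": _tamura,
    "cedd": _cedd,
    "fcth": _fcth,
    "jcd": _jcd,
    "gabor": _gabor,
    "phog": _phog,
}


def lire_descriptor(frame, name: str) -> np.ndarray:
    """Compute the named descriptor; dimensionality per ``LIRE_DIMS``."""
    if name not in _DISPATCH:
        raise ValueError(f"unknown descriptor {name!r}; choose from {sorted(_DISPATCH)}")
    vec = np.asarray(_DISPATCH[name](_pixels(frame)), dtype=np.float64)
    expected = LIRE_DIMS[name]
    if vec.shape != (expected,):
        raise AssertionError(f"{name}: expected dim {expected}, got {vec.shape}")
    return vec
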