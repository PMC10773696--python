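"""Synthetic data generators used for offline verification.

Everything other modules consume can be generated here: endoscopy-like
frames with class-conditional colour/texture signatures, injected specular
highlights with ground-truth masks, imbalanced labelled datasets, and
probability matrices with planted per-class decision thresholds together
with an exhaustive grid-search threshold oracle.

Generated frames keep their grayscale at or below ``LUMA_HEADROOM`` so the
only pixels exceeding the strong-reflection threshold are the injected
highlight cores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from endoframe.frame import Frame, LabeledDataset
from endoframe.gaboost import decide_batch
from endoframe.metrics import confusion, f1_macro
from endoframe.preprocess import to_grayscale

__all__ = [
    "LUMA_HEADROOM",
    "ClassSpec",
    "ImbalanceSpec",
    "SyntheticProbSpec",
    "make_frame",
    "inject_reflections",
    "make_dataset",
    "make_probability_matrix",
    "grid_search_thresholds",
    "save_probability_matrix",
    "load_probability_matrix",
    "default_class_specs",
]

#: Upper bound on generated-frame grayscale before reflections are injected.
LUMA_HEADROOM = 170

_TEXTURES = ("smooth", "speckle", "striped")


@dataclass(frozen=True)
class ClassSpec:
    """Appearance signature of one synthetic class."""

    name: str
    base_color: tuple[int, int, int]
    texture: str = "smooth"
    texture_scale: int = 4

    def __post_init__(self) -> None:
        if not all(0 <= c <= 255 for c in self.base_color):
            raise ValueError("base_color channels must lie in [0, 255]")
        if self.texture not in _TEXTURES:
            raise ValueError(f"texture must be one of {_TEXTURES}")
        if self.texture_scale < 1:
            raise ValueError("texture_scale must be >= 1")


@dataclass(frozen=True)
class ImbalanceSpec:
    """Per-class frame counts, typically severely skewed."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        if len(self.counts) < 2:
            raise ValueError("need at least 2 classes")
        if any(n < 1 for n in self.counts.values()):
            raise ValueError("all counts must be >= 1")


@dataclass(frozen=True)
class SyntheticProbSpec:
    """Recipe for a probability matrix with planted per-class thresholds."""

    n_per_class: int
    separation: tuple[float, ...]
    planted_thresholds: tuple[float, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be positive")
        if len(self.separation) != len(self.planted_thresholds):
            raise ValueError("separation and planted_thresholds lengths differ")
        if any(s <= 0 for s in self.separation):
            raise ValueError("separation must be positive")
        if any(not (0.0 < t < 1.0) for t in self.planted_thresholds):
            raise ValueError("planted thresholds must lie strictly inside (0, 1)")


def _texture_field(
    texture: str, scale: int, h: int, w: int, rng: np.random.Generator
) -> np.ndarray:
    """Multiplicative modulation field in [0.55, 1.0]."""
    if texture == "smooth":
        return np.ones((h, w))
    if texture == "speckle":
        coarse = rng.uniform(0.0, 1.0, size=(max(1, h // scale), max(1, w // scale)))
        field_ = np.kron(coarse, np.ones((scale, scale)))[:h, :w]
        if field_.shape != (h, w):  # pad ragged edge by repeating last row/col
            field_ = np.pad(
                field_,
                ((0, h - field_.shape[0]), (0, w - field_.shape[1])),
                mode="edge",
            )
        return 0.55 + 0.45 * field_
    # striped
    phase = rng.uniform(0.0, 2.0 * np.pi)
    xs = np.arange(w)[None, :] + np.arange(h)[:, None] * 0.35
    wave = 0.5 * (1.0 + np.sin(2.0 * np.pi * xs / (2.0 * scale) + phase))
    return 0.55 + 0.45 * wave


def make_frame(spec: ClassSpec, height: int, width: int, seed: int) -> Frame:
    """One synthetic frame; deterministic per seed; luma capped at 170."""
    if height < 32 or width < 32:
        raise ValueError("frame size must be at least 32x32")
    rng = np.random.default_rng(seed)
    base = np.array(spec.base_color, dtype=np.float64)
    field_ = _texture_field(spec.texture, spec.texture_scale, height, width, rng)
    px = base[None, None, :] * field_[..., None]
    px += rng.normal(0.0, 3.0, size=px.shape)
    px = np.clip(px, 0.0, 255.0)
    # rescale any pixel whose luma would breach the headroom (169 before
    # rounding keeps the rounded BT.601 luma <= 170)
    luma = px @ np.array([0.299, 0.587, 0.114])
    hot = luma > 169.0
    if hot.any():
        px[hot] *= (169.0 / luma[hot])[:, None]
    frame = Frame(np.rint(px).astype(np.uint8), id=f"{spec.name}_{seed}", label=spec.name)
    assert int(to_grayscale(frame).max()) <= LUMA_HEADROOM
    return frame


def inject_reflections(
    frame: Frame, n_spots: int, seed: int
) -> tuple[Frame, np.ndarray]:
    """Paint ``n_spots`` elliptical specular highlights; return ground truth.

    Each spot is a bright core (grayscale strictly above 180) surrounded by
    a halo ring with grayscale inside (130, 180].  The returned {0,255}
    mask covers core plus halo; pixels outside it are unchanged.
    """
    if n_spots < 0:
        raise ValueError("n_spots must be non-negative")
    h, w = frame.shape
    px = frame.pixels.copy()
    mask = np.zeros((h, w), dtype=np.uint8)
    if n_spots == 0:
        return Frame(px, id=frame.id, label=frame.label, source_id=frame.source_id), mask
    rng = np.random.default_rng(seed)
    occupied = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    placed = 0
    attempts = 0
    while placed < n_spots:
        attempts += 1
        if attempts > 500 * n_spots:
            raise RuntimeError("could not place non-overlapping reflection spots")
        a = float(rng.uniform(2.0, 4.0))  # core semi-axes
        b = float(rng.uniform(2.0, 4.0))
        halo = float(rng.uniform(2.0, 3.0))
        margin = int(np.ceil(max(a, b) + halo)) + 2
        if 2 * margin >= min(h, w):
            raise ValueError("frame too small for reflection spots")
        cy = int(rng.integers(margin, h - margin))
        cx = int(rng.integers(margin, w - margin))
        r2 = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2
        core = r2 <= 1.0
        ring = (r2 > 1.0) & (((yy - cy) / (a + halo)) ** 2 + ((xx - cx) / (b + halo)) ** 2 <= 1.0)
        spot = core | ring
        # keep spots separated so mask components stay distinct
        grown = np.zeros_like(spot)
        ys, xs = np.nonzero(spot)
        y0, y1 = max(ys.min() - 2, 0), min(ys.max() + 3, h)
        x0, x1 = max(xs.min() - 2, 0), min(xs.max() + 3, w)
        grown[y0:y1, x0:x1] = True
        if (grown & occupied).any():
            continue
        core_val = rng.integers(215, 246)
        halo_val = rng.integers(145, 171)
        px[core] = core_val  # equal channels -> grayscale == channel value
        px[ring] = halo_val
        mask[spot] = 255
        occupied |= grown
        placed += 1
    out = Frame(px, id=frame.id, label=frame.label, source_id=frame.source_id)
    gray = to_grayscale(out)
    assert (gray[mask > 0] > 130).all()
    return out, mask


def default_class_specs(n_classes: int = 4) -> list[ClassSpec]:
    """Well-separated dark-ish class signatures (luma stays below the weak
    reflection band so mask expansion halts at spot halos)."""
    palette = [
        ClassSpec("mucosa_red", (130, 35, 40), "smooth", 4),
        ClassSpec("polyp_pink", (120, 75, 90), "speckle", 6),
        ClassSpec("vein_blue", (40, 55, 120), "striped", 8),
        ClassSpec("bile_green", (60, 110, 45), "speckle", 3),
        ClassSpec("dark_lumen", (35, 25, 30), "smooth", 4),
        ClassSpec("stool_brown", (110, 80, 30), "striped", 5),
    ]
    if n_classes > len(palette):
        raise ValueError(f"at most {len(palette)} default classes available")
    return palette[:n_classes]


def make_dataset(
    specs: list[ClassSpec],
    imbalance: ImbalanceSpec,
    seed: int,
    height: int = 64,
    width: int = 64,
    n_reflections: int = 0,
) -> LabeledDataset:
    """Labelled dataset with exactly the requested per-class counts.

    With ``n_reflections > 0`` every frame receives that many injected
    highlights (ground truth masks are not retained here; regenerate via
    :func:`inject_reflections` if needed).
    """
    by_name = {s.name: s for s in specs}
    missing = set(imbalance.counts) - set(by_name)
    if missing:
        raise ValueError(f"no ClassSpec for labels: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    frames = []
    for label in sorted(imbalance.counts):
        spec = by_name[label]
        for i in range(imbalance.counts[label]):
            fseed = int(rng.integers(0, 2**31 - 1))
            f = make_frame(spec, height, width, fseed)
            f.id = f"{label}_{i:05d}"
            if n_reflections > 0:
                f, _ = inject_reflections(f, n_reflections, fseed + 1)
            frames.append(f)
    return LabeledDataset(frames)


def make_probability_matrix(
    spec: SyntheticProbSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scores concentrating just above (true class) / below (off class) the
    planted per-class thresholds; returns (probs, labels, oracle_thresholds).

    Larger ``separation`` pulls scores tighter against the threshold from
    both sides, so the macro-F1-optimal thresholds approach the planted
    ones.  The oracle is an exhaustive coordinate-wise grid search.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.planted_thresholds)
    n = spec.n_per_class * k
    t = np.asarray(spec.planted_thresholds)
    sep = np.asarray(spec.separation)
    labels = np.repeat(np.arange(k), spec.n_per_class)
    probs = np.empty((n, k))
    for c in range(k):
        own = labels == c
        # Beta(1, sep) concentrates near 0 as sep grows
        above = rng.beta(1.0, sep[c], size=own.sum())
        below = rng.beta(1.0, sep[c], size=n - own.sum())
        probs[own, c] = t[c] + (1.0 - t[c]) * above
        probs[~own, c] = t[c] * (1.0 - below)
    probs = np.clip(probs, 1e-9, 1.0 - 1e-9)
    # The margin decision rule is invariant to shifting every threshold
    # down by the same amount, so planted thresholds are only identifiable
    # under the raw qualifying rule; the low tie-break hugs the planted
    # values, which are themselves margin-rule optimal.
    # starting high decouples the coordinates: with every other threshold
    # raised, each class's own threshold window is individually identifiable
    oracle = grid_search_thresholds(probs, labels, rule="raw", tie="center", init=0.99)
    return probs, labels, oracle


def save_probability_matrix(probs, labels, class_names, probs_path, labels_path):
    """CSV pair: header = class names, one row per sample; parallel labels."""
    import pandas as pd

    pd.DataFrame(np.asarray(probs), columns=list(class_names)).to_csv(
        probs_path, index=False
    )
    names = np.asarray(class_names)[np.asarray(labels, dtype=int)]
    pd.DataFrame({"label": names}).to_csv(labels_path, index=False)


def load_probability_matrix(probs_path, labels_path):
    """Inverse of :func:`save_probability_matrix`; returns (probs, labels,
    class_names) with labels as integer indices into class_names."""
    import pandas as pd

    probs_df = pd.read_csv(probs_path)
    class_names = list(probs_df.columns)
    col = pd.read_csv(labels_path)["label"]
    labels = np.array([class_names.index(str(v)) for v in col])
    return probs_df.to_numpy(float), labels, class_names


def grid_search_thresholds(
    probs: np.ndarray,
    labels: np.ndarray,
    grid: np.ndarray | None = None,
    sweeps: int = 5,
    rule: str = "margin",
    tie: str = "high",
    init: float = 0.5,
) -> np.ndarray:
    """Coordinate-wise exhaustive search over a threshold grid, maximizing
    macro F1 under the chosen decision rule.  Independent of the GA.

    ``tie`` picks among equal maxima: the lowest grid value, the highest,
    or the one closest to 0.5 ("center", the least extreme threshold).
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0, 0.01), 2)
    if tie not in ("low", "high", "center"):
        raise ValueError("tie must be 'low', 'high' or 'center'")
    k = probs.shape[1]
    t = np.full(k, init)

    def score(tv: np.ndarray) -> float:
        preds = decide_batch(probs, tv, rule=rule)
        return f1_macro(confusion(labels, preds, k))

    def prefer(v: float, incumbent: float) -> bool:
        if tie == "high":
            return v > incumbent
        if tie == "center":
            return abs(v - 0.5) < abs(incumbent - 0.5)
        return False  # "low": ascending scan keeps the first maximum

    for _ in range(sweeps):
        changed = False
        for c in range(k):
            orig = t[c]
            best_v, best_s = None, -1.0
            for v in grid:  # ascending scan
                t[c] = v
                s = score(t)
                if s > best_s + 1e-12:
                    best_v, best_s = v, s
                elif abs(s - best_s) <= 1e-12 and prefer(v, best_v):
                    best_v = v
            t[c] = best_v
            changed = changed or best_v != orig
        if not changed:
            break
    return t
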