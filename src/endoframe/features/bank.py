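"""Descriptor registry and fused-vector extraction.

Descriptors are concatenated in alphabetical order of their registry names
so the per-descriptor spans are reproducible; ``extract_bank`` returns the
fused vector together with a name -> (start, stop) span table that feature
selection slices by name.

Screening on held-out accuracy classifies the bank into a selected set
(used by default) and a misleading set (implemented for ablations but
excluded from the default configuration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from endoframe.features.color import auto_color_correlogram, color_histogram
from endoframe.features.lire import LIRE_DIMS, lire_descriptor
from endoframe.features.texture import (
    glcm_vector,
    haralick_vector,
    lbp_histogram,
    ltp_histogram,
)
from endoframe.preprocess import to_grayscale

__all__ = [
    "FeatureVector",
    "ALL_DESCRIPTORS",
    "LIRE_SET",
    "TEXTURE_SET",
    "SELECTED_SET",
    "MISLEADING_SET",
    "descriptor_dim",
    "compute_descriptor",
    "extract_bank",
]


@dataclass(frozen=True)
class FeatureVector:
    name: str
    values: np.ndarray

    @property
    def dim(self) -> int:
        return int(self.values.shape[0])


def _lire(name):
    return lambda frame: lire_descriptor(frame, name)


_REGISTRY = {
    "auto_color_correlogram": lambda f: auto_color_correlogram(f, levels=64, distances=(1, 3, 5, 7)),
    "cedd": _lire("cedd"),
    "color_histogram": lambda f: np.concatenate(
        [color_histogram(f, "RGB", 64), color_histogram(f, "HSV", 64)]
    ),
    "color_layout": _lire("color_layout"),
    "edge_histogram": _lire("edge_histogram"),
    "fcth": _lire("fcth"),
    "gabor": _lire("gabor"),
    "glcm": lambda f: glcm_vector(to_grayscale(f), levels=8, distance=1),
    "haralick": lambda f: haralick_vector(to_grayscale(f), levels=8, distance=1),
    "jcd": _lire("jcd"),
    "lbp": lambda f: lbp_histogram(to_grayscale(f), radii=(1, 2, 3, 4, 5)),
    "ltp": lambda f: ltp_histogram(to_grayscale(f), radii=(1, 2, 3)),
    "phog": _lire("phog"),
    "tamura": _lire("tamura"),
}

_DIMS = {
    "auto_color_correlogram": 64 * 4,
    "cedd": LIRE_DIMS["cedd"],
    "color_histogram": 64 * 6,
    "color_layout": LIRE_DIMS["color_layout"],
    "edge_histogram": LIRE_DIMS["edge_histogram"],
    "fcth": LIRE_DIMS["fcth"],
    "gabor": LIRE_DIMS["gabor"],
    "glcm": 64,
    "haralick": 7,
    "jcd": LIRE_DIMS["jcd"],
    "lbp": 256 * 5,
    "ltp": 512 * 3,
    "phog": LIRE_DIMS["phog"],
    "tamura": LIRE_DIMS["tamura"],
}

ALL_DESCRIPTORS = tuple(sorted(_REGISTRY))

#: LIRE-family descriptors (the "All Lire" ablation row).
LIRE_SET = (
    "auto_color_correlogram",
    "cedd",
    "color_layout",
    "edge_histogram",
    "fcth",
    "gabor",
    "jcd",
    "phog",
    "tamura",
)

#: Texture descriptors (the "All Texture" ablation row).
TEXTURE_SET = ("edge_histogram", "gabor", "glcm", "haralick", "lbp", "ltp", "phog", "tamura")

#: Default handcrafted set (deep features are fused in by the pipeline).
SELECTED_SET = (
    "auto_color_correlogram",
    "color_layout",
    "edge_histogram",
    "gabor",
    "jcd",
    "lbp",
    "phog",
    "tamura",
)

#: Screened out of the default set; kept for ablation rows.
MISLEADING_SET = ("color_histogram", "ltp", "glcm", "haralick")


def descriptor_dim(name: str) -> int:
    try:
        return _DIMS[name]
    except KeyError:
        raise ValueError(f"unknown descriptor {name!r}") from None


def compute_descriptor(frame, name: str) -> FeatureVector:
    if name not in _REGISTRY:
        raise ValueError(f"unknown descriptor {name!r}; choose from {ALL_DESCRIPTORS}")
    values = np.asarray(_REGISTRY[name](frame), dtype=np.float64)
    if values.shape != (_DIMS[name],):
        raise AssertionError(f"{name}: expected dim {_DIMS[name]}, got {values.shape}")
    return FeatureVector(name, values)


def extract_bank(
    frame, config: tuple[str, ...] = SELECTED_SET
) -> tuple[np.ndarray, dict[str, tuple[int, int]]]:
    """Fused vector plus name -> (start, stop) spans, alphabetical order."""
    if not config:
        raise ValueError("descriptor config must not be empty")
    names = sorted(set(config))
    parts = []
    spans: dict[str, tuple[int, int]] = {}
    pos = 0
    for name in names:
        fv = compute_descriptor(frame, name)
        spans[name] = (pos, pos + fv.dim)
        pos += fv.dim
        parts.append(fv.values)
    return np.concatenate(parts), spans


def bank_spans(config: tuple[str, ...]) -> dict[str, tuple[int, int]]:
    """Span table for a config without touching any image."""
    names = sorted(set(config))
    spans = {}
    pos = 0
    for name in names:
        d = descriptor_dim(name)
        spans[name] = (pos, pos + d)
        pos += d
    return spans
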