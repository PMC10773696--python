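"""Core raster and dataset containers plus disk I/O.

A :class:`Frame` is an 8-bit RGB raster with an identifier and an optional
class label; a :class:`LabeledDataset` is an ordered collection of frames
with a CSV manifest representation.  Datasets on disk follow the
class-per-directory convention (one subdirectory per label, PNG/JPEG files
inside) with an optional ``manifest.csv`` (columns ``path,label`` and
optionally ``source_id``) overriding directory discovery.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["Frame", "LabeledDataset", "load_dataset", "save_dataset"]


@dataclass
class Frame:
    """One 8-bit RGB image flowing through the pipeline."""

    pixels: np.ndarray
    id: str = ""
    label: Optional[str] = None
    source_id: Optional[str] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"Frame pixels must be HxWx3, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("Frame channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    def copy(self) -> "Frame":
        return replace(self, pixels=self.pixels.copy())


@dataclass
class LabeledDataset:
    """Ordered frames plus manifest bookkeeping."""

    frames: list[Frame] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def labels(self) -> list[str]:
        return [f.label for f in self.frames]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for f in self.frames:
            counts[f.label] = counts.get(f.label, 0) + 1
        return counts

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "path": [f"{f.label}/{f.id}.png" for f in self.frames],
                "label": [f.label for f in self.frames],
                "source_id": [f.source_id or "" for f in self.frames],
            }
        )

    def subset(self, indices) -> "LabeledDataset":
        return LabeledDataset([self.frames[i] for i in indices])


def save_dataset(data: LabeledDataset, root: str | os.PathLike) -> Path:
    """Write a class-per-directory PNG tree plus ``manifest.csv``."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for f in data.frames:
        d = root / str(f.label)
        d.mkdir(exist_ok=True)
        Image.fromarray(f.pixels).save(d / f"{f.id}.png")
    data.manifest().to_csv(root / "manifest.csv", index=False)
    return root


def load_dataset(root: str | os.PathLike) -> LabeledDataset:
    """Read a dataset written by :func:`save_dataset` or laid out manually."""
    root = Path(root)
    frames: list[Frame] = []
    manifest = root / "manifest.csv"
    if manifest.exists():
        df = pd.read_csv(manifest, keep_default_na=False)
        for _, row in df.iterrows():
            px = np.asarray(Image.open(root / row["path"]).convert("RGB"))
            sid = row.get("source_id", "") or None
            frames.append(
                Frame(px, id=Path(row["path"]).stem, label=str(row["label"]), source_id=sid)
            )
    else:
        for d in sorted(p for p in root.iterdir() if p.is_dir()):
            for img in sorted(d.glob("*")):
                if img.suffix.lower() not in {".png", ".jpg", ".jpeg"}:
                    continue
                px = np.asarray(Image.open(img).convert("RGB"))
                frames.append(Frame(px, id=img.stem, label=d.name))
    return LabeledDataset(frames)
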