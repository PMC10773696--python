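"""Per-dimension min-max scaling of fused feature vectors to [0, 1].

Fit on the training split only; at inference out-of-range values clamp to
[0, 1] and dimensions that were constant during fitting map to 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["MinMaxScaler", "fit_scaler", "scale"]


@dataclass
class MinMaxScaler:
    mins: np.ndarray
    maxs: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != self.mins.shape[0]:
            raise ValueError("dimension mismatch with fitted scaler")
        span = self.maxs - self.mins
        out = np.zeros_like(x)
        ok = span > 0
        out[:, ok] = (x[:, ok] - self.mins[ok]) / span[ok]
        return np.clip(out, 0.0, 1.0)

    def to_json(self) -> str:
        return json.dumps({"mins": self.mins.tolist(), "maxs": self.maxs.tolist()})

    @classmethod
    def from_json(cls, s: str) -> "MinMaxScaler":
        d = json.loads(s)
        return cls(np.asarray(d["mins"], float), np.asarray(d["maxs"], float))


def fit_scaler(vectors) -> MinMaxScaler:
    """Fit per-dimension minima/maxima on a (n, d) stack of vectors."""
    x = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
    if x.size == 0:
        raise ValueError("cannot fit a scaler on no data")
    return MinMaxScaler(mins=x.min(axis=0), maxs=x.max(axis=0))


def scale(scaler: MinMaxScaler, vector: np.ndarray) -> np.ndarray:
    """Scale one vector (or a stack) with a fitted scaler."""
    if scaler is None:
        raise ValueError("scaler must be fitted before scaling")
    out = scaler.transform(vector)
    return out[0] if np.asarray(vector).ndim == 1 else out
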