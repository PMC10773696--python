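"""MobileNet V2 as a NumPy inference graph.

The backbone is the standard inverted-residual architecture: a strided
3x3 stem, seven bottleneck stages with expansion/depthwise/projection
convolutions, and a final 1x1 convolution to 1,280 channels.  Truncated
before the classification head, the globally pooled output flattens to a
1,280-length feature vector for any input size; the untruncated head emits
1,000 class logits (the original pretraining task).

No deep-learning runtime is required: weights are either randomly
initialized (the architecture, and hence every dimensionality contract,
is identical) or loaded from an ``.npz`` checkpoint.  Fine-tuning attaches
a temporary sigmoid classification head and trains it together with the
final 1x1 convolution (the last convolutional block) by explicit
backpropagation with the Nadam optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from endoframe.classify import NadamState, nadam_step
from endoframe.frame import Frame
from endoframe.preprocess import resize_frame

__all__ = [
    "ExtractorConfig",
    "Extractor",
    "build_extractor",
    "deep_features",
    "fine_tune",
    "FEATURE_DIM",
    "HEAD_CLASSES",
]

FEATURE_DIM = 1280
HEAD_CLASSES = 1000

# (expansion t, output channels c, repeats n, first stride s)
_STAGES = [
    (1, 16, 1, 1),
    (6, 24, 2, 2),
    (6, 32, 3, 2),
    (6, 64, 4, 2),
    (6, 96, 3, 1),
    (6, 160, 3, 2),
    (6, 320, 1, 1),
]


def _make_divisible(v: float, divisor: int = 8) -> int:
    new_v = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return new_v


@dataclass(frozen=True)
class ExtractorConfig:
    input_size: tuple[int, int] = (224, 224)
    width_multiplier: float = 1.0
    weights: str = "random"  # "random", "pretrained" or a .npz path
    fine_tune_epochs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")
        if self.fine_tune_epochs < 0:
            raise ValueError("fine_tune_epochs must be non-negative")


def _relu6(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 6.0)


def _conv2d(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """x: (H, W, Cin); w: (kh, kw, Cin, Cout)."""
    if pad:
        x = np.pad(x, ((pad, pad), (pad, pad), (0, 0)))
    kh, kw = w.shape[:2]
    win = sliding_window_view(x, (kh, kw), axis=(0, 1))[::stride, ::stride]
    # win: (Ho, Wo, Cin, kh, kw)
    return np.einsum("hwckl,klcd->hwd", win, w, optimize=True)


def _depthwise(x: np.ndarray, w: np.ndarray, stride: int) -> np.ndarray:
    """x: (H, W, C); w: (3, 3, C); 'same' padding."""
    x = np.pad(x, ((1, 1), (1, 1), (0, 0)))
    win = sliding_window_view(x, (3, 3), axis=(0, 1))[::stride, ::stride]
    return np.einsum("hwckl,klc->hwc", win, w, optimize=True)


def _bn(x: np.ndarray, p: dict) -> np.ndarray:
    return (x - p["mean"]) / np.sqrt(p["var"] + 1e-5) * p["gamma"] + p["beta"]


def _he(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float64)


def _bn_params(c: int) -> dict:
    return {
        "gamma": np.ones(c),
        "beta": np.zeros(c),
        "mean": np.zeros(c),
        "var": np.ones(c),
    }


def _init_params(width: float, rng: np.random.Generator) -> dict:
    p: dict = {}
    c_stem = _make_divisible(32 * width)
    p["stem_w"] = _he(rng, (3, 3, 3, c_stem), 27)
    p["stem_bn"] = _bn_params(c_stem)
    blocks = []
    c_in = c_stem
    for t, c, n, s in _STAGES:
        c_out = _make_divisible(c * width)
        for i in range(n):
            stride = s if i == 0 else 1
            hidden = c_in * t
            blk = {"t": t, "stride": stride, "c_in": c_in, "c_out": c_out}
            if t != 1:
                blk["expand_w"] = _he(rng, (c_in, hidden), c_in)
                blk["expand_bn"] = _bn_params(hidden)
            blk["dw_w"] = _he(rng, (3, 3, hidden), 9)
            blk["dw_bn"] = _bn_params(hidden)
            blk["project_w"] = _he(rng, (hidden, c_out), hidden)
            blk["project_bn"] = _bn_params(c_out)
            blocks.append(blk)
            c_in = c_out
    p["blocks"] = blocks
    c_last = _make_divisible(1280 * width) if width > 1.0 else 1280
    p["final_w"] = _he(rng, (c_in, c_last), c_in)
    p["final_bn"] = _bn_params(c_last)
    p["head_w"] = _he(rng, (c_last, HEAD_CLASSES), c_last)
    p["head_b"] = np.zeros(HEAD_CLASSES)
    return p


class Extractor:
    """Frozen-weight MobileNet V2 with a detachable classification head."""

    def __init__(self, config: ExtractorConfig, params: dict):
        self.config = config
        self.params = params

    # -- forward pieces -------------------------------------------------

    def _trunk(self, x: np.ndarray) -> np.ndarray:
        """Input image tensor -> (h, w, 320-ish) pre-final feature map."""
        p = self.params
        x = _relu6(_bn(_conv2d(x, p["stem_w"], stride=2, pad=1), p["stem_bn"]))
        for blk in p["blocks"]:
            inp = x
            if blk["t"] != 1:
                x = _relu6(_bn(x @ blk["expand_w"], blk["expand_bn"]))
            x = _relu6(_bn(_depthwise(x, blk["dw_w"], blk["stride"]), blk["dw_bn"]))
            x = _bn(x @ blk["project_w"], blk["project_bn"])
            if blk["stride"] == 1 and blk["c_in"] == blk["c_out"]:
                x = x + inp
        return x

    def _final_map(self, x: np.ndarray) -> np.ndarray:
        p = self.params
        return _relu6(_bn(self._trunk(x) @ p["final_w"], p["final_bn"]))

    def preprocess_frame(self, frame: Frame | np.ndarray) -> np.ndarray:
        """Resize to the configured input and map to the [-1, 1] convention."""
        px = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
        px = resize_frame(px, self.config.input_size)
        return px.astype(np.float64) / 127.5 - 1.0

    def features(self, frame: Frame | np.ndarray) -> np.ndarray:
        """Truncated-backbone output: pooled and flattened, length 1,280."""
        fmap = self._final_map(self.preprocess_frame(frame))
        return fmap.mean(axis=(0, 1))

    def logits(self, frame: Frame | np.ndarray) -> np.ndarray:
        """Untruncated output: the original 1,000-way classification layer."""
        p = self.params
        return self.features(frame) @ p["head_w"] + p["head_b"]

    @property
    def feature_dim(self) -> int:
        return int(self.params["final_w"].shape[1])

    def save(self, path: str) -> None:
        flat = {"stem_w": self.params["stem_w"], "final_w": self.params["final_w"],
                "head_w": self.params["head_w"], "head_b": self.params["head_b"]}
        for key in ("stem_bn", "final_bn"):
            for k, v in self.params[key].items():
                flat[f"{key}.{k}"] = v
        for i, blk in enumerate(self.params["blocks"]):
            for k, v in blk.items():
                if isinstance(v, dict):
                    for kk, vv in v.items():
                        flat[f"b{i}.{k}.{kk}"] = vv
                elif isinstance(v, np.ndarray):
                    flat[f"b{i}.{k}"] = v
                else:
                    flat[f"b{i}.{k}"] = np.asarray(v)
        np.savez(path, **flat)


def build_extractor(config: ExtractorConfig | None = None) -> Extractor:
    """Instantiate the backbone per config; random weights by default."""
    config = config or ExtractorConfig()
    if config.weights == "pretrained":
        raise ValueError(
            "pretrained weights require a downloaded checkpoint; pass the "
            "path of an .npz export as `weights` or use weights='random'"
        )
    rng = np.random.default_rng(config.seed)
    if config.weights == "random":
        params = _init_params(config.width_multiplier, rng)
    else:  # treat as an .npz checkpoint path
        params = _load_npz(config.weights, config.width_multiplier, rng)
    return Extractor(config, params)


def _load_npz(path: str, width: float, rng: np.random.Generator) -> dict:
    params = _init_params(width, rng)
    data = np.load(path)
    params["stem_w"] = data["stem_w"]
    params["final_w"] = data["final_w"]
    params["head_w"] = data["head_w"]
    params["head_b"] = data["head_b"]
    for key in ("stem_bn", "final_bn"):
        for k in params[key]:
            params[key][k] = data[f"{key}.{k}"]
    for i, blk in enumerate(params["blocks"]):
        for k in list(blk):
            if isinstance(blk[k], dict):
                for kk in blk[k]:
                    blk[k][kk] = data[f"b{i}.{k}.{kk}"]
            elif isinstance(blk[k], np.ndarray):
                blk[k] = data[f"b{i}.{k}"]
    return params


def deep_features(ex: Extractor, frame: Frame | np.ndarray) -> np.ndarray:
    """Length-1,280 deep feature vector for one frame."""
    return ex.features(frame)


def fine_tune(ex: Extractor, data, epochs: int, seed: int = 0,
              lr: float = 1e-3) -> Extractor:
    """Fine-tune the final convolutional block on a labelled dataset.

    A temporary sigmoid classification head is attached, the final 1x1
    convolution and the head are trained with Nadam on per-class binary
    cross-entropy, and the head is detached.  ``epochs == 0`` returns an
    extractor with identical weights.
    """
    labels = sorted({f.label for f in data})
    if len(labels) < 2:
        raise ValueError("fine-tuning needs at least 2 classes")
    if epochs == 0:
        return ex
    lab_idx = {l: i for i, l in enumerate(labels)}
    y = np.zeros((len(data), len(labels)))
    for i, f in enumerate(data):
        y[i, lab_idx[f.label]] = 1.0

    # frozen trunk activations, computed once
    maps = np.stack([ex._trunk(ex.preprocess_frame(f)) for f in data])
    n, mh, mw, c_in = maps.shape
    bn = ex.params["final_bn"]
    bn_scale = bn["gamma"] / np.sqrt(bn["var"] + 1e-5)
    bn_shift = bn["beta"] - bn["mean"] * bn_scale

    rng = np.random.default_rng(seed)
    w_conv = ex.params["final_w"].copy()
    c_last = w_conv.shape[1]
    w_head = rng.normal(0.0, np.sqrt(1.0 / c_last), size=(c_last, len(labels)))
    b_head = np.zeros(len(labels))

    params = [w_conv, w_head, b_head]
    state = NadamState.for_params(params)
    losses = []
    for _ in range(epochs):
        z = maps @ w_conv * bn_scale + bn_shift
        a = _relu6(z)
        pooled = a.mean(axis=(1, 2))
        logits = pooled @ w_head + b_head
        probs = 1.0 / (1.0 + np.exp(-logits))
        eps = 1e-12
        losses.append(float(-(y * np.log(probs + eps)
                              + (1 - y) * np.log(1 - probs + eps)).mean()))
        dlogits = (probs - y) / (y.shape[0] * y.shape[1])
        g_whead = pooled.T @ dlogits
        g_bhead = dlogits.sum(axis=0)
        dpooled = dlogits @ w_head.T
        da = dpooled[:, None, None, :] / (mh * mw)
        dz = da * ((z > 0) & (z < 6)) * bn_scale
        g_wconv = np.einsum("nhwc,nhwd->cd", maps, dz, optimize=True)
        params, state = nadam_step(params, [g_wconv, g_whead, g_bhead], state,
                                   {"lr": lr})
        w_conv, w_head, b_head = params

    new_params = dict(ex.params)
    new_params["final_w"] = w_conv
    out = Extractor(ex.config, new_params)
    out.fine_tune_losses_ = losses  # training curve, for diagnostics
    return out
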