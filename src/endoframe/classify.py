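"""Three-layer fusion classifier and feature-selection search.

The network is two ReLU hidden layers of 64 units followed by a sigmoid
output with one unit per class, so each output is an independent class
probability in (0, 1) ready for per-class thresholding (rows need not sum
to 1).  Training minimizes per-class binary cross-entropy with the Nadam
optimizer; a softmax/cross-entropy alternative is selectable.

``nadam_step`` follows the standard Nesterov-Adam update: with
bias-corrected moments m̂_t, v̂_t,

    θ <- θ - lr / (sqrt(v̂_t) + eps) * (β1 m̂_t + (1-β1) g_t / (1-β1^t))
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from endoframe.metrics import confusion, f1_macro

__all__ = [
    "NetConfig",
    "NadamState",
    "relu",
    "sigmoid",
    "nadam_step",
    "ThreeLayerNet",
    "forward",
    "train",
    "predict_proba",
    "evaluate_feature_set",
    "select_features",
    "stratified_split",
]


def relu(x):
    """max(0, x), elementwise."""
    return np.maximum(0.0, x)


def sigmoid(x):
    """1 / (1 + exp(-x)), numerically stable for large |x|."""
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class NetConfig:
    hidden1: int = 64
    hidden2: int = 64
    out_units: int = 2  # one per class
    epochs: int = 100
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int = 32
    loss: str = "bce"  # "bce" (independent sigmoids) or "softmax"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.out_units < 2:
            raise ValueError("out_units must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss not in ("bce", "softmax"):
            raise ValueError("loss must be 'bce' or 'softmax'")


@dataclass
class NadamState:
    m: list[np.ndarray]
    v: list[np.ndarray]
    t: int = 0

    @classmethod
    def for_params(cls, params) -> "NadamState":
        return cls(
            m=[np.zeros_like(p) for p in params],
            v=[np.zeros_like(p) for p in params],
        )


_NADAM_DEFAULTS = {"lr": 1e-3, "beta1": 0.9, "beta2": 0.999, "eps": 1e-8}


def nadam_step(params, grads, state: NadamState, hyper: dict | None = None):
    """One Nadam update over a list of parameter arrays; returns
    (new params, new state).  Raises on non-finite gradients."""
    h = dict(_NADAM_DEFAULTS)
    if hyper:
        h.update(hyper)
    lr, b1, b2, eps = h["lr"], h["beta1"], h["beta2"], h["eps"]
    t = state.t + 1
    new_params, new_m, new_v = [], [], []
    for p, g, m, v in zip(params, grads, state.m, state.v):
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite gradient in nadam_step")
        m = b1 * m + (1.0 - b1) * g
        v = b2 * v + (1.0 - b2) * g * g
        m_hat = m / (1.0 - b1**t)
        v_hat = v / (1.0 - b2**t)
        update = lr / (np.sqrt(v_hat) + eps) * (
            b1 * m_hat + (1.0 - b1) * g / (1.0 - b1**t)
        )
        new_params.append(p - update)
        new_m.append(m)
        new_v.append(v)
    return new_params, NadamState(new_m, new_v, t)


class ThreeLayerNet:
    """64-64-(n classes) fully connected network with sigmoid outputs."""

    def __init__(self, in_dim: int, config: NetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        dims = [in_dim, config.hidden1, config.hidden2, config.out_units]
        self.weights = [
            rng.normal(0.0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1]))
            for i in range(3)
        ]
        self.biases = [np.zeros(dims[i + 1]) for i in range(3)]
        self.classes_: list | None = None
        self.loss_history_: list[float] = []

    # -- forward --------------------------------------------------------

    def _hidden(self, x: np.ndarray):
        h1 = relu(x @ self.weights[0] + self.biases[0])
        h2 = relu(h1 @ self.weights[1] + self.biases[1])
        return h1, h2

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != self.weights[0].shape[0]:
            raise ValueError("input dimension does not match the first layer")
        _, h2 = self._hidden(x)
        z = h2 @ self.weights[2] + self.biases[2]
        if self.config.loss == "softmax":
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            return e / e.sum(axis=1, keepdims=True)
        return sigmoid(z)


def forward(net: ThreeLayerNet, x: np.ndarray) -> np.ndarray:
    """Probability vector(s) for scaled input(s)."""
    out = net.forward(x)
    return out[0] if np.asarray(x).ndim == 1 else out


def _one_hot(labels: np.ndarray, k: int) -> np.ndarray:
    y = np.zeros((labels.shape[0], k))
    y[np.arange(labels.shape[0]), labels] = 1.0
    return y


def train(features: np.ndarray, labels, config: NetConfig | None = None) -> ThreeLayerNet:
    """Train the three-layer network; deterministic per config seed."""
    x = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    k = int(labels.max()) + 1
    if config is None:
        config = NetConfig(out_units=k)
    elif config.out_units != k:
        config = replace(config, out_units=k)
    net = ThreeLayerNet(x.shape[1], config)
    y = _one_hot(labels, k)
    rng = np.random.default_rng(config.seed + 1)
    params = net.weights + net.biases
    state = NadamState.for_params(params)
    hyper = {
        "lr": config.learning_rate,
        "beta1": config.beta1,
        "beta2": config.beta2,
        "eps": config.eps,
    }
    n = x.shape[0]
    bs = min(config.batch_size, n)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            xb, yb = x[idx], y[idx]
            h1 = relu(xb @ net.weights[0] + net.biases[0])
            h2 = relu(h1 @ net.weights[1] + net.biases[1])
            z = h2 @ net.weights[2] + net.biases[2]
            if config.loss == "softmax":
                zs = z - z.max(axis=1, keepdims=True)
                e = np.exp(zs)
                p = e / e.sum(axis=1, keepdims=True)
                loss = float(-(yb * np.log(p + 1e-12)).sum(axis=1).mean())
                dz = (p - yb) / xb.shape[0]
            else:
                p = sigmoid(z)
                loss = float(
                    -(yb * np.log(p + 1e-12) + (1 - yb) * np.log(1 - p + 1e-12)).mean()
                )
                dz = (p - yb) / (xb.shape[0] * k)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training loss became non-finite (epoch {len(net.loss_history_)})"
                )
            epoch_loss += loss * xb.shape[0]
            g_w3 = h2.T @ dz
            g_b3 = dz.sum(axis=0)
            dh2 = (dz @ net.weights[2].T) * (h2 > 0)
            g_w2 = h1.T @ dh2
            g_b2 = dh2.sum(axis=0)
            dh1 = (dh2 @ net.weights[1].T) * (h1 > 0)
            g_w1 = xb.T @ dh1
            g_b1 = dh1.sum(axis=0)
            grads = [g_w1, g_w2, g_w3, g_b1, g_b2, g_b3]
            params, state = nadam_step(params, grads, state, hyper)
            net.weights = params[:3]
            net.biases = params[3:]
        net.loss_history_.append(epoch_loss / n)
    net.classes_ = list(range(k))
    return net


def predict_proba(net: ThreeLayerNet, features: np.ndarray) -> np.ndarray:
    """(n samples, n classes) matrix of independent class probabilities."""
    probs = net.forward(features)
    return np.clip(probs, 1e-12, 1.0 - 1e-12)


def stratified_split(labels, test_fraction: float, seed: int):
    """Indices of a seeded stratified split; at least one test sample per
    class whenever a class has two or more samples."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(idx.size)]
        n_test = int(round(idx.size * test_fraction))
        if idx.size >= 2:
            n_test = min(max(n_test, 1), idx.size - 1)
        else:
            n_test = 0
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(test_idx))


def _baseline(name: str, seed: int):
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise ValueError("baseline must be 'decision_tree' or 'random_forest'")


def evaluate_feature_set(
    features: np.ndarray,
    labels,
    baseline: str = "decision_tree",
    test_fraction: float = 0.2,
    seed: int = 0,
) -> float:
    """Macro F1 of a tree baseline on a held-out stratified split."""
    labels = np.asarray(labels, dtype=int)
    tr, te = stratified_split(labels, test_fraction, seed)
    clf = _baseline(baseline, seed)
    clf.fit(features[tr], labels[tr])
    preds = clf.predict(features[te])
    k = int(labels.max()) + 1
    return f1_macro(confusion(labels[te], preds, k))


def select_features(
    spans: dict[str, tuple[int, int]],
    features: np.ndarray,
    labels,
    n_trials: int = 10,
    seed: int = 0,
    published_set: tuple[str, ...] | None = None,
    baseline: str = "decision_tree",
) -> tuple[str, ...]:
    """Random-subset descriptor search scored by the tree baseline.

    The full set and (when its descriptors are present) the published
    selected set are always evaluated alongside ``n_trials`` random
    subsets; ties break toward fewer total dimensions.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    names = sorted(spans)
    rng = np.random.default_rng(seed)
    candidates = [tuple(names)]
    if published_set:
        pub = tuple(sorted(set(published_set) & set(names)))
        if pub and pub not in candidates:
            candidates.append(pub)
    for _ in range(n_trials):
        mask = rng.random(len(names)) < 0.5
        if not mask.any():
            mask[rng.integers(0, len(names))] = True
        cand = tuple(n for n, m in zip(names, mask) if m)
        if cand not in candidates:
            candidates.append(cand)

    def slice_cols(subset):
        cols = np.concatenate([np.arange(*spans[n]) for n in subset])
        return features[:, cols], cols.size

    best, best_f1, best_dim = None, -1.0, np.inf
    for cand in candidates:
        x, dim = slice_cols(cand)
        f1 = evaluate_feature_set(x, labels, baseline=baseline, seed=seed)
        if f1 > best_f1 + 1e-12 or (abs(f1 - best_f1) <= 1e-12 and dim < best_dim):
            best, best_f1, best_dim = cand, f1, dim
    return best
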