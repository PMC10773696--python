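"""Genetic-algorithm learning of per-class decision thresholds.

A chromosome is one threshold per class in [0, 1).  Crossover is additive
with a mod-1 wrap: (x, y) -> ((x + 2y) mod 1, (2x + y) mod 1).  Mutation
resamples each gene uniformly with a fixed probability.  Fitness is the
macro F1 obtained by thresholded decisions on a probability matrix, and
selection is truncation with elitism, so the best fitness never decreases.

The decision rule: among classes whose probability clears their threshold,
pick the largest margin (probability minus threshold); if no class
qualifies, fall back to plain argmax.  With all thresholds equal this
degrades to argmax.  A raw-probability variant is available via
``rule="raw"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from endoframe.metrics import confusion, f1_macro

__all__ = [
    "GAConfig",
    "decide",
    "decide_batch",
    "crossover",
    "mutate",
    "fitness",
    "run_gaboost",
]


@dataclass(frozen=True)
class GAConfig:
    population: int = 10
    mutation_rate: float = 0.20
    iterations: int = 20
    elitism: bool = True
    seed: int = 0
    discrete_init: bool = False  # init genes on the 0.0..0.9 grid instead of U[0,1)
    rule: str = "margin"

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.rule not in ("margin", "raw"):
            raise ValueError("rule must be 'margin' or 'raw'")


def decide_batch(probs: np.ndarray, t: np.ndarray, rule: str = "margin") -> np.ndarray:
    """Vectorized decision rule over an (n, k) probability matrix."""
    probs = np.asarray(probs, dtype=float)
    t = np.asarray(t, dtype=float)
    if probs.shape[1] != t.shape[0]:
        raise ValueError("threshold length must equal number of classes")
    margin = probs - t[None, :]
    qualifies = margin >= 0.0
    key = margin if rule == "margin" else probs
    # non-qualifying classes are pushed below every qualifying one
    masked = np.where(qualifies, key, -np.inf)
    preds = np.argmax(masked, axis=1)  # argmax takes lowest index on ties
    none_q = ~qualifies.any(axis=1)
    if none_q.any():
        preds[none_q] = np.argmax(probs[none_q], axis=1)
    return preds


def decide(p: np.ndarray, t: np.ndarray, rule: str = "margin") -> int:
    """Class index for a single probability vector."""
    return int(decide_batch(np.asarray(p, float)[None, :], t, rule=rule)[0])


def crossover(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Additive mod-1 crossover; outputs always lie in [0, 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("chromosomes must have equal length")
    return np.mod(x + 2.0 * y, 1.0), np.mod(2.0 * x + y, 1.0)


def mutate(t: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Resample each gene uniformly in [0, 1) with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    t = np.asarray(t, dtype=float).copy()
    hit = rng.random(t.shape) < rate
    t[hit] = rng.random(int(hit.sum()))
    return t


def fitness(
    t: np.ndarray, probs: np.ndarray, labels, rule: str = "margin"
) -> float:
    """Macro F1 of thresholded decisions against the labels."""
    labels = np.asarray(labels, dtype=int)
    preds = decide_batch(probs, t, rule=rule)
    return f1_macro(confusion(labels, preds, probs.shape[1]))


def run_gaboost(
    probs: np.ndarray,
    labels,
    config: GAConfig | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Evolve per-class thresholds; returns (best chromosome, best-fitness
    history, one entry per iteration, non-decreasing under elitism).

    The initial population always contains an all-0.5 baseline chromosome,
    so the result is never worse than a fixed 0.5 threshold.
    """
    config = config or GAConfig()
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    k = probs.shape[1]
    if k < 2 or len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes with samples")
    rng = np.random.default_rng(config.seed)
    if config.discrete_init:
        pop = rng.integers(0, 10, size=(config.population, k)) / 10.0
    else:
        pop = rng.random((config.population, k))
    pop[0] = 0.5  # seeded baseline chromosome

    def fit(t: np.ndarray) -> float:
        return fitness(t, probs, labels, rule=config.rule)

    scores = np.array([fit(t) for t in pop])
    best_t = pop[int(np.argmax(scores))].copy()
    best_s = float(scores.max())
    history: list[float] = []

    n_keep = max(2, config.population // 2)
    for _ in range(config.iterations):
        order = np.argsort(-scores, kind="stable")
        survivors = pop[order[:n_keep]].copy()
        children = []
        while len(survivors) + len(children) < config.population:
            i, j = rng.integers(0, n_keep, size=2)
            a, b = crossover(survivors[i], survivors[j])
            children.append(a)
            if len(survivors) + len(children) < config.population:
                children.append(b)
        pop = np.vstack([survivors] + ([np.vstack(children)] if children else []))
        start = 1 if config.elitism else 0  # elite member escapes mutation
        for m in range(start, config.population):
            pop[m] = mutate(pop[m], config.mutation_rate, rng)
        if config.elitism:
            pop[0] = best_t  # best-ever always survives
        scores = np.array([fit(t) for t in pop])
        it_best = int(np.argmax(scores))
        if scores[it_best] > best_s:
            best_s = float(scores[it_best])
            best_t = pop[it_best].copy()
        history.append(best_s)
    return best_t, history
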