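"""Budgeted active learning for training-set construction.

Starting from a small initial labeled set K, the loop repeatedly retrains
the spatio-temporal model on the current set K', scores every unlabeled
node by the euclidean distance between its forecast and the vector of
training labels at the target step (output-space diversity), and queries
the node with the largest score. Three initial-selection strategies are
provided: uniform random, scattered (greedy max-min over weighted
shortest-path distances) and closer (greedily following the heaviest
edges out of the current set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .graphs import ZipGraph
from .model import HesitancySTL, TrainConfig, TrainSplit
from .panel import NodePanel
from .spatial import SpatialConfig
from .temporal import TemporalConfig

__all__ = ["ALConfig", "ALTrace", "select_initial", "al_score", "al_loop"]


@dataclass
class ALConfig:
    initial_size: int = 10
    budget: int = 10
    init_strategy: str = "random"    # random | scattered | closer
    seed: int = 0
    retrain_epochs: int = 500
    score_mode: str = "norm"         # norm: ||pred - labels||; min: min |pred - label|

    def __post_init__(self):
        if self.initial_size < 1 or self.budget < 0:
            raise ValueError("initial_size >= 1 and budget >= 0 required")
        if self.init_strategy not in {"random", "scattered", "closer"}:
            raise ValueError(f"unknown strategy {self.init_strategy!r}")


@dataclass
class ALTrace:
    selected_order: list[int] = field(default_factory=list)
    scores: list[dict[int, float]] = field(default_factory=list)


def select_initial(g: ZipGraph, n: int, strategy: str = "random",
                   seed: int = 0, start: int | None = None) -> list[int]:
    """Pick the initial labeled node set using one of three strategies.

    random: uniform without replacement. scattered: greedy max-min over
    weighted shortest-path distances (edge length 1/w), seeded at a
    diameter endpoint so the choice is deterministic. closer: a start node
    (random unless given), then repeatedly the unselected node with the
    heaviest edge into the current set.
    """
    N = g.n_nodes
    if n > N:
        raise ValueError(f"cannot select {n} of {N} nodes")
    rng = np.random.default_rng(seed)
    if strategy == "random":
        return sorted(int(i) for i in rng.choice(N, size=n, replace=False))

    if strategy == "scattered":
        # greedy max-min over weighted shortest paths, edge length = 1/w
        lengths = np.zeros_like(g.W)
        nz = g.W > 0
        lengths[nz] = 1.0 / g.W[nz]
        dist = dijkstra(csr_matrix(lengths), directed=False)
        if start is None:
            # deterministic: an endpoint of the (finite) graph diameter
            finite = np.where(np.isfinite(dist), dist, -1.0)
            start = int(np.argmax(finite.max(axis=1)))
        selected = [int(start)]
        while len(selected) < n:
            d_min = dist[:, selected].min(axis=1)
            d_min[selected] = -np.inf
            # unreachable nodes (inf) are maximally scattered, picked first
            selected.append(int(np.argmax(d_min)))
        return sorted(selected)

    # closer: seed node, then repeatedly the heaviest edge into the set
    selected = [int(start) if start is not None else int(rng.integers(N))]
    while len(selected) < n:
        best_w = g.W[selected].max(axis=0)
        best_w[selected] = -np.inf
        selected.append(int(np.argmax(best_w)))
    return sorted(selected)


def al_score(prediction: float, labels: np.ndarray,
             mode: str = "norm") -> float:
    """Distance between a candidate's forecast and the training labels.

    `norm` is the euclidean norm of (prediction - label_k) over all labeled
    nodes k; `min` is the distance to the closest label.
    """
    labels = np.asarray(labels, dtype=np.float64)
    diffs = prediction - labels
    if mode == "norm":
        return float(np.linalg.norm(diffs))
    if mode == "min":
        return float(np.min(np.abs(diffs)))
    raise ValueError(f"unknown score mode {mode!r}")


def al_loop(panel: NodePanel, g: ZipGraph, cfg: ALConfig,
            spatial: SpatialConfig | None = None,
            temporal: TemporalConfig | None = None,
            initial_K: list[int] | None = None,
            train: TrainConfig | None = None) -> tuple[list[int], ALTrace]:
    """Grow the training set by `budget` queried nodes.

    Labels for any queried node must exist in the panel (simulated-oracle
    setting). Each iteration retrains from scratch at `retrain_epochs`,
    scores all candidates at the target step T+1, and adds the argmax
    (ties broken by lowest node index).
    """
    N = panel.n_nodes
    K = initial_K if initial_K is not None else \
        select_initial(g, cfg.initial_size, cfg.init_strategy, cfg.seed)
    if cfg.budget > N - len(K):
        raise ValueError("budget exceeds the number of unlabeled nodes")
    K_prime = sorted(K)
    trace = ALTrace()
    target_t = panel.n_timesteps - 1          # labels for T+1 live here
    base_train = train or TrainConfig()
    for it in range(cfg.budget):
        split = TrainSplit(K_prime, sorted(set(range(N)) - set(K_prime)))
        tc = TrainConfig(**{**base_train.__dict__,
                            "epochs": cfg.retrain_epochs, "seed": cfg.seed})
        res = HesitancySTL(panel, g, split, spatial=spatial,
                           temporal=temporal, train=tc).fit()
        candidates = np.asarray(split.eval_set)
        preds = res.predict(candidates, horizon=1)[:, -1]
        obs = panel.mask[K_prime, target_t]
        labels = panel.h[np.asarray(K_prime)[obs], target_t]
        scores = {int(x): al_score(float(p), labels, cfg.score_mode)
                  for x, p in zip(candidates, preds)}
        best = min(scores, key=lambda x: (-scores[x], x))
        trace.selected_order.append(best)
        trace.scores.append(scores)
        K_prime = sorted(K_prime + [best])
    return K_prime, trace
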