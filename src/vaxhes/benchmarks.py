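"""Canonical synthetic benchmark studies and desk-scale model settings.

These helpers bundle the package's standard evaluation conditions: a
planted-structure study (spatially autocorrelated hesitancy with
demographic dependence over a gravity contact graph) and the reduced
model sizes used for single-CPU experiments. Tests and the reproduction
script share them so every experiment runs under identical conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphs import (ZipGraph, build_adjacency_graph,
                     build_aggregated_contact_graph, build_distance_graph,
                     minmax_normalize_weights)
from .claims import normalize_features
from .model import TrainConfig
from .panel import NodePanel
from .simulate import (SimConfig, ZipGeometry, simulate_contact_network,
                       simulate_geography, simulate_panel)
from .spatial import SpatialConfig
from .temporal import TemporalConfig

__all__ = ["Study", "make_study", "desk_spatial", "desk_temporal",
           "desk_train", "fit_and_score", "al_vs_random"]


@dataclass
class Study:
    """A generated benchmark: normalized panel, graph variants, truth."""

    panel: NodePanel                 # normalized features, raw-fraction h
    panel_raw: NodePanel
    ga: ZipGraph                     # aggregated contact graph (normalized)
    gb1: ZipGraph                    # geographic adjacency
    gb2: ZipGraph                    # inverse centroid distance (normalized)
    geom: ZipGeometry
    truth: dict
    cfg: SimConfig


def make_study(cfg: SimConfig) -> Study:
    """Simulate geography, contacts and the panel; build all graph variants."""
    geom = simulate_geography(cfg)
    edges = simulate_contact_network(geom, cfg)
    zips = sorted(geom.centroids)
    ga = minmax_normalize_weights(build_aggregated_contact_graph(edges, zips))
    gb1 = build_adjacency_graph(geom, zips)
    gb2 = minmax_normalize_weights(build_distance_graph(geom, zips))
    panel_raw, truth = simulate_panel(geom, ga, cfg)
    panel = normalize_features(panel_raw)
    return Study(panel=panel, panel_raw=panel_raw, ga=ga, gb1=gb1, gb2=gb2,
                 geom=geom, truth=truth, cfg=cfg)


def desk_spatial(hidden: int = 32, dropout: float = 0.6) -> SpatialConfig:
    """Reduced spatial module for single-CPU experiments."""
    return SpatialConfig(hidden=hidden, dropout_rate=dropout)


def desk_temporal(hidden: int = 8) -> TemporalConfig:
    return TemporalConfig(hidden=hidden, dropout_rate=0.0)


def desk_train(epochs: int = 2500, seed: int = 0, lr: float = 2e-3
               ) -> TrainConfig:
    return TrainConfig(epochs=epochs, seed=seed, lr=lr, mape_eps=0.15)


def fit_and_score(study: Study, K: list[int], epochs: int, seed: int,
                  spatial: SpatialConfig | None = None,
                  temporal: TemporalConfig | None = None) -> float:
    """Train on labeled set K and return the eval-set forecast MAPE."""
    from .model import HesitancySTL, TrainSplit
    n = study.panel.n_nodes
    split = TrainSplit(sorted(K), sorted(set(range(n)) - set(K)))
    res = HesitancySTL(study.panel, study.ga, split,
                       spatial=spatial or desk_spatial(),
                       temporal=temporal or desk_temporal(),
                       train=desk_train(epochs=epochs, seed=seed)).fit()
    return res.evaluate().mape


def al_vs_random(study: Study, n_seeds: int = 20, initial_size: int = 10,
                 budget: int = 10, retrain_epochs: int = 80,
                 final_epochs: int = 500,
                 spatial: SpatialConfig | None = None,
                 temporal: TemporalConfig | None = None) -> dict:
    """Budgeted query selection vs equally sized random label sets.

    For each seed, grow an initial random set by `budget` actively queried
    ZIPs, then compare the forecast error of a model trained on that set
    against one trained on an independent random set of equal size.
    """
    from .active import ALConfig, al_loop, select_initial
    spatial = spatial or SpatialConfig(hidden=16, dropout_rate=0.5)
    temporal = temporal or desk_temporal(hidden=8)
    mape_al, mape_rand = [], []
    for seed in range(n_seeds):
        cfg = ALConfig(initial_size=initial_size, budget=budget,
                       init_strategy="random", seed=seed,
                       retrain_epochs=retrain_epochs)
        K_al, _ = al_loop(study.panel, study.ga, cfg, spatial=spatial,
                          temporal=temporal,
                          train=desk_train(epochs=retrain_epochs, seed=seed))
        mape_al.append(fit_and_score(study, K_al, final_epochs, seed,
                                     spatial, temporal))
        K_rand = select_initial(study.ga, initial_size + budget, "random",
                                seed=seed + 104729)
        mape_rand.append(fit_and_score(study, K_rand, final_epochs, seed,
                                       spatial, temporal))
    return {"mape_al": mape_al, "mape_random": mape_rand,
            "mean_al": float(np.mean(mape_al)),
            "mean_random": float(np.mean(mape_rand))}
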