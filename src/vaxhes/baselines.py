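"""Comparison models and ablations for the spatio-temporal forecaster.

All baselines consume the same panel, graph and train/eval split as the
main model (fair-comparison contract):

* ``lrn`` — linear regression with a labeled-neighbour hesitancy feature,
* ``mlp`` — feedforward network on each node's flattened feature history,
* ``gnn_gru`` — the full framework with the LSTM swapped for a GRU,
* ``gcn_lstm`` — spatial layers swapped for symmetric-normalized GCN
  convolution with self-loops,
* ``gnn_only`` — spatial module alone (forecast from the last feature
  step),
* ``lstm_only`` — temporal module trained directly on observed hesitancy
  series. NOTE: at evaluation this consumes the eval nodes' own observed
  h histories, a deliberately different (easier) information regime than
  the cold-start contract of every other model; reports flag it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphs import ZipGraph
from .metrics import MetricReport, metrics
from .model import HesitancySTL, TrainConfig, TrainSplit
from .nn import Adam, Linear, Module, Tensor, dropout, mape_loss
from .panel import NodePanel
from .spatial import SpatialConfig, SpatialModule, loss1
from .temporal import (SequenceBatch, TemporalConfig, TemporalModule,
                       forecast, loss2)

__all__ = ["lrn_fit_predict", "baseline_forecast", "BaselineConfig"]


@dataclass
class BaselineConfig:
    train: TrainConfig = field(default_factory=TrainConfig)
    spatial: SpatialConfig = field(default_factory=SpatialConfig)
    temporal: TemporalConfig = field(default_factory=TemporalConfig)
    mlp_hidden: tuple[int, int] = (128, 128)


def _target_step(panel: NodePanel, cfg: TrainConfig) -> tuple[int, int]:
    T = cfg.T if cfg.T is not None else panel.n_timesteps - cfg.horizon
    return T, T + cfg.horizon - 1


def lrn_fit_predict(panel: NodePanel, g: ZipGraph, split: TrainSplit,
                    cfg: TrainConfig | None = None) -> np.ndarray:
    """Linear regression with a labeled-neighbour hesitancy feature.

    Design per node i: [nc_i(T), Σ_{j in N(i) ∩ K} h_j(T) w(i,j)]; ordinary
    least squares fitted on K against h(target step), applied to the eval
    nodes. Nodes with no labeled neighbour get a zero neighbour feature.
    A singular design falls back to ridge (lstsq handles rank deficiency).
    """
    cfg = cfg or TrainConfig(epochs=1)
    T, target_t = _target_step(panel, cfg)
    K = np.asarray(split.K)
    evals = np.asarray(split.eval_set)
    labeled_h = np.zeros(panel.n_nodes)
    labeled_h[K] = panel.h[K, T - 1]                 # last observed step
    in_K = np.zeros(panel.n_nodes)
    in_K[K] = 1.0
    neigh = g.W @ (labeled_h * in_K)                 # labeled neighbours only
    X_all = np.column_stack([panel.nc[:, :, T - 1], neigh,
                             np.ones(panel.n_nodes)])
    coef, *_ = np.linalg.lstsq(X_all[K], panel.h[K, target_t], rcond=None)
    return X_all[evals] @ coef


class _MLP(Module):
    def __init__(self, d_in: int, hidden: tuple[int, int], dropout_rate: float,
                 rng: np.random.Generator):
        dims = [d_in, *hidden, 1]
        self.layers = [Linear(dims[i], dims[i + 1], rng)
                       for i in range(len(dims) - 1)]
        self.dropout_rate = dropout_rate

    def __call__(self, x: Tensor, training: bool,
                 rng: np.random.Generator | None = None) -> Tensor:
        for li, layer in enumerate(self.layers):
            x = layer(x)
            if li < len(self.layers) - 1:
                x = x.relu()
                if training and self.dropout_rate > 0:
                    x = dropout(x, self.dropout_rate, rng, True)
        return x.reshape(-1)


def _mlp_forecast(panel: NodePanel, split: TrainSplit,
                  cfg: BaselineConfig) -> np.ndarray:
    tc = cfg.train
    T, target_t = _target_step(panel, tc)
    rng = np.random.default_rng(tc.seed)
    K = np.asarray(split.K)
    evals = np.asarray(split.eval_set)
    flat = panel.nc[:, :, :T].reshape(panel.n_nodes, -1)
    model = _MLP(flat.shape[1], cfg.mlp_hidden,
                 cfg.spatial.dropout_rate, rng)
    opt = Adam(model.parameters(), lr=tc.lr, weight_decay=tc.weight_decay)
    y = panel.h[K, target_t]
    for _ in range(tc.epochs):
        pred = model(Tensor(flat[K]), training=True, rng=rng)
        l = mape_loss(y, pred, eps=tc.mape_eps)
        if tc.lam:
            l = l + Tensor(tc.lam) * model.l2()
        opt.zero_grad()
        l.backward()
        opt.step()
    return model(Tensor(flat[evals]), training=False).data


def _gnn_only_forecast(panel: NodePanel, g: ZipGraph, split: TrainSplit,
                       cfg: BaselineConfig) -> np.ndarray:
    """Spatial module alone; future steps reuse nc(T) (features persist)."""
    tc = cfg.train
    T, target_t = _target_step(panel, tc)
    rng = np.random.default_rng(tc.seed)
    K = np.asarray(split.K)
    evals = np.asarray(split.eval_set)
    ms = SpatialModule(panel.n_features, cfg.spatial, rng)
    opt = Adam(ms.parameters(), lr=tc.lr, weight_decay=tc.weight_decay)
    accumulate = tc.ms_update == "accumulate"
    from .nn import mape_loss
    nc_seq = panel.nc[:, :, :T].transpose(2, 0, 1)
    h_TK = panel.h[K, :T].T
    sel = np.nonzero(panel.mask[K, :T].T)
    tail_start = tc.epochs - int(tc.tail_average * tc.epochs) \
        if tc.tail_average > 0 else tc.epochs
    n_avg = 0
    avg = [p_.data.copy() * 0 for p_ in ms.parameters()]
    for ep in range(tc.epochs):
        if accumulate:
            out = ms.forward_sequence(nc_seq, g, training=True, rng=rng)
            l = mape_loss(h_TK[sel], out[:, K][sel], eps=tc.mape_eps)
            if tc.lam:
                l = l + Tensor(tc.lam) * ms.l2()
            opt.zero_grad()
            l.backward()
            opt.step()
        else:
            for t in range(T):
                obs = panel.mask[K, t]
                if not obs.any():
                    continue
                yhat = ms(panel.nc[:, :, t], g, training=True, rng=rng)
                l = loss1(panel.h[K[obs], t], yhat[K[obs]], tc.lam, ms,
                          eps=tc.mape_eps)
                opt.zero_grad()
                l.backward()
                opt.step()
        if ep >= tail_start:
            n_avg += 1
            for slot, p_ in zip(avg, ms.parameters()):
                slot += (p_.data - slot) / n_avg
    if n_avg > 0:
        ms.load_state_dict(avg)
    return ms(panel.nc[:, :, T - 1], g, training=False).data[evals]


def _lstm_only_forecast(panel: NodePanel, split: TrainSplit,
                        cfg: BaselineConfig) -> np.ndarray:
    """Temporal module on raw h series; eval uses eval nodes' own history."""
    tc = cfg.train
    T, target_t = _target_step(panel, tc)
    rng = np.random.default_rng(tc.seed)
    K = np.asarray(split.K)
    evals = np.asarray(split.eval_set)
    mt = TemporalModule(cfg.temporal, rng)
    opt = Adam(mt.parameters(), lr=tc.lr, weight_decay=tc.weight_decay)
    batch = SequenceBatch(panel.h[K, :T], panel.h[K, :T], panel.mask[K, :T])
    tail_start = tc.epochs - int(tc.tail_average * tc.epochs) \
        if tc.tail_average > 0 else tc.epochs
    n_avg = 0
    avg = [p_.data.copy() * 0 for p_ in mt.parameters()]
    for ep in range(tc.epochs):
        out = mt(batch.inputs, training=True, rng=rng)
        l = loss2(batch, out, tc.lam, mt, alignment=cfg.temporal.alignment,
                  eps=tc.mape_eps)
        opt.zero_grad()
        l.backward()
        opt.step()
        if ep >= tail_start:
            n_avg += 1
            for slot, p_ in zip(avg, mt.parameters()):
                slot += (p_.data - slot) / n_avg
    if n_avg > 0:
        mt.load_state_dict(avg)
    return forecast(panel.h[evals, :T], mt, horizon=tc.horizon)[:, -1]


def baseline_forecast(name: str, panel: NodePanel, g: ZipGraph,
                      split: TrainSplit,
                      cfg: BaselineConfig | None = None) -> np.ndarray:
    """Forecast h(target step) for the eval nodes with a named baseline."""
    cfg = cfg or BaselineConfig()
    if name == "lrn":
        return lrn_fit_predict(panel, g, split, cfg.train)
    if name == "mlp":
        return _mlp_forecast(panel, split, cfg)
    if name == "gnn_only":
        return _gnn_only_forecast(panel, g, split, cfg)
    if name == "lstm_only":
        return _lstm_only_forecast(panel, split, cfg)
    if name in {"gnn_gru", "gcn_lstm"}:
        spatial = cfg.spatial
        temporal = cfg.temporal
        if name == "gnn_gru":
            temporal = TemporalConfig(**{**temporal.__dict__, "cell": "gru"})
        else:
            spatial = SpatialConfig(**{**spatial.__dict__, "conv": "gcn"})
        res = HesitancySTL(panel, g, split, spatial=spatial,
                           temporal=temporal, train=cfg.train).fit()
        return res.predict(split.eval_set, horizon=cfg.train.horizon)[:, -1]
    raise ValueError(f"unknown baseline {name!r}")


def evaluate_baseline(name: str, panel: NodePanel, g: ZipGraph,
                      split: TrainSplit,
                      cfg: BaselineConfig | None = None) -> MetricReport:
    cfg = cfg or BaselineConfig()
    _, target_t = _target_step(panel, cfg.train)
    preds = baseline_forecast(name, panel, g, split, cfg)
    evals = np.asarray(split.eval_set)
    obs = panel.mask[evals, target_t]
    return metrics(panel.h[evals[obs], target_t], np.asarray(preds)[obs])
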