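"""The spatio-temporal hesitancy model and its fitted results.

`HesitancySTL` couples the spatial learner (stacked GraphConv over the ZIP
graph, one shared module applied at every timestep) with the temporal
learner (per-node LSTM over the spatial outputs). The two modules are
trained with *separate* Adam optimizers on separate MAPE + L2 losses: each
training step loops over timesteps updating the spatial module against
h_K(t), then runs the temporal module over the (detached) spatial output
series and updates it against the one-step-shifted targets. No gradient
flows between the modules.

Evaluation is cold-start: hesitancy of evaluation nodes is never read.
Their features participate in full-graph message passing at every step,
the temporal module rolls their y_hat series forward, and the output at
the final step is the forecast for T+1 (closed-loop autoregression for
longer horizons).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .graphs import ZipGraph
from .metrics import MetricReport, metrics
from .nn import Adam
from .panel import NodePanel
from .spatial import SpatialConfig, SpatialModule, loss1
from .temporal import (SequenceBatch, TemporalConfig, TemporalModule, forecast,
                       loss2)

__all__ = ["TrainConfig", "TrainSplit", "HesitancySTL", "HesitancySTLResults",
           "train_hesitancy_stl", "predict_hesitancy", "run_experiment"]


@dataclass
class TrainConfig:
    lr: float = 5e-4
    weight_decay: float = 5e-4
    epochs: int = 15000              # desk-scale runs use far fewer
    lam: float = 0.0                 # explicit L2 term inside the losses
    seed: int = 0
    T: int | None = None             # last training timestep (index, exclusive bound TS-1)
    horizon: int = 1                 # target step is T + horizon
    mape_eps: float = 1e-2           # |y| floor in the *training* MAPE
    ms_update: str = "accumulate"    # batch-gradient: one Adam step per epoch
                                     # over the mean of per-timestep losses;
                                     # "per_step" updates after every t
    tail_average: float = 0.25       # Polyak-average parameters over the
                                     # final fraction of epochs (0 disables)

    def __post_init__(self):
        if self.lr < 0 or self.epochs < 1 or self.horizon < 1:
            raise ValueError("invalid training configuration")


@dataclass
class TrainSplit:
    """Labeled node set K and the held-out evaluation set V - K."""

    K: list[int]
    eval_set: list[int]

    def __post_init__(self):
        if not self.K:
            raise ValueError("labeled set K must be nonempty")
        if set(self.K) & set(self.eval_set):
            raise ValueError("K and eval_set must be disjoint")

    @classmethod
    def random(cls, n_nodes: int, frac_labeled: float,
               seed: int) -> "TrainSplit":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n_nodes)
        k = max(1, int(round(frac_labeled * n_nodes)))
        return cls(sorted(int(i) for i in perm[:k]),
                   sorted(int(i) for i in perm[k:]))


class HesitancySTL:
    """Spatio-temporal hesitancy forecaster (unfitted model object).

    Parameters
    ----------
    panel : NodePanel
        Normalized feature/target panel. The feature tensor must not
        contain the target series (cold-start contract).
    graph : ZipGraph
        Normalized ZIP graph sharing the panel's node ordering.
    split : TrainSplit
        Labeled node indices K and evaluation indices.
    spatial, temporal, train : configs with the field defaults.
    """

    def __init__(self, panel: NodePanel, graph: ZipGraph, split: TrainSplit,
                 spatial: SpatialConfig | None = None,
                 temporal: TemporalConfig | None = None,
                 train: TrainConfig | None = None):
        if panel.n_nodes != graph.n_nodes:
            raise ValueError("panel and graph node counts differ")
        if panel.zips != graph.zips:
            raise ValueError("panel and graph ZIP orderings differ")
        self.panel = panel
        self.graph = graph
        self.split = split
        self.spatial_cfg = spatial or SpatialConfig()
        self.temporal_cfg = temporal or TemporalConfig()
        self.train_cfg = train or TrainConfig()
        T = self.train_cfg.T
        if T is None:
            T = panel.n_timesteps - self.train_cfg.horizon
        if not 2 <= T <= panel.n_timesteps - 1:
            raise ValueError(f"invalid last training timestep T={T}")
        self.T = T

    # ------------------------------------------------------------------
    def fit(self, callback=None) -> "HesitancySTLResults":
        """Run the alternating two-optimizer training loop."""
        cfg = self.train_cfg
        rng = np.random.default_rng(cfg.seed)
        K = np.asarray(self.split.K)
        panel, g = self.panel, self.graph

        ms = SpatialModule(panel.n_features, self.spatial_cfg, rng)
        mt = TemporalModule(self.temporal_cfg, rng)
        opt_s = Adam(ms.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
        opt_t = Adam(mt.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)

        from .nn import Tensor, mape_loss
        accumulate = cfg.ms_update == "accumulate"
        nc_seq = panel.nc[:, :, :self.T].transpose(2, 0, 1)   # [T, N, X]
        h_TK = panel.h[K, :self.T].T                          # [T, |K|]
        mask_TK = panel.mask[K, :self.T].T
        sel = np.nonzero(mask_TK)
        if sel[0].size == 0:
            raise ValueError("no observed labeled cells to train on")
        tail_start = cfg.epochs - int(cfg.tail_average * cfg.epochs) \
            if cfg.tail_average > 0 else cfg.epochs
        n_avg = 0
        avg_s = [p_.data.copy() * 0 for p_ in ms.parameters()]
        avg_t = [p_.data.copy() * 0 for p_ in mt.parameters()]
        trace1, trace2 = [], []
        for epoch in range(cfg.epochs):
            if accumulate:
                # batch gradient: one Adam step over all timesteps at once
                out = ms.forward_sequence(nc_seq, g, training=True, rng=rng)
                l1 = mape_loss(h_TK[sel], out[:, K][sel], eps=cfg.mape_eps)
                if cfg.lam:
                    l1 = l1 + Tensor(cfg.lam) * ms.l2()
                if not np.isfinite(l1.data):
                    raise FloatingPointError(f"loss1 diverged at epoch {epoch}")
                opt_s.zero_grad()
                l1.backward()
                opt_s.step()
                l1_sum = float(l1.data)
                train_mode_yhat = out.data[:, K].T    # [|K|, T]
            else:
                l1_sum = 0.0
                for t in range(self.T):
                    obs = panel.mask[K, t]
                    if not obs.any():
                        continue
                    yhat = ms(panel.nc[:, :, t], g, training=True, rng=rng)
                    l1 = loss1(panel.h[K[obs], t],
                               yhat[K][np.nonzero(obs)[0]],
                               cfg.lam, ms, eps=cfg.mape_eps)
                    if not np.isfinite(l1.data):
                        raise FloatingPointError(
                            f"loss1 diverged at epoch {epoch}, t={t}")
                    opt_s.zero_grad()
                    l1.backward()
                    opt_s.step()
                    l1_sum += float(l1.data) / self.T
            trace1.append(l1_sum)
            # detached input for M_t: the training-mode (dropout-active)
            # spatial outputs. The dropout noise keeps the temporal module
            # from calibrating to memorized in-sample estimates it will
            # never see for cold-start nodes.
            if accumulate:
                yhat_seq = train_mode_yhat
            else:
                yhat_seq = ms.forward_sequence(nc_seq, g, training=True,
                                               rng=rng).data[:, K].T

            batch = SequenceBatch(yhat_seq, panel.h[K, :self.T],
                                  panel.mask[K, :self.T])
            out = mt(batch.inputs, training=True, rng=rng)
            l2 = loss2(batch, out, cfg.lam, mt,
                       alignment=self.temporal_cfg.alignment,
                       eps=cfg.mape_eps)
            if not np.isfinite(l2.data):
                raise FloatingPointError(f"loss2 diverged at epoch {epoch}")
            opt_t.zero_grad()
            l2.backward()
            opt_t.step()
            trace2.append(float(l2.data))
            if epoch >= tail_start:
                n_avg += 1
                for avg, mod in ((avg_s, ms), (avg_t, mt)):
                    for slot, p_ in zip(avg, mod.parameters()):
                        slot += (p_.data - slot) / n_avg
            if callback is not None:
                callback(epoch, trace1[-1], trace2[-1])

        if n_avg > 0:
            ms.load_state_dict(avg_s)
            mt.load_state_dict(avg_t)
        return HesitancySTLResults(self, ms, mt,
                                   loss1_trace=np.array(trace1),
                                   loss2_trace=np.array(trace2))


class HesitancySTLResults:
    """Fitted model: forecasts, evaluation metrics and a summary table."""

    def __init__(self, model: HesitancySTL, ms: SpatialModule,
                 mt: TemporalModule, loss1_trace: np.ndarray,
                 loss2_trace: np.ndarray):
        self.model = model
        self.ms = ms
        self.mt = mt
        self.loss1_trace = loss1_trace
        self.loss2_trace = loss2_trace

    # ------------------------------------------------------------------
    def spatial_outputs(self) -> np.ndarray:
        """Deterministic y_hat for all nodes and training timesteps [N, T]."""
        panel, g = self.model.panel, self.model.graph
        out = np.empty((panel.n_nodes, self.model.T))
        for t in range(self.model.T):
            out[:, t] = self.ms(panel.nc[:, :, t], g, training=False).data
        return out

    def predict(self, nodes: list[int] | np.ndarray | None = None,
                horizon: int = 1) -> np.ndarray:
        """Forecast h(T+1 .. T+horizon) for `nodes` (default: eval set).

        Cold-start: only features of the requested nodes are read; message
        passing uses the full graph so neighbours inform the estimates.
        """
        if horizon > max(self.model.train_cfg.horizon, 1) and \
                horizon > self.model.panel.n_timesteps - self.model.T:
            raise ValueError(f"horizon {horizon} beyond configured range")
        if nodes is None:
            nodes = self.model.split.eval_set
        nodes = np.asarray(nodes)
        yhat = self.spatial_outputs()
        return forecast(yhat[nodes], self.mt, horizon=horizon)

    def evaluate(self, nodes=None, horizon: int = 1) -> MetricReport:
        """Metrics at the target step T + horizon over observed cells."""
        panel = self.model.panel
        if nodes is None:
            nodes = self.model.split.eval_set
        nodes = np.asarray(nodes)
        target_t = self.model.T + horizon - 1
        if target_t >= panel.n_timesteps:
            raise ValueError("target step beyond panel")
        preds = self.predict(nodes, horizon=horizon)[:, -1]
        obs = panel.mask[nodes, target_t]
        return metrics(panel.h[nodes[obs], target_t], preds[obs])

    def summary(self, horizon: int = 1) -> str:
        rep = self.evaluate(horizon=horizon)
        m = self.model
        lines = [
            "Spatio-Temporal Hesitancy Model Results",
            "=" * 47,
            f"nodes: {m.panel.n_nodes}   labeled |K|: {len(m.split.K)}"
            f"   eval: {len(m.split.eval_set)}",
            f"timesteps: {m.panel.n_timesteps}   last training step T: {m.T}"
            f"   target: T+{horizon}",
            f"spatial: {m.spatial_cfg.n_layers} x GraphConv({m.spatial_cfg.hidden})"
            f"   temporal: {m.temporal_cfg.cell.upper()}({m.temporal_cfg.hidden})",
            f"epochs: {m.train_cfg.epochs}   lr: {m.train_cfg.lr}"
            f"   weight_decay: {m.train_cfg.weight_decay}   seed: {m.train_cfg.seed}",
            f"final loss1: {self.loss1_trace[-1]:.5f}"
            f"   final loss2: {self.loss2_trace[-1]:.5f}",
            "-" * 47,
            f"eval MAPE: {rep.mape:.4f}   MAE: {rep.mae:.4f}   MSE: {rep.mse:.5f}",
            f"eval RMSE: {rep.rmse:.4f}   R2: {rep.r2:.4f}   n: {rep.n_eval}",
        ]
        return "\n".join(lines)

    # ---- checkpointing -------------------------------------------------
    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        state = {"spatial": [a.tolist() for a in self.ms.state_dict()],
                 "temporal": [a.tolist() for a in self.mt.state_dict()]}
        (outdir / "checkpoint.json").write_text(json.dumps(state))
        cfg = {"spatial": asdict(self.model.spatial_cfg),
               "temporal": asdict(self.model.temporal_cfg),
               "train": asdict(self.model.train_cfg), "T": self.model.T,
               "split": asdict(self.model.split)}
        (outdir / "config.json").write_text(json.dumps(cfg))


# ---- spec-surface convenience functions --------------------------------

def train_hesitancy_stl(panel: NodePanel, g: ZipGraph, split: TrainSplit,
                    cfg: TrainConfig, spatial: SpatialConfig | None = None,
                    temporal: TemporalConfig | None = None) -> HesitancySTLResults:
    return HesitancySTL(panel, g, split, spatial=spatial, temporal=temporal,
                        train=cfg).fit()


def predict_hesitancy(results: HesitancySTLResults, nodes, horizon: int = 1
                      ) -> np.ndarray:
    return results.predict(nodes, horizon=horizon)


def run_experiment(panel: NodePanel, g: ZipGraph, split: TrainSplit,
                   cfg: TrainConfig, spatial: SpatialConfig | None = None,
                   temporal: TemporalConfig | None = None,
                   outdir: str | Path | None = None) -> dict:
    """Train, evaluate and (optionally) write a JSON + CSV report."""
    res = train_hesitancy_stl(panel, g, split, cfg, spatial, temporal)
    rep = res.evaluate(horizon=cfg.horizon)
    cfg_blob = json.dumps({"spatial": asdict(spatial or SpatialConfig()),
                           "temporal": asdict(temporal or TemporalConfig()),
                           "train": asdict(cfg)}, sort_keys=True)
    report = {
        "metrics": rep.as_dict(),
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(cfg_blob.encode()).hexdigest()[:16],
        "final_loss1": float(res.loss1_trace[-1]),
        "final_loss2": float(res.loss2_trace[-1]),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        nodes = np.asarray(split.eval_set)
        preds = res.predict(nodes, horizon=cfg.horizon)[:, -1]
        pd.DataFrame({"zip": [panel.zips[i] for i in nodes],
                      "prediction": preds}).to_csv(
            outdir / "predictions.csv", index=False)
        res.save(outdir / "model")
    return report
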