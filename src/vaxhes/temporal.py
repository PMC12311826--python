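"""Temporal learner M_t: per-node LSTM over the spatial outputs.

The module consumes each node's scalar series y_hat(1..T) and emits an
output o(t) at every input step. Under the one-step-ahead alignment used
for training and forecasting, o(t) is the prediction of h(t+1), so the
output at the final observed step is a genuine forecast of the next
quarter. Nodes are processed as independent rows of a batch; no information
flows between nodes inside this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import GRU, LSTM, Linear, Module, Tensor, dropout, mape_loss

__all__ = ["TemporalConfig", "TemporalModule", "SequenceBatch", "loss2", "forecast"]


@dataclass
class TemporalConfig:
    hidden: int = 32
    n_layers: int = 1
    dropout_rate: float = 0.5
    horizon: int = 1
    cell: str = "lstm"               # or "gru" (baseline variant)
    alignment: str = "shifted"       # o(t) predicts h(t+1); or "reconstruction"
    residual: bool = True            # o(t) = input(t) + learned correction

    def __post_init__(self):
        if self.hidden < 1 or self.horizon < 1 or self.n_layers < 1:
            raise ValueError("hidden, n_layers and horizon must be >= 1")


@dataclass
class SequenceBatch:
    """Per-node scalar input series with targets and an observation mask."""

    inputs: np.ndarray               # [N, TS] scalar series (y_hat)
    targets: np.ndarray              # [N, TS] observed h
    mask: np.ndarray                 # [N, TS] True where observed

    def __post_init__(self):
        self.inputs = np.asarray(self.inputs, dtype=np.float64)
        self.targets = np.asarray(self.targets, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.inputs.shape == self.targets.shape == self.mask.shape):
            raise ValueError("inputs/targets/mask shapes differ")


class TemporalModule(Module):
    def __init__(self, cfg: TemporalConfig, rng: np.random.Generator,
                 d_in: int = 1):
        self.cfg = cfg
        cell_cls = LSTM if cfg.cell == "lstm" else GRU
        self.cells = [cell_cls(d_in if i == 0 else cfg.hidden, cfg.hidden, rng)
                      for i in range(cfg.n_layers)]
        self.head = Linear(cfg.hidden, 1, rng)

    def __call__(self, inputs: np.ndarray, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        """Map [N, TS] scalar series to [N, TS] outputs o(t)."""
        inputs = np.asarray(inputs, dtype=np.float64)
        if inputs.ndim != 2 or inputs.shape[1] < 2:
            raise ValueError("need a [N, TS] series with TS >= 2")
        raw = [Tensor(inputs[:, t:t + 1]) for t in range(inputs.shape[1])]
        xs = raw
        for cell in self.cells:
            xs = cell(xs)
            if training and self.cfg.dropout_rate > 0:
                if rng is None:
                    raise ValueError("training-mode dropout needs an rng")
                xs = [dropout(x, self.cfg.dropout_rate, rng, True) for x in xs]
        if self.cfg.residual:
            # the recurrent stack learns a correction to the input series,
            # so an untrained module behaves like persistence
            cols = [r + self.head(x) for r, x in zip(raw, xs)]
        else:
            cols = [self.head(x) for x in xs]
        from .nn import concat
        return concat(cols, axis=1)


def loss2(batch: SequenceBatch, outputs: Tensor, lam: float,
          model: TemporalModule, alignment: str = "shifted",
          eps: float | None = None) -> Tensor:
    """MAPE over aligned, unmasked (target, output) pairs + lambda * L2.

    shifted: o(t) vs h(t+1) for t = 1..TS-1 (a pair is used when h(t+1) is
    observed); reconstruction: o(t) vs h(t) at every observed step.
    """
    if alignment == "shifted":
        pred = outputs[:, :-1]
        true = batch.targets[:, 1:]
        m = batch.mask[:, 1:]
    elif alignment == "reconstruction":
        pred, true, m = outputs, batch.targets, batch.mask
    else:
        raise ValueError(f"unknown alignment {alignment!r}")
    if not m.any():
        raise ValueError("no unmasked aligned pairs for loss2")
    from .nn import EPS_MAPE
    rows, cols = np.nonzero(m)
    out = mape_loss(true[rows, cols], pred[rows, cols],
                    eps=EPS_MAPE if eps is None else eps)
    if lam:
        out = out + Tensor(lam) * model.l2()
    return out


def forecast(inputs: np.ndarray, model: TemporalModule,
             horizon: int = 1) -> np.ndarray:
    """Forecast h(T+1 .. T+horizon) for each node from y_hat(1..T).

    horizon 1 reads the output at the final input step; larger horizons
    roll the model forward closed-loop, feeding each prediction back in as
    the next input.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    series = np.asarray(inputs, dtype=np.float64).copy()
    preds = np.empty((series.shape[0], horizon))
    for step in range(horizon):
        out = model(series, training=False)
        preds[:, step] = out.data[:, -1]
        if step < horizon - 1:
            series = np.concatenate([series, preds[:, step:step + 1]], axis=1)
    return preds
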