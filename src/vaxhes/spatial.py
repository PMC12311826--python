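"""Spatial learner M_s: stacked GraphConv layers with a linear head.

One forward pass maps the feature matrix of a single timestep, nc(t) with
shape [N, X], to a per-node hesitancy estimate y_hat(t). Message passing is
order-1 Weisfeiler–Leman: each layer combines a node's own features with
the weighted sum of its neighbours' features, so a node with no neighbours
depends only on itself and the whole map is permutation-equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphs import ZipGraph
from .nn import GCNConv, GraphConv, Linear, Module, Tensor, dropout, mape_loss

__all__ = ["SpatialConfig", "SpatialModule", "loss1"]


@dataclass
class SpatialConfig:
    n_layers: int = 2
    hidden: int = 256
    dropout_rate: float = 0.5
    k: int = 1                       # order of the WL message passing
    activation: str = "relu"
    conv: str = "graphconv"          # or "gcn" (shared self/neighbour weights)

    def __post_init__(self):
        if self.n_layers < 1 or self.hidden < 1:
            raise ValueError("n_layers and hidden must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.k != 1:
            raise ValueError("only k=1 message passing is implemented")


class SpatialModule(Module):
    def __init__(self, d_in: int, cfg: SpatialConfig, rng: np.random.Generator):
        self.cfg = cfg
        conv_cls = GraphConv if cfg.conv == "graphconv" else GCNConv
        dims = [d_in] + [cfg.hidden] * cfg.n_layers
        self.layers = [conv_cls(dims[i], dims[i + 1], rng)
                       for i in range(cfg.n_layers)]
        self.head = Linear(cfg.hidden, 1, rng)

    def __call__(self, nc_t: np.ndarray, g: ZipGraph, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        """Return y_hat(t) as a Tensor of shape [N]."""
        if nc_t.shape[0] != g.n_nodes:
            raise ValueError(
                f"feature rows {nc_t.shape[0]} != graph nodes {g.n_nodes}")
        W = g.W if self.cfg.conv == "graphconv" \
            else GCNConv.normalize_adjacency(g.W)
        x = Tensor(np.asarray(nc_t, dtype=np.float64))
        for li, layer in enumerate(self.layers):
            x = layer(x, W)
            # activation + dropout between conv layers, none after the last
            if li < len(self.layers) - 1:
                x = x.relu()
                if training and self.cfg.dropout_rate > 0:
                    if rng is None:
                        raise ValueError("training-mode dropout needs an rng")
                    x = dropout(x, self.cfg.dropout_rate, rng, training=True)
        return self.head(x).reshape(-1)

    def forward_sequence(self, nc_seq: np.ndarray, g: ZipGraph,
                         training: bool = False,
                         rng: np.random.Generator | None = None) -> Tensor:
        """Batched forward over all timesteps: [T, N, X] -> [T, N].

        Equivalent to calling the module once per timestep; one broadcast
        matmul per layer keeps training loops fast.
        """
        nc_seq = np.asarray(nc_seq, dtype=np.float64)
        if nc_seq.shape[1] != g.n_nodes:
            raise ValueError("node dimension mismatch with graph")
        W = g.W if self.cfg.conv == "graphconv" \
            else GCNConv.normalize_adjacency(g.W)
        x = Tensor(nc_seq)
        for li, layer in enumerate(self.layers):
            x = layer(x, W)
            if li < len(self.layers) - 1:
                x = x.relu()
                if training and self.cfg.dropout_rate > 0:
                    if rng is None:
                        raise ValueError("training-mode dropout needs an rng")
                    x = dropout(x, self.cfg.dropout_rate, rng, training=True)
        out = self.head(x)
        return out.reshape(nc_seq.shape[0], nc_seq.shape[1])


def loss1(y_true: np.ndarray, y_pred: Tensor, lam: float,
          model: SpatialModule, eps: float | None = None) -> Tensor:
    """MAPE over labeled nodes plus lambda * L2 on the spatial parameters.

    `eps` floors |y_true| in the MAPE denominator (default EPS_MAPE); a
    larger training floor keeps near-zero hesitancy cells from dominating
    the gradient.
    """
    from .nn import EPS_MAPE
    y_true = np.asarray(y_true, dtype=np.float64)
    if y_true.size == 0:
        raise ValueError("loss1 over an empty labeled set")
    out = mape_loss(y_true, y_pred, eps=EPS_MAPE if eps is None else eps)
    if lam:
        out = out + Tensor(lam) * model.l2()
    return out
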