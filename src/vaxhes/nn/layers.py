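"""Neural layers used by the spatial and temporal learners.

All layers hold :class:`~vaxhes.nn.autodiff.Tensor` parameters initialised
from a caller-supplied :class:`numpy.random.Generator`, so a single seed
makes every model build (and hence every training run) reproducible.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

__all__ = ["Module", "Linear", "GraphConv", "GCNConv", "LSTM", "GRU", "dropout"]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Module:
    """Base class: parameter collection and L2 penalty."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def l2(self) -> Tensor:
        total = Tensor(0.0)
        for p in self.parameters():
            total = total + (p * p).sum()
        return total

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state size mismatch")
        for p, arr in zip(params, state):
            p.data = np.asarray(arr, dtype=np.float64).reshape(p.data.shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Tensor(_glorot(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class GraphConv(Module):
    """Order-1 Weisfeiler–Leman message passing (k-GNN with k=1).

    out_i = W_self x_i + W_neigh * sum_j w(i,j) x_j + b, with the weighted
    adjacency supplied as a dense constant matrix at call time.
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W_self = Tensor(_glorot(rng, d_in, d_out), requires_grad=True)
        self.W_neigh = Tensor(_glorot(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor, W: np.ndarray) -> Tensor:
        agg = Tensor(W) @ x
        return x @ self.W_self + agg @ self.W_neigh + self.b


class GCNConv(Module):
    """Spectral-style convolution: D̃^(-1/2) (W+I) D̃^(-1/2) X Θ.

    Self-connections and neighbour edges share one weight matrix, the
    key contrast with :class:`GraphConv`.
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Tensor(_glorot(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    @staticmethod
    def normalize_adjacency(W: np.ndarray) -> np.ndarray:
        A = W + np.eye(W.shape[0])
        d = A.sum(axis=1)
        dinv = 1.0 / np.sqrt(d)
        return A * dinv[:, None] * dinv[None, :]

    def __call__(self, x: Tensor, W_hat: np.ndarray) -> Tensor:
        return (Tensor(W_hat) @ x) @ self.W + self.b


class LSTM(Module):
    """Single-layer LSTM over [N, TS, d_in]; returns hidden states [N, TS, H]."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.W = Tensor(_glorot(rng, d_in + hidden, 4 * hidden), requires_grad=True)
        self.b = Tensor(np.zeros(4 * hidden), requires_grad=True)
        # forget-gate bias at 1: standard trick for gradient flow early on
        self.b.data[hidden:2 * hidden] = 1.0

    def step(self, x_t: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        H = self.hidden
        z = concat([x_t, h], axis=1) @ self.W + self.b
        i = z[:, 0 * H:1 * H].sigmoid()
        f = z[:, 1 * H:2 * H].sigmoid()
        g = z[:, 2 * H:3 * H].tanh()
        o = z[:, 3 * H:4 * H].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new

    def __call__(self, xs: list[Tensor]) -> list[Tensor]:
        n = xs[0].shape[0]
        h = Tensor(np.zeros((n, self.hidden)))
        c = Tensor(np.zeros((n, self.hidden)))
        outs = []
        for x_t in xs:
            h, c = self.step(x_t, h, c)
            outs.append(h)
        return outs


class GRU(Module):
    """Single-layer GRU with the same calling convention as :class:`LSTM`."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.W_rz = Tensor(_glorot(rng, d_in + hidden, 2 * hidden), requires_grad=True)
        self.b_rz = Tensor(np.zeros(2 * hidden), requires_grad=True)
        self.W_n = Tensor(_glorot(rng, d_in + hidden, hidden), requires_grad=True)
        self.b_n = Tensor(np.zeros(hidden), requires_grad=True)

    def step(self, x_t: Tensor, h: Tensor) -> Tensor:
        H = self.hidden
        rz = concat([x_t, h], axis=1) @ self.W_rz + self.b_rz
        r = rz[:, :H].sigmoid()
        z = rz[:, H:].sigmoid()
        n = (concat([x_t, r * h], axis=1) @ self.W_n + self.b_n).tanh()
        return (Tensor(1.0) - z) * n + z * h

    def __call__(self, xs: list[Tensor]) -> list[Tensor]:
        n_rows = xs[0].shape[0]
        h = Tensor(np.zeros((n_rows, self.hidden)))
        outs = []
        for x_t in xs:
            h = self.step(x_t, h)
            outs.append(h)
        return outs


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)
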