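"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine supports exactly the operations the package's neural modules
need: affine maps, elementwise nonlinearities, masking, reductions and
slicing. Tensors wrap float64 arrays; calling :meth:`Tensor.backward` on a
scalar loss accumulates gradients into every upstream tensor created with
``requires_grad=True``. The graph is rebuilt on every forward pass (define-
by-run), which keeps recurrent models straightforward.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # ---- helpers -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += _unbroadcast(g, self.data.shape)

    # ---- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        out._backward = _backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        out._backward = _backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def _backward(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / other.data**2)

        out._backward = _backward
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))
        swap = lambda a: np.swapaxes(a, -1, -2)  # noqa: E731

        def _backward(g):
            # batched matmul: leading dims broadcast; _accum sums them out
            if self.requires_grad:
                self._accum(g @ swap(other.data))
            if other.requires_grad:
                other._accum(swap(self.data) @ g)

        out._backward = _backward
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * p * self.data ** (p - 1)
        )
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def _backward(g):
            if self.requires_grad:
                buf = np.zeros_like(self.data)
                np.add.at(buf, idx, g)
                self._accum(buf)

        out._backward = _backward
        return out

    # ---- nonlinearities ------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * (self.data > 0)
        )
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (1 - t**2))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * s * (1 - s))
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * np.sign(self.data)
        )
        return out

    # ---- reductions / shaping -----------------------------------------
    def sum(self):
        out = Tensor(self.data.sum(), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            np.broadcast_to(g, self.data.shape).copy()
        )
        return out

    def mean(self):
        n = self.data.size
        out = Tensor(self.data.mean(), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            np.broadcast_to(g / n, self.data.shape).copy()
        )
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g.reshape(self.data.shape)
        )
        return out

    # ---- graph traversal ----------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; recurrent graphs get deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = _backward
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))

    def _backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    out._backward = _backward
    return out
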