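"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for a small transformer encoder: broadcast-aware
elementwise arithmetic, batched matmul, ReLU/sigmoid/log, layer norm, masked
softmax, dropout, embedding-row gathering and reductions.  Everything runs in
float64 on a tape of ``Tensor`` nodes; ``backward()`` topologically sorts the
tape and accumulates gradients into leaf ``Parameter``s.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff tape."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in self._parents)

    @property
    def shape(self):
        return self.data.shape

    # -- graph traversal -------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    # -- operators -------------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul(_wrap(other), _wrap(-1.0)))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, _wrap(-1.0)))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, _wrap(-1.0))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.array(data, dtype=np.float64), requires_grad=True)

    def zero_grad(self):
        self.grad = None


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x) -> Tensor:
    return Tensor(np.asarray(x, dtype=np.float64))


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    out._backward = backward
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, (a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = backward
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, (a, b))

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))

    out._backward = backward
    return out


def relu(a: Tensor) -> Tensor:
    out = Tensor(np.maximum(a.data, 0.0), (a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (a.data > 0))

    out._backward = backward
    return out


def sigmoid(a: Tensor) -> Tensor:
    """Numerically stable logistic function e^x / (1 + e^x)."""
    x = a.data
    s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))), np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    out = Tensor(s, (a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * s * (1.0 - s))

    out._backward = backward
    return out


def log(a: Tensor) -> Tensor:
    out = Tensor(np.log(a.data), (a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    out._backward = backward
    return out


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    out = Tensor(np.clip(a.data, lo, hi), (a,))

    def backward(g):
        if a.requires_grad:
            inside = (a.data >= lo) & (a.data <= hi)
            a._accumulate(g * inside)

    out._backward = backward
    return out


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), (a,))

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    out._backward = backward
    return out


def reshape(a: Tensor, shape) -> Tensor:
    out = Tensor(a.data.reshape(shape), (a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    out._backward = backward
    return out


def transpose(a: Tensor, axes) -> Tensor:
    out = Tensor(np.transpose(a.data, axes), (a,))
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.transpose(g, inv))

    out._backward = backward
    return out


def gather_rows(table: Tensor, idx: np.ndarray) -> Tensor:
    """Embedding lookup: rows of ``table`` indexed by an integer array."""
    out = Tensor(table.data[idx], (table,))

    def backward(g):
        if table.requires_grad:
            grad = np.zeros_like(table.data)
            np.add.at(grad, idx.reshape(-1), g.reshape(-1, table.data.shape[-1]))
            table._accumulate(grad)

    out._backward = backward
    return out


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with learned gain and bias."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat * gain.data + bias.data, (x, gain, bias))

    def backward(g):
        if gain.requires_grad:
            gain._accumulate(_unbroadcast(g * xhat, gain.data.shape))
        if bias.requires_grad:
            bias._accumulate(_unbroadcast(g, bias.data.shape))
        if x.requires_grad:
            gx = g * gain.data
            gxc = gx * inv
            term2 = np.mean(gxc, axis=-1, keepdims=True)
            term3 = xhat * np.mean(gx * xhat * inv, axis=-1, keepdims=True)
            x._accumulate(gxc - term2 - term3)

    out._backward = backward
    return out


def masked_softmax(scores: Tensor, valid_mask: np.ndarray) -> Tensor:
    """Softmax over the last axis with invalid positions given weight 0.

    ``valid_mask`` broadcasts against ``scores``; positions where it is False
    receive exactly zero probability and propagate exactly zero gradient.
    """
    s = np.where(valid_mask, scores.data, -np.inf)
    s_max = np.max(s, axis=-1, keepdims=True)
    e = np.exp(s - s_max)
    p = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(p, (scores,))

    def backward(g):
        if scores.requires_grad:
            dot = np.sum(g * p, axis=-1, keepdims=True)
            scores._accumulate(p * (g - dot))

    out._backward = backward
    return out


def dropout(a: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity in evaluation mode or at rate 0."""
    if not training or rate == 0.0:
        return a
    keep = rng.random(a.data.shape) >= rate
    scale = 1.0 / (1.0 - rate)
    out = Tensor(a.data * keep * scale, (a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * keep * scale)

    out._backward = backward
    return out
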