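"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough operator coverage for an encoder-decoder transformer: broadcast
add/mul, batched matmul, reshape/transpose, relu, embedding lookup, layer
norm, softmax, dropout, and masked token-level cross-entropy.  Gradients are
accumulated by a topological backward pass; correctness is pinned by
finite-difference tests rather than by construction.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "_prev", "_backward")

    def __init__(self, data, prev=(), backward=None):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._prev = prev
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep for long sequences
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # convenience arithmetic
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data + b.data, (a, b))

    def backward(g):
        a._accum(_unbroadcast(g, a.shape))
        b._accum(_unbroadcast(g, b.shape))

    out._backward = backward
    return out


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data * b.data, (a, b))

    def backward(g):
        a._accum(_unbroadcast(g * b.data, a.shape))
        b._accum(_unbroadcast(g * a.data, b.shape))

    out._backward = backward
    return out


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(np.matmul(a.data, b.data), (a, b))

    def backward(g):
        ga = np.matmul(g, b.data.swapaxes(-1, -2))
        gb = np.matmul(a.data.swapaxes(-1, -2), g)
        a._accum(_unbroadcast(ga, a.shape))
        b._accum(_unbroadcast(gb, b.shape))

    out._backward = backward
    return out


def reshape(a: Tensor, shape) -> Tensor:
    a = _as_tensor(a)
    out = Tensor(a.data.reshape(shape), (a,))

    def backward(g):
        a._accum(g.reshape(a.shape))

    out._backward = backward
    return out


def transpose(a: Tensor, axes) -> Tensor:
    a = _as_tensor(a)
    out = Tensor(a.data.transpose(axes), (a,))
    inv = np.argsort(axes)

    def backward(g):
        a._accum(g.transpose(inv))

    out._backward = backward
    return out


def relu(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    out = Tensor(np.maximum(a.data, 0.0), (a,))

    def backward(g):
        a._accum(g * (a.data > 0))

    out._backward = backward
    return out


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``weight[ids]``; gradients scatter-add into the table."""
    out = Tensor(weight.data[ids], (weight,))

    def backward(g):
        if weight.grad is None:
            weight.grad = np.zeros_like(weight.data)
        np.add.at(weight.grad, ids, g)

    out._backward = backward
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(gamma.data * xhat + beta.data, (x, gamma, beta))

    def backward(g):
        d = x.data.shape[-1]
        dxhat = g * gamma.data
        dx = inv / d * (
            d * dxhat
            - dxhat.sum(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
        )
        x._accum(dx)
        reduce_axes = tuple(range(g.ndim - 1))
        gamma._accum((g * xhat).sum(axis=reduce_axes))
        beta._accum(g.sum(axis=reduce_axes))

    out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, (x,))

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accum(y * (g - dot))

    out._backward = backward
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, train: bool) -> Tensor:
    if not train or p <= 0.0:
        return x
    mask = ((rng.random(x.shape) >= p) / (1.0 - p)).astype(x.data.dtype)
    out = Tensor(x.data * mask, (x,))

    def backward(g):
        x._accum(g * mask)

    out._backward = backward
    return out


def cross_entropy(logits: Tensor, targets: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean negative log-likelihood per unmasked token.

    ``logits`` has shape (..., V); ``targets`` integer ids, ``mask`` 1.0 for
    tokens that count.  Returns a scalar Tensor.
    """
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - logsumexp
    picked = np.take_along_axis(logp, targets[..., None], axis=-1)[..., 0]
    denom = mask.sum()
    if denom <= 0:
        raise ValueError("cross_entropy mask selects no tokens")
    loss = -(picked * mask).sum() / denom
    out = Tensor(np.asarray(loss), (logits,))
    probs = np.exp(logp)

    def backward(g):
        grad = probs.copy()
        np.put_along_axis(
            grad, targets[..., None],
            np.take_along_axis(grad, targets[..., None], axis=-1) - 1.0, axis=-1,
        )
        grad *= (mask / denom)[..., None]
        logits._accum(g * grad)

    out._backward = backward
    return out
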