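"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package trains small transformer encoders on CPU; this module provides
the handful of differentiable operations those models need (dense algebra,
softmax, layer normalisation, embedding lookup, fused cross-entropy) with a
classic tape/topological-sort backward pass.  Arrays keep whatever dtype
they are given, so float64 can be used where tests compare against
high-precision oracles and float32 everywhere else.
"""

from __future__ import annotations

import math
from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction inside the block (teacher passes, inference)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An n-d array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=np.float64)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents = _parents if self.requires_grad or _parents else ()
        self._backward = _backward

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph machinery -----------------------------------------------------
    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    topo.append(n)
                    continue
                if id(n) in seen or not n.requires_grad:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    stack.append((p, False))

        visit(self)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data + other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))
        out._backward = bw if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data * other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            self._accumulate(g * p * self.data ** (p - 1))
        out._backward = bw if out.requires_grad else None
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bw if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), requires_grad=self.requires_grad,
                     _parents=(self,))

        def bw(g):
            self._accumulate(g.reshape(self.data.shape))
        out._backward = bw if out.requires_grad else None
        return out

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes), requires_grad=self.requires_grad,
                     _parents=(self,))
        inv = np.argsort(axes)

        def bw(g):
            self._accumulate(g.transpose(inv))
        out._backward = bw if out.requires_grad else None
        return out

    def swapaxes(self, a, b):
        axes = list(range(self.data.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(tuple(axes))

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)
        out._backward = bw if out.requires_grad else None
        return out

    # -- linear algebra --------------------------------------------------------
    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data),
                     requires_grad=self.requires_grad or other.requires_grad,
                     _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.data.shape))
        out._backward = bw if out.requires_grad else None
        return out

    # -- nonlinearities --------------------------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            self._accumulate(g * y)
        out._backward = bw if out.requires_grad else None
        return out

    def log(self):
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad,
                     _parents=(self,))

        def bw(g):
            self._accumulate(g / self.data)
        out._backward = bw if out.requires_grad else None
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            self._accumulate(g * (1.0 - y * y))
        out._backward = bw if out.requires_grad else None
        return out


_GELU_C = math.sqrt(2.0 / math.pi)


def gelu(x: Tensor) -> Tensor:
    """GELU with the standard tanh approximation."""
    d = x.data
    u = _GELU_C * (d + 0.044715 * d ** 3)
    t = np.tanh(u)
    y = 0.5 * d * (1.0 + t)
    out = Tensor(y, requires_grad=x.requires_grad, _parents=(x,))

    def bw(g):
        du = _GELU_C * (1.0 + 3 * 0.044715 * d ** 2)
        dy = 0.5 * (1.0 + t) + 0.5 * d * (1.0 - t * t) * du
        x._accumulate(g * dy)
    out._backward = bw if out.requires_grad else None
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, requires_grad=x.requires_grad, _parents=(x,))

    def bw(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accumulate(y * (g - dot))
    out._backward = bw if out.requires_grad else None
    return out


def layer_norm(x: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis with affine parameters."""
    d = x.data
    mu = d.mean(axis=-1, keepdims=True)
    xc = d - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    y = weight.data * xhat + bias.data
    rq = x.requires_grad or weight.requires_grad or bias.requires_grad
    out = Tensor(y, requires_grad=rq, _parents=(x, weight, bias))

    def bw(g):
        if weight.requires_grad:
            axes = tuple(range(g.ndim - 1))
            weight._accumulate((g * xhat).sum(axis=axes))
        if bias.requires_grad:
            axes = tuple(range(g.ndim - 1))
            bias._accumulate(g.sum(axis=axes))
        if x.requires_grad:
            gx = g * weight.data
            m1 = gx.mean(axis=-1, keepdims=True)
            m2 = (gx * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(inv * (gx - m1 - xhat * m2))
    out._backward = bw if out.requires_grad else None
    return out


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    ids = np.asarray(ids)
    out = Tensor(weight.data[ids], requires_grad=weight.requires_grad,
                 _parents=(weight,))

    def bw(g):
        gw = np.zeros_like(weight.data)
        np.add.at(gw, ids.reshape(-1), g.reshape(-1, g.shape[-1]))
        weight._accumulate(gw)
    out._backward = bw if out.requires_grad else None
    return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 requires_grad=any(t.requires_grad for t in tensors),
                 _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)
    out._backward = bw if out.requires_grad else None
    return out


def cross_entropy_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``targets`` under softmax of ``logits``.

    ``logits``: (M, V); ``targets``: (M,) int.  Fused for numerical stability.
    """
    targets = np.asarray(targets, dtype=np.int64)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - lse
    M = targets.shape[0]
    nll = -logp[np.arange(M), targets]
    out = Tensor(np.asarray(nll.mean(), dtype=logits.data.dtype),
                 requires_grad=logits.requires_grad, _parents=(logits,))

    def bw(g):
        p = np.exp(logp)
        p[np.arange(M), targets] -= 1.0
        logits._accumulate(g * p / M)
    out._backward = bw if out.requires_grad else None
    return out


def row_scatter(base: Tensor, batch_idx: np.ndarray, row_idx: np.ndarray,
                src: Tensor) -> Tensor:
    """Return ``base`` with rows at ``[batch_idx, row_idx]`` replaced by ``src``.

    ``base``: (B, S, D); ``src``: rows matching the index arrays.  Used to place
    visible-token features among mask tokens in the reconstruction decoder.
    """
    src = Tensor.as_tensor(src)
    data = base.data.copy()
    data[batch_idx, row_idx] = src.data
    out = Tensor(data, requires_grad=base.requires_grad or src.requires_grad,
                 _parents=(base, src))

    def bw(g):
        if base.requires_grad:
            gb = g.copy()
            gb[batch_idx, row_idx] = 0.0
            base._accumulate(gb)
        if src.requires_grad:
            src._accumulate(g[batch_idx, row_idx])
    out._backward = bw if out.requires_grad else None
    return out


def mse(a: Tensor, b: Tensor) -> Tensor:
    """Mean squared error over all elements."""
    a = Tensor.as_tensor(a)
    b = Tensor.as_tensor(b)
    diff = a - b
    return (diff * diff).mean()
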