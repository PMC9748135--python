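"""Minimal reverse-mode automatic differentiation over numpy arrays.

A tape-based engine providing exactly the operations the ZINB autoencoder and
its losses need: broadcasting arithmetic, matmul, reductions, elementwise
transcendentals (including log-gamma, whose gradient is the digamma function),
ELU/sigmoid activations, concatenation and an axis-wise max. Gradients are
accumulated by topologically-ordered backward passes.

Arrays are kept in float32 by default; callers that need float64 can pass it.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, dtype=DTYPE):
        self.data = np.asarray(data, dtype=dtype)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # ---- graph plumbing ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False, dtype=self.data.dtype)

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if not self.requires_grad and self._backward is None:
            return
        self.grad = g if self.grad is None else self.grad + g

    # ---- helpers -------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, dtype=data.dtype)
        if any(p.requires_grad or p._backward is not None for p in parents):
            out._parents = parents
            out._backward = backward
            out.requires_grad = True
        return out

    # ---- arithmetic ----------------------------------------------------
    def __add__(self, other):
        o = self._wrap(other)
        out_data = self.data + o.data

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            o._accum(_unbroadcast(g, o.data.shape))

        return self._make(out_data, (self, o), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        o = self._wrap(other)
        out_data = self.data * o.data

        def backward(g):
            self._accum(_unbroadcast(g * o.data, self.data.shape))
            o._accum(_unbroadcast(g * self.data, o.data.shape))

        return self._make(out_data, (self, o), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._wrap(other)
        out_data = self.data / o.data

        def backward(g):
            self._accum(_unbroadcast(g / o.data, self.data.shape))
            o._accum(_unbroadcast(-g * self.data / (o.data ** 2), o.data.shape))

        return self._make(out_data, (self, o), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), backward)

    def matmul(self, other):
        o = self._wrap(other)
        out_data = self.data @ o.data

        def backward(g):
            self._accum(g @ o.data.T)
            o._accum(self.data.T @ g)

        return self._make(out_data, (self, o), backward)

    __matmul__ = matmul

    # ---- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(np.asarray(out_data, dtype=self.data.dtype), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int):
        """Max along an axis; gradient flows to the (first) argmax entries."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis).squeeze(axis)

        def backward(g):
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis=axis)
            self._accum(full)

        return self._make(out_data, (self,), backward)

    def transpose2(self):
        """2-D transpose."""
        def backward(g):
            self._accum(g.T)

        return self._make(self.data.T.copy(), (self,), backward)

    # ---- elementwise transcendentals -----------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            self._accum(g / self.data)

        return self._make(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g * 0.5 / np.maximum(out_data, 1e-12))

        return self._make(out_data, (self,), backward)

    def lgamma(self):
        out_data = _sp.gammaln(self.data).astype(self.data.dtype)

        def backward(g):
            self._accum(g * _sp.digamma(self.data).astype(self.data.dtype))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = _sp.expit(self.data)

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def elu(self, alpha: float = 1.0):
        neg = self.data < 0
        out_data = np.where(neg, alpha * np.expm1(self.data), self.data)

        def backward(g):
            self._accum(g * np.where(neg, out_data + alpha, 1.0))

        return self._make(out_data.astype(self.data.dtype), (self,), backward)

    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            self._accum(g * mask)

        return self._make(out_data, (self,), backward)

    def clamp(self, lo=None, hi=None):
        """Clip values; gradient is zero outside [lo, hi] (hard clip)."""
        out_data = np.clip(self.data, lo, hi)
        inside = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            inside &= self.data >= lo
        if hi is not None:
            inside &= self.data <= hi

        def backward(g):
            self._accum(g * inside)

        return self._make(out_data, (self,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    out = Tensor(out_data, dtype=out_data.dtype)
    if any(t.requires_grad or t._backward is not None for t in tensors):
        out._parents = tuple(tensors)
        out._backward = backward
        out.requires_grad = True
    return out


def maximum(a, b) -> Tensor:
    """Elementwise maximum; gradient to the winning side (ties to `a`)."""
    a, b = Tensor._wrap(a), Tensor._wrap(b)
    take_a = a.data >= b.data
    out_data = np.where(take_a, a.data, b.data)

    def backward(g):
        a._accum(_unbroadcast(g * take_a, a.data.shape))
        b._accum(_unbroadcast(g * ~take_a, b.data.shape))

    out = Tensor(out_data, dtype=out_data.dtype)
    if any(t.requires_grad or t._backward is not None for t in (a, b)):
        out._parents = (a, b)
        out._backward = backward
        out.requires_grad = True
    return out


def parameter(data, dtype=DTYPE) -> Tensor:
    return Tensor(np.asarray(data, dtype=dtype), requires_grad=True, dtype=dtype)
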