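"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the point network needs: broadcast
arithmetic, batched matmul, elementwise nonlinearities, axis reductions
(sum/mean/max), concatenation, reshape/transpose, point gathering, and a
pass-through clip. Gradients are accumulated by topological-order backward
passes; correctness is checked against central differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "cat", "gather_points"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = self._make(self.data + other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out = self._make(self.data * other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** (-1.0)

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** (-1.0)

    def __pow__(self, exponent: float):
        out = self._make(self.data ** exponent, (self,), None)

        def bw(g):
            self._accum(_unbroadcast(
                g * exponent * self.data ** (exponent - 1), self.data.shape))
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = self._make(self.data @ other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))
        out._backward = bw
        return out

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = self._make(np.where(mask, self.data, 0.0), (self,), None)
        out._backward = lambda g: self._accum(g * mask)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = self._make(s, (self,), None)
        out._backward = lambda g: self._accum(g * s * (1 - s))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = self._make(e, (self,), None)
        out._backward = lambda g: self._accum(g * e)
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through unchanged inside the range."""
        mask = (self.data >= lo) & (self.data <= hi)
        out = self._make(np.clip(self.data, lo, hi), (self,), None)
        out._backward = lambda g: self._accum(g * mask)
        return out

    # -- reductions & shaping ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims=False):
        idx = np.argmax(self.data, axis=axis)
        val = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        out_data = val if keepdims else np.squeeze(val, axis=axis)
        out = self._make(out_data, (self,), None)

        def bw(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            gx = np.zeros_like(self.data)
            np.put_along_axis(gx, np.expand_dims(idx, axis), g, axis=axis)
            self._accum(gx)
        out._backward = bw
        return out

    def reshape(self, *shape):
        out = self._make(self.data.reshape(*shape), (self,), None)
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        out = self._make(self.data.transpose(*axes), (self,), None)
        inv = np.argsort(axes)
        out._backward = lambda g: self._accum(g.transpose(*inv))
        return out


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def cat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            for t, gs in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(gs)
        out._backward = bw
    return out


def gather_points(features: Tensor, index: np.ndarray) -> Tensor:
    """Gather per-point features by group index.

    ``features`` is (B, N, C) and ``index`` (B, S, K) of int; the result is
    (B, S, K, C). The backward pass scatter-adds into the feature grid.
    """
    idx = np.asarray(index)
    B, N, C = features.data.shape
    b_idx = np.arange(B)[:, None, None]
    out = Tensor(features.data[b_idx, idx])
    out.requires_grad = features.requires_grad
    if out.requires_grad:
        out._parents = (features,)

        def bw(g):
            gx = np.zeros_like(features.data)
            np.add.at(gx, (np.broadcast_to(b_idx, idx.shape), idx), g)
            features._accum(gx)
        out._backward = bw
    return out


class Adam:
    """Adam optimizer with decoupled L2 weight decay."""

    def __init__(self, params: list[Parameter], lr=5e-4, betas=(0.9, 0.999),
                 eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
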