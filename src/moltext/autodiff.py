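"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the package's transformer encoders and
contrastive losses need: broadcast arithmetic, matrix products, exp/log/relu,
powers, axis reductions, reshapes/transposes, integer-array indexing (used
for embedding-table lookups) and stacking. Gradients are accumulated in
float64. Correctness is pinned against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum grad down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- helpers ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data**2), b.shape))

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        def backward(g, a=self, p=p):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return self._make(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            A, B = a.data, b.data
            if A.ndim == 1 and B.ndim == 1:          # dot product
                ga, gb = g * B, g * A
            elif A.ndim == 1:                        # (k,) @ (..., k, n)
                ga = g @ np.swapaxes(B, -1, -2)
                gb = A[:, None] * np.expand_dims(g, -2)
            elif B.ndim == 1:                        # (..., m, k) @ (k,)
                ga = np.expand_dims(g, -1) * B
                gb = np.swapaxes(A, -1, -2) @ g
            else:
                ga = g @ np.swapaxes(B, -1, -2)
                gb = np.swapaxes(A, -1, -2) @ g
            if a.requires_grad:
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(gb, b.shape))

        return self._make(self.data @ other.data, (self, other), backward)

    # -- elementwise ------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * o)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return self._make(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)

        return self._make(self.data * mask, (self,), backward)

    def sqrt(self):
        return self**0.5

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.reshape(a.shape))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def backward(g, a=self, inv=inv):
            if a.requires_grad:
                a._accum(np.transpose(g, inv))

        return self._make(np.transpose(self.data, axes), (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        def backward(g, a=self, idx=idx):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)

        return self._make(self.data[idx], (self,), backward)

    # -- graph traversal ---------------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)


# -- free functions --------------------------------------------------------

def stack(tensors, axis: int = 0) -> Tensor:
    """Stack tensors of identical shape along a new axis."""
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor(data, requires_grad=any(t.requires_grad for t in tensors))

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (max-shift uses a detached constant)."""
    shift = x - np.max(x.data, axis=axis, keepdims=True)
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


def logsumexp(x: Tensor, axis: int = -1) -> Tensor:
    m = np.max(x.data, axis=axis, keepdims=True)
    return (x - m).exp().sum(axis=axis, keepdims=False).log() + Tensor(np.squeeze(m, axis=axis))


def l2_normalize(x: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    norm = ((x * x).sum(axis=axis, keepdims=True) + eps) ** 0.5
    return x / norm


def cosine(u: Tensor, v: Tensor) -> Tensor:
    """Cosine similarity of two 1-D tensors."""
    un = l2_normalize(u)
    vn = l2_normalize(v)
    return (un * vn).sum()
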