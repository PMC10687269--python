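"""Minimal reverse-mode automatic differentiation over numpy arrays.

The neural components of this package (GCN encoders, the pocket-detection
module, the meta-learning loops) are small dense computations at desk scale,
so they run on this self-contained engine rather than an external deep
learning framework.  Gradients are first-order only: calling
:meth:`Tensor.backward` accumulates ``grad`` on every leaf reachable from the
output, and the graph is not itself differentiable.

Conventions
-----------
* ``Tensor`` wraps a float64 ``numpy.ndarray``; ``requires_grad`` marks leaves
  (parameters).  Intermediate nodes track their parents for backprop.
* Broadcasting follows numpy; gradients are summed back over broadcast axes.
* ``constant(x)`` wraps data that should be treated as a constant (detached).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "concat", "stack", "relu", "sigmoid",
           "softmax", "logsumexp"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading added axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = ()

    # -- helpers ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return self.data.item()

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _node(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._prev for p in parents):
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray):
        # never mutate in place: stored grads may alias upstream arrays
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic ------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g, a=self, b=other):
            a._accum(_unbroadcast(g, a.data.shape))
            b._accum(_unbroadcast(g, b.data.shape))

        return self._node(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            a._accum(-g)
        return self._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g, a=self, b=other):
            a._accum(_unbroadcast(g * b.data, a.data.shape))
            b._accum(_unbroadcast(g * a.data, b.data.shape))

        return self._node(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g, a=self, b=other):
            a._accum(_unbroadcast(g / b.data, a.data.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return self._node(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g, a=self):
            a._accum(g * p * a.data ** (p - 1))

        return self._node(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g, a=self, b=other):
            A, B = a.data, b.data
            if A.ndim == 2 and B.ndim == 2:
                ga, gb = g @ B.T, A.T @ g
            elif A.ndim == 1 and B.ndim == 2:   # (d,) @ (d,k) -> (k,)
                ga, gb = g @ B.T, np.outer(A, g)
            elif A.ndim == 2 and B.ndim == 1:   # (n,d) @ (d,) -> (n,)
                ga, gb = np.outer(g, B), A.T @ g
            else:                               # (d,) @ (d,) -> scalar
                ga, gb = g * B, g * A
            a._accum(np.asarray(ga, dtype=np.float64))
            b._accum(np.asarray(gb, dtype=np.float64))

        return self._node(out_data, (self, other), backward)

    # -- shape ops -------------------------------------------------------
    @property
    def T(self):
        def backward(g, a=self):
            a._accum(g.T)
        return self._node(self.data.T, (self,), backward)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g, a=self):
            a._accum(g.reshape(old))

        return self._node(self.data.reshape(*shape), (self,), backward)

    def __getitem__(self, idx):
        def backward(g, a=self, idx=idx):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return self._node(self.data[idx], (self,), backward)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return self._node(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, o=out_data):
            a._accum(g * o)

        return self._node(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            a._accum(g / a.data)

        return self._node(np.log(self.data), (self,), backward)

    def clip(self, lo: float, hi: float):
        out_data = np.clip(self.data, lo, hi)
        mask = (self.data > lo) & (self.data < hi)

        def backward(g, a=self, m=mask):
            a._accum(g * m)

        return self._node(out_data, (self,), backward)

    # -- backprop --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:  # iterative DFS (graphs can be deep: inner-loop unrolls)
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None


def constant(x) -> Tensor:
    """A tensor explicitly outside the gradient graph."""
    return Tensor(np.asarray(x, dtype=np.float64))


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g, a=x, m=mask):
        a._accum(g * m)

    return x._node(x.data * mask, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g, a=x, o=out_data):
        a._accum(g * o * (1.0 - o))

    return x._node(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g, a=x, o=out_data):
        dot = (g * o).sum(axis=axis, keepdims=True)
        a._accum(o * (g - dot))

    return x._node(out_data, (x,), backward)


def logsumexp(x: Tensor, axis=None) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    s = e.sum(axis=axis, keepdims=True)
    out_data = (np.log(s) + m)
    if axis is not None:
        out_data = np.squeeze(out_data, axis=axis)
    else:
        out_data = out_data.reshape(())

    def backward(g, a=x, e=e, s=s):
        gg = np.asarray(g)
        if axis is not None:
            gg = np.expand_dims(gg, axis)
        a._accum(gg * e / s)

    return x._node(out_data, (x,), backward)


def tile_rows(x: Tensor, reps: int) -> Tensor:
    """Stack ``reps`` copies of a (n, d) tensor into (reps*n, d)."""
    n, d = x.data.shape

    def backward(g, a=x):
        a._accum(g.reshape(reps, n, d).sum(axis=0))

    return x._node(np.tile(x.data, (reps, 1)), (x,), backward)


def repeat_rows(x: Tensor, reps: int) -> Tensor:
    """Repeat each row of a (B, d) tensor ``reps`` times -> (B*reps, d)."""
    b, d = x.data.shape

    def backward(g, a=x):
        a._accum(g.reshape(b, reps, d).sum(axis=1))

    return x._node(np.repeat(x.data, reps, axis=0), (x,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    out = Tensor(out_data)
    if any(t.requires_grad or t._prev for t in tensors):
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [t.reshape(*((1,) + t.data.shape)) for t in tensors]
    return concat(tensors, axis=0) if axis == 0 else concat(tensors, axis=axis)
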