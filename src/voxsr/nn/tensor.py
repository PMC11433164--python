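"""A minimal reverse-mode autodiff tape over numpy arrays.

Just enough machinery to express 3D convolutional networks and their
training losses: tensors wrap float32 ndarrays, operations record a
closure that propagates the upstream gradient to their parents, and
``backward`` walks the tape in reverse topological order.  There is no
broadcasting beyond scalars — shapes must match exactly, which keeps
gradient bookkeeping trivial and mistakes loud.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad=False, parents=(), backward=None, name=""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self):
        if self.data.ndim != 0:
            raise ValueError("backward() requires a scalar loss")
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
            if t._parents:  # leaf (parameter) grads accumulate across calls
                t.grad = None
        self.grad = np.ones((), dtype=np.float32)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, g):
        g = np.asarray(g, dtype=np.float32)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- elementwise arithmetic (exact-shape or python-scalar operands) ----

    def __add__(self, other):
        if isinstance(other, (int, float)):
            out = Tensor(self.data + other, parents=(self,))
            out._backward = lambda g, a=self: a._accumulate(g)
            return out
        _check_shapes(self, other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(g)
            if b.requires_grad:
                b._accumulate(g)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g, a=self: a._accumulate(-g)
        return out

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-other)

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            out = Tensor(self.data * other, parents=(self,))
            out._backward = lambda g, a=self, k=other: a._accumulate(g * k)
            return out
        _check_shapes(self, other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(g * b.data)
            if b.requires_grad:
                b._accumulate(g * a.data)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        _check_shapes(self, other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(g / b.data)
            if b.requires_grad:
                b._accumulate(-g * a.data / (b.data * b.data))

        out._backward = bwd
        return out


def _check_shapes(a: Tensor, b: Tensor):
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def square(x: Tensor) -> Tensor:
    return x * x


def sqrt(x: Tensor, eps: float = 0.0) -> Tensor:
    val = np.sqrt(x.data + eps)
    out = Tensor(val, parents=(x,))

    def bwd(g, a=x, v=val):
        a._accumulate(g * (0.5 / np.maximum(v, 1e-12)))

    out._backward = bwd
    return out


def absolute(x: Tensor) -> Tensor:
    out = Tensor(np.abs(x.data), parents=(x,))
    out._backward = lambda g, a=x: a._accumulate(g * np.sign(a.data))
    return out


def mean(x: Tensor) -> Tensor:
    n = x.data.size
    out = Tensor(np.asarray(x.data.mean(), dtype=np.float32), parents=(x,))
    out._backward = lambda g, a=x, n=n: a._accumulate(
        np.full(a.data.shape, float(g) / n, dtype=np.float32)
    )
    return out


def tsum(x: Tensor) -> Tensor:
    out = Tensor(np.asarray(x.data.sum(), dtype=np.float32), parents=(x,))
    out._backward = lambda g, a=x: a._accumulate(
        np.full(a.data.shape, float(g), dtype=np.float32)
    )
    return out


def concat(tensors, axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]

    def bwd(g, parts=tuple(tensors), sizes=tuple(sizes), axis=axis):
        offset = 0
        for t, s in zip(parts, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(offset, offset + s)
                t._accumulate(g[tuple(sl)])
            offset += s

    out._backward = bwd
    return out
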