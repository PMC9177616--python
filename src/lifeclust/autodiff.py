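"""Minimal reverse-mode automatic differentiation on numpy arrays.

The lifetime-clustering loss chains a feed-forward network, a softmax,
weighted Kaplan-Meier curves, and a Kuiper/MMD divergence; all of it is
built from the handful of array primitives below.  Each op records its
inputs and a backward rule on a tape; ``Tensor.backward`` walks the tape
in reverse topological order accumulating gradients in float64.

Only what the loss needs is implemented: broadcasting elementwise
arithmetic, matmul, tanh/relu/exp/log, axis reductions (sum/max/min),
cumulative sum, clipping and transpose.  Reductions use the argmax
subgradient convention, so piecewise-smooth losses (min over cluster
pairs, sup over step points) differentiate correctly almost everywhere.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an attached gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor({self.data!r}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor._from_op(self.data + other.data, (self, other), None)

        def backward(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._from_op(-self.data, (self,), None)
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor._from_op(self.data * other.data, (self, other), None)

        def backward(g):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor._from_op(self.data / other.data, (self, other), None)

        def backward(g):
            ga = _unbroadcast(g / other.data, self.data.shape)
            gb = _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            return ga, gb

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        out = Tensor._from_op(self.data**p, (self,), None)
        out._backward = lambda g: (g * p * self.data ** (p - 1),)
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor._from_op(self.data @ other.data, (self, other), None)

        def backward(g):
            return g @ other.data.T, self.data.T @ g

        out._backward = backward
        return out

    # -- unary maps ----------------------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor._from_op(val, (self,), None)
        out._backward = lambda g: (g * val,)
        return out

    def log(self):
        out = Tensor._from_op(np.log(self.data), (self,), None)
        out._backward = lambda g: (g / self.data,)
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor._from_op(val, (self,), None)
        out._backward = lambda g: (g * (1.0 - val**2),)
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor._from_op(self.data * mask, (self,), None)
        out._backward = lambda g: (g * mask,)
        return out

    def clip(self, lo: float | None, hi: float | None):
        """Clamp; gradient is zero where the clamp is active."""
        val = np.clip(self.data, lo, hi)
        inside = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            inside &= self.data > lo
        if hi is not None:
            inside &= self.data < hi
        out = Tensor._from_op(val, (self,), None)
        out._backward = lambda g: (g * inside,)
        return out

    def maximum(self, other: float):
        """Elementwise max with a scalar constant (hinge); ties go to self."""
        mask = self.data >= other
        out = Tensor._from_op(np.maximum(self.data, other), (self,), None)
        out._backward = lambda g: (g * mask,)
        return out

    @property
    def T(self):
        out = Tensor._from_op(self.data.T, (self,), None)
        out._backward = lambda g: (g.T,)
        return out

    def __getitem__(self, idx):
        out = Tensor._from_op(self.data[idx], (self,), None)

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        out._backward = backward
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims),
                              (self,), None)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        out._backward = backward
        return out

    def _extremum(self, axis, np_arg):
        """Shared max/min reduction with one-hot argmax subgradient."""
        idx = np_arg(self.data, axis=axis)
        if axis is None:
            val = self.data.reshape(-1)[idx]

            def backward(g):
                full = np.zeros_like(self.data)
                full.reshape(-1)[idx] = g
                return (full,)
        else:
            val = np.take_along_axis(self.data, np.expand_dims(idx, axis),
                                     axis=axis).squeeze(axis)

            def backward(g):
                full = np.zeros_like(self.data)
                np.put_along_axis(full, np.expand_dims(idx, axis),
                                  np.expand_dims(g, axis), axis=axis)
                return (full,)

        out = Tensor._from_op(val, (self,), None)
        out._backward = backward
        return out

    def max(self, axis=None):
        return self._extremum(axis, np.argmax)

    def min(self, axis=None):
        return self._extremum(axis, np.argmin)

    def cumsum(self, axis: int):
        out = Tensor._from_op(np.cumsum(self.data, axis=axis), (self,), None)

        def backward(g):
            rev = np.flip(g, axis=axis)
            return (np.flip(np.cumsum(rev, axis=axis), axis=axis),)

        out._backward = backward
        return out

    def softmax(self, axis: int = -1):
        """Numerically stable softmax; the row-max shift is a constant."""
        shifted = self - self.data.max(axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- backward pass -------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: loss graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad:
                    continue
                g = np.asarray(g, dtype=np.float64)
                parent.grad = g if parent.grad is None else parent.grad + g


def tensor(data, requires_grad: bool = False) -> Tensor:
    """Convenience constructor."""
    return Tensor(data, requires_grad=requires_grad)


def stack(tensors: list[Tensor]) -> Tensor:
    """Stack scalar (0-d) tensors into a 1-d tensor."""
    data = np.array([t.data for t in tensors])
    out = Tensor._from_op(data, tuple(tensors), None)
    out._backward = lambda g: tuple(g[i] for i in range(len(tensors)))
    return out
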