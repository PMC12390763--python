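"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operator set the deconvolution networks and their
training objectives need: broadcasting arithmetic, matmul, elementwise
nonlinearities, reductions, row gathering and concatenation.  Gradients
are accumulated by topological traversal of the operation graph.

Everything is float64; no GPU, no in-place ops.  Constants (plain arrays
or scalars) participate in expressions without tracking gradients.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "cat", "logsumexp"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make numpy defer to the reflected operators instead of building
    # object arrays when an ndarray meets a Tensor
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def _child(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
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

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ----------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        return self._child(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return self._child(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        other = self._lift(other)
        return self._child(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self._child(
            self.data / other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            ),
        )

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data**p
        return self._child(
            out_data,
            (self,),
            lambda g: (g * p * self.data ** (p - 1),),
        )

    def __matmul__(self, other):
        other = self._lift(other)
        return self._child(
            self.data @ other.data,
            (self, other),
            lambda g: (g @ other.data.T, self.data.T @ g),
        )

    # -- elementwise nonlinearities -------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        return self._child(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._child(np.log(self.data), (self,), lambda g: (g / self.data,))

    def relu(self):
        mask = self.data > 0
        return self._child(self.data * mask, (self,), lambda g: (g * mask,))

    def leaky_relu(self, alpha: float = 0.01):
        slope = np.where(self.data > 0, 1.0, alpha)
        return self._child(self.data * slope, (self,), lambda g: (g * slope,))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return self._child(out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),))

    def abs(self):
        sign = np.sign(self.data)
        return self._child(np.abs(self.data), (self,), lambda g: (g * sign,))

    def clamp(self, lo: float, hi: float):
        inside = (self.data >= lo) & (self.data <= hi)
        return self._child(np.clip(self.data, lo, hi), (self,), lambda g: (g * inside,))

    # -- reductions & shaping -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.data.shape).copy(),)

        return self._child(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape):
        orig = self.data.shape
        return self._child(self.data.reshape(*shape), (self,), lambda g: (g.reshape(orig),))

    @property
    def T(self):
        return self._child(self.data.T, (self,), lambda g: (g.T,))

    def take(self, indices):
        """Gather rows (axis 0); gradient scatter-adds back."""
        idx = np.asarray(indices, dtype=np.intp)

        def backward(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)

        return self._child(self.data[idx], (self,), backward)

    # -- backward pass ---------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g.copy()
                else:
                    parent.grad = parent.grad + g

    def zero_grad(self):
        self.grad = None


def cat(tensors, axis: int = 0) -> Tensor:
    """Concatenate tensors along `axis`, splitting the gradient back."""
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        return tuple(
            np.take(g, np.arange(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(tensors))
        )

    out = Tensor(data, requires_grad=any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def logsumexp(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp; the max shift is treated as constant."""
    m = x.data.max(axis=axis, keepdims=True)
    shifted = x - m
    s = shifted.exp().sum(axis=axis, keepdims=True).log() + m
    if not keepdims and axis is not None:
        # collapse the reduced axis
        new_shape = list(s.data.shape)
        del new_shape[axis]
        s = s.reshape(*new_shape)
    elif not keepdims and axis is None:
        s = s.reshape(())
    return s
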