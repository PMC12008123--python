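"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough tensor calculus to express and train the attention /
convolution / GRU network in :mod:`supenh.deep`: elementwise arithmetic
with broadcasting, (batched) matmul, the usual nonlinearities, softmax,
reshape/transpose/slice/concat, reductions, and max-pooling via ``max``
over an axis.  Everything is float64 and single-threaded; gradients are
verified against central differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a gradient back to the shape it was broadcast from."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the tape needed for reverse-mode differentiation."""

    __slots__ = ("data", "grad", "parents", "requires_grad", "_backward")

    def __init__(self, data, parents=(), requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents: tuple[Tensor, ...] = tuple(parents)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad: np.ndarray | None = None
        self._backward = lambda: None

    # -- plumbing -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (typically scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            t._backward()

    # -- arithmetic -----------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, (self, other))

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))

        def backward():
            if self.requires_grad:
                self._accum(-out.grad)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, (self, other))

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, (self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * exponent * self.data ** (exponent - 1.0))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, (self, other))

        def backward():
            if self.requires_grad:
                g = out.grad @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                g = np.swapaxes(self.data, -1, -2) @ out.grad
                other._accum(_unbroadcast(g, other.shape))

        out._backward = backward
        return out

    # -- nonlinearities -------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), (self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * out.data)

        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out._backward = backward
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), (self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * (1.0 - out.data**2))

        out._backward = backward
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), (self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * out.data * (1.0 - out.data))

        out._backward = backward
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), (self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        out._backward = backward
        return out

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out = Tensor(e / e.sum(axis=axis, keepdims=True), (self,))

        def backward():
            if self.requires_grad:
                y, g = out.data, out.grad
                self._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)))

        out._backward = backward
        return out

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.shape))

        out._backward = backward
        return out

    def transpose(self, axes: tuple[int, ...]):
        out = Tensor(self.data.transpose(axes), (self,))
        inverse = tuple(np.argsort(axes))

        def backward():
            if self.requires_grad:
                self._accum(out.grad.transpose(inverse))

        out._backward = backward
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def backward():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)

        out._backward = backward
        return out

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int):
        idx = np.argmax(self.data, axis=axis)
        out = Tensor(np.take_along_axis(self.data, np.expand_dims(idx, axis), axis).squeeze(axis), (self,))

        def backward():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.put_along_axis(
                    g, np.expand_dims(idx, axis), np.expand_dims(out.grad, axis), axis
                )
                self._accum(g)

        out._backward = backward
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along an axis (differentiable)."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out.data.ndim
                idx[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(idx)])

    out._backward = backward
    return out


def parameter(rng: np.random.Generator, *shape, scale: float | None = None) -> Tensor:
    """Trainable tensor with Glorot-style uniform initialization."""
    if scale is None:
        fan_in = shape[-2] if len(shape) >= 2 else shape[-1]
        fan_out = shape[-1]
        scale = float(np.sqrt(6.0 / (fan_in + fan_out)))
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


def zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)
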