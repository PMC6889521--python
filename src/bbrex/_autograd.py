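"""Minimal reverse-mode automatic differentiation over numpy arrays.

All model arithmetic in this package runs through the :class:`Tensor`
wrapper defined here: float64 numpy storage, a dynamically built tape,
and a topological-order backward pass.  Only the handful of operations
the relation-extraction model needs are provided (elementwise maps,
matmul, reductions, concatenation, indexing, softmax).  Gradients for
broadcast operands are summed back to the operand shape.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "stack", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------

    @staticmethod
    def _lift(value) -> "Tensor":
        return value if isinstance(value, Tensor) else Tensor(value)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def backward():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad, other.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward():
            if self.requires_grad:
                self._accumulate(-out.grad)

        out = self._make(-self.data, (self,), backward)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def backward():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad * self.data, other.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor._lift(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        out_data = self.data**exponent

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad * exponent * self.data ** (exponent - 1.0))

        out = self._make(out_data, (self,), backward)
        return out

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out_data = self.data @ other.data

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accumulate(self.data.swapaxes(-1, -2) @ out.grad)

        out = self._make(out_data, (self, other), backward)
        return out

    # -- elementwise maps --------------------------------------------------

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad * out_data)

        out = self._make(out_data, (self,), backward)
        return out

    def log(self) -> "Tensor":
        def backward():
            if self.requires_grad:
                self._accumulate(out.grad / self.data)

        out = self._make(np.log(self.data), (self,), backward)
        return out

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad * (1.0 - out_data**2))

        out = self._make(out_data, (self,), backward)
        return out

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad * out_data * (1.0 - out_data))

        out = self._make(out_data, (self,), backward)
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad * mask)

        out = self._make(self.data * mask, (self,), backward)
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            if not self.requires_grad:
                return
            grad = out.grad
            if axis is not None and not keepdims:
                grad = np.expand_dims(grad, axis)
            self._accumulate(np.broadcast_to(grad, self.shape).copy())

        out = self._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Maximum along ``axis``; ties route the gradient to the first hit."""
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        argmax = self.data.argmax(axis=axis)

        def backward():
            if not self.requires_grad:
                return
            grad = np.zeros_like(self.data)
            idx = list(np.indices(argmax.shape))
            idx.insert(axis, argmax)
            g = out.grad if keepdims else np.expand_dims(out.grad, axis)
            np.add.at(grad, tuple(idx), np.squeeze(g, axis=axis))
            self._accumulate(grad)

        out = self._make(out_data, (self,), backward)
        return out

    # -- shape manipulation ------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        def backward():
            if self.requires_grad:
                self._accumulate(out.grad.reshape(self.shape))

        out = self._make(self.data.reshape(*shape), (self,), backward)
        return out

    @property
    def T(self) -> "Tensor":
        def backward():
            if self.requires_grad:
                self._accumulate(out.grad.swapaxes(-1, -2))

        out = self._make(self.data.swapaxes(-1, -2), (self,), backward)
        return out

    def __getitem__(self, key) -> "Tensor":
        def backward():
            if self.requires_grad:
                grad = np.zeros_like(self.data)
                np.add.at(grad, key, out.grad)
                self._accumulate(grad)

        out = self._make(self.data[key], (self,), backward)
        return out

    # -- backward pass -----------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward()

    def zero_grad(self) -> None:
        self.grad = None


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out_data.ndim
                sl[axis] = slice(start, stop)
                t._accumulate(out.grad[tuple(sl)])

    out = tensors[0]._make(out_data, tensors, backward)
    return out


def stack(tensors: Sequence[Tensor]) -> Tensor:
    """Stack 1-D tensors into a matrix, one row per tensor."""
    return concat([t.reshape(1, -1) for t in tensors], axis=0)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (shift by a constant, then exp-normalize)."""
    shifted = x - x.data.max(axis=axis, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)
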