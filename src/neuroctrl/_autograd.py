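"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations needed to backpropagate through unrolled
recurrent controllers coupled to linear plants: elementwise arithmetic,
2-D matrix products, tanh, exp/log, reductions, and a detached `where`.
Gradients for broadcasting operands are summed back to the operand shape.

This is an internal engine; public training APIs live in
:mod:`neuroctrl.training`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "where", "minimum", "clip", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward  # callable(grad_out) -> tuple of parent grads

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        return Tensor(
            self.data + other.data,
            parents=(self, other),
            backward=lambda g: (
                _unbroadcast(g, self.data.shape),
                _unbroadcast(g, other.data.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        return Tensor(
            self.data * other.data,
            parents=(self, other),
            backward=lambda g: (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out = self.data ** p
        return Tensor(
            out,
            parents=(self,),
            backward=lambda g: (g * p * self.data ** (p - 1.0),),
        )

    def __matmul__(self, other):
        other = self._lift(other)
        if self.data.ndim != 2 or other.data.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")
        return Tensor(
            self.data @ other.data,
            parents=(self, other),
            backward=lambda g: (g @ other.data.T, self.data.T @ g),
        )

    def T_(self) -> "Tensor":
        """2-D transpose inside the graph."""
        return Tensor(self.data.T, parents=(self,), backward=lambda g: (g.T,))

    # -- nonlinearities --------------------------------------------------

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor(out, parents=(self,), backward=lambda g: (g * (1.0 - out ** 2),))

    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, parents=(self,), backward=lambda g: (g * out,))

    def log(self):
        return Tensor(
            np.log(self.data), parents=(self,), backward=lambda g: (g / self.data,)
        )

    # -- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            g_exp = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g_exp, self.data.shape).copy(),)

        return Tensor(out, parents=(self,), backward=backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- backward pass ---------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, grad in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.array(grad, dtype=np.float64, copy=True)
                else:
                    parent.grad += grad


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def where(cond: np.ndarray, a, b) -> Tensor:
    """Select elementwise; `cond` is a plain boolean array (not differentiated)."""
    a, b = Tensor._lift(a), Tensor._lift(b)
    cond = np.asarray(cond, dtype=bool)
    return Tensor(
        np.where(cond, a.data, b.data),
        parents=(a, b),
        backward=lambda g: (
            _unbroadcast(np.where(cond, g, 0.0), a.data.shape),
            _unbroadcast(np.where(cond, 0.0, g), b.data.shape),
        ),
    )


def minimum(a: Tensor, b: Tensor) -> Tensor:
    return where(a.data <= Tensor._lift(b).data, a, b)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp with zero gradient outside [lo, hi]."""
    out = where(x.data < lo, Tensor(np.full(x.shape, lo)), x)
    return where(out.data > hi, Tensor(np.full(out.shape, hi)), out)


def concat(parts: list[Tensor], axis: int = -1) -> Tensor:
    datas = [p.data for p in parts]
    splits = np.cumsum([d.shape[axis] for d in datas])[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate(datas, axis=axis), parents=tuple(parts), backward=backward)
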