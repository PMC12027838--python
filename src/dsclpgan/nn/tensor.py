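"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float64 ``numpy.ndarray`` together with an optional
gradient and a closure that propagates adjoints to its parents.  The graph is
built eagerly by the arithmetic operators below; :meth:`Tensor.backward` runs a
topological sweep.  Only the operations the package's networks need are
implemented — this is a deliberately small engine, not a framework.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 stretched by broadcasting
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
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
        if self.data.size != 1:
            raise ValueError("item() requires a single-element tensor")
        return float(self.data.reshape(()))

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not (parent.requires_grad or parent._parents):
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data
        a, b = self, other

        def backward(g):
            return (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape))

        return Tensor._make(out_data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            return (_unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            ga = _unbroadcast(g / b.data, a.shape)
            gb = _unbroadcast(-g * a.data / (b.data * b.data), b.shape)
            return (ga, gb)

        return Tensor._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def backward(g):
            return (g * e * np.power(a.data, e - 1.0),)

        return Tensor._make(np.power(a.data, e), (a,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other
        out_data = a.data @ b.data

        def backward(g):
            if a.data.ndim == 1:
                ga = g @ b.data.T if b.data.ndim > 1 else g * b.data
            else:
                ga = g @ np.swapaxes(b.data, -1, -2)
                ga = _unbroadcast(ga, a.shape)
            gb = np.swapaxes(a.data, -1, -2) @ g
            gb = _unbroadcast(gb, b.shape)
            return (ga, gb)

        return Tensor._make(out_data, (a, b), backward)

    # -- elementwise functions -------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._make(out_data, (a,), lambda g: (g * out_data,))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: (g / a.data,))

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)
        return Tensor._make(out_data, (a,), lambda g: (g / (2.0 * out_data),))

    def abs(self):
        a = self
        return Tensor._make(np.abs(a.data), (a,), lambda g: (g * np.sign(a.data),))

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._make(out_data, (a,), lambda g: (g * out_data * (1.0 - out_data),))

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)
        return Tensor._make(out_data, (a,), lambda g: (g * (1.0 - out_data * out_data),))

    def leaky_relu(self, slope: float = 0.2):
        a = self
        mask = np.where(a.data > 0, 1.0, slope)
        return Tensor._make(a.data * mask, (a,), lambda g: (g * mask,))

    def relu(self):
        return self.leaky_relu(0.0)

    def clip(self, lo: float, hi: float):
        a = self
        mask = ((a.data >= lo) & (a.data <= hi)).astype(np.float64)
        return Tensor._make(np.clip(a.data, lo, hi), (a,), lambda g: (g * mask,))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, tuple(ax % a.data.ndim for ax in axes))
            return (np.broadcast_to(g, a.shape).copy(),)

        return Tensor._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        return Tensor._make(a.data.reshape(shape), (a,), lambda g: (g.reshape(a.shape),))

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)
        return Tensor._make(
            a.data.transpose(axes), (a,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, idx):
        a = self

        def backward(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(a.data[idx], (a,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, ts, backward)
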