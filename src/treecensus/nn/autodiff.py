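"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine is deliberately small: it supports exactly the operations the
tree counting / segmentation / height networks and their losses need
(elementwise arithmetic, reductions, activations, and the structured ops
in :mod:`treecensus.nn.functional`). Gradients are accumulated by a
topological sweep over the dynamically recorded graph, micrograd-style
but fully vectorised.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph recording (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (the inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_diff = grad.ndim - len(shape)
    if ndim_diff > 0:
        grad = grad.sum(axis=tuple(range(ndim_diff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make ndarray <op> Tensor defer to the reflected Tensor ops
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float64 if not isinstance(data, np.ndarray) else data.dtype)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float64)
        self.grad = None
        track = _grad_enabled and (requires_grad or any(p.requires_grad for p in parents))
        self.requires_grad = track
        self._parents = tuple(parents) if track else ()
        self._backward = backward if track else None

    # -- graph mechanics ------------------------------------------------
    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- conveniences ---------------------------------------------------
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

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- elementwise arithmetic ------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a.accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b.accumulate(_unbroadcast(g, b.data.shape))

        out._backward = backward if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def backward(g, a=self):
            if a.requires_grad:
                a.accumulate(-g)

        out._backward = backward if out.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a.accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b.accumulate(_unbroadcast(g * a.data, b.data.shape))

        out._backward = backward if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a.accumulate(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b.accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        out._backward = backward if out.requires_grad else None
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))

        def backward(g, a=self, e=exponent):
            if a.requires_grad:
                a.accumulate(g * e * a.data ** (e - 1))

        out._backward = backward if out.requires_grad else None
        return out

    # -- reductions -------------------------------------------------------
    def sum(self):
        out = Tensor(np.asarray(self.data.sum()), parents=(self,))

        def backward(g, a=self):
            if a.requires_grad:
                a.accumulate(np.broadcast_to(g, a.data.shape).astype(a.data.dtype))

        out._backward = backward if out.requires_grad else None
        return out

    def mean(self):
        return self.sum() / self.data.size

    # -- nonlinearities ----------------------------------------------------
    def abs(self):
        out = Tensor(np.abs(self.data), parents=(self,))

        def backward(g, a=self):
            if a.requires_grad:
                a.accumulate(g * np.sign(a.data))

        out._backward = backward if out.requires_grad else None
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def backward(g, a=self):
            if a.requires_grad:
                a.accumulate(g * (a.data > 0))

        out._backward = backward if out.requires_grad else None
        return out

    def sigmoid(self):
        # clip keeps exp in range for float32; sigmoid saturates anyway
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -30.0, 30.0)))
        out = Tensor(y, parents=(self,))

        def backward(g, a=self, y=y):
            if a.requires_grad:
                a.accumulate(g * y * (1.0 - y))

        out._backward = backward if out.requires_grad else None
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)
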