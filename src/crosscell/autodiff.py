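"""Minimal reverse-mode automatic differentiation over numpy arrays.

The conditional VAE in this package needs gradients of a zero-inflated
negative binomial likelihood (with log-gamma terms) through a small MLP.
Rather than hand-deriving and hard-coding those gradients, this module
provides a vectorised tape-based autodiff engine with exactly the
primitives the model uses: affine maps, elementwise nonlinearities,
reductions, ``gammaln`` and numerically stable ``softplus`` /
``logsumexp``. Gradients are checked against central finite differences
in the test suite.

Only what the model needs is implemented; this is not a general tensor
library.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.special import digamma, expit, gammaln as _gammaln


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were broadcast from size 1
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out = _node(np.add(self.data, other.data), (self, other))

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad)
            if other.requires_grad:
                other._accumulate(out.grad)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))

        def backward():
            if self.requires_grad:
                self._accumulate(-out.grad)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = _node(np.multiply(self.data, other.data), (self, other))

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad * other.data)
            if other.requires_grad:
                other._accumulate(out.grad * self.data)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = _node(np.divide(self.data, other.data), (self, other))

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad / other.data)
            if other.requires_grad:
                other._accumulate(-out.grad * self.data / other.data**2)

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        out = _node(self.data**exponent, (self,))

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad * exponent * self.data ** (exponent - 1))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = _node(self.data @ other.data, (self, other))

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ out.grad)

        out._backward = backward
        return out

    # -- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward():
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- autodiff driver -------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward()

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


def _node(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    out._parents = tuple(p for p in parents if p.requires_grad) if out.requires_grad else ()
    # keep full parent tuple for traversal when any parent requires grad
    if out.requires_grad:
        out._parents = parents
    return out


# -- elementwise functions ----------------------------------------------


def exp(x: Tensor) -> Tensor:
    out = _node(np.exp(x.data), (x,))

    def backward():
        if x.requires_grad:
            x._accumulate(out.grad * out.data)

    out._backward = backward
    return out


def log(x: Tensor) -> Tensor:
    out = _node(np.log(x.data), (x,))

    def backward():
        if x.requires_grad:
            x._accumulate(out.grad / x.data)

    out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    out = _node(np.maximum(x.data, 0.0), (x,))

    def backward():
        if x.requires_grad:
            x._accumulate(out.grad * (x.data > 0))

    out._backward = backward
    return out


def sigmoid(x: Tensor) -> Tensor:
    out = _node(expit(x.data), (x,))

    def backward():
        if x.requires_grad:
            x._accumulate(out.grad * out.data * (1.0 - out.data))

    out._backward = backward
    return out


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), computed without overflow; d/dx = sigmoid(x)."""
    val = np.maximum(x.data, 0.0) + np.log1p(np.exp(-np.abs(x.data)))
    out = _node(val, (x,))

    def backward():
        if x.requires_grad:
            x._accumulate(out.grad * expit(x.data))

    out._backward = backward
    return out


def log_sigmoid(x: Tensor) -> Tensor:
    return -softplus(-x)


def gammaln(x: Tensor) -> Tensor:
    out = _node(_gammaln(x.data), (x,))

    def backward():
        if x.requires_grad:
            x._accumulate(out.grad * digamma(x.data))

    out._backward = backward
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient is passed only where unclamped."""
    out = _node(np.clip(x.data, lo, hi), (x,))

    def backward():
        if x.requires_grad:
            mask = (x.data > lo) & (x.data < hi)
            x._accumulate(out.grad * mask)

    out._backward = backward
    return out


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    val = np.log(np.exp(x.data - m).sum(axis=axis, keepdims=True)) + m
    softmax = np.exp(x.data - val)
    if not keepdims:
        val = np.squeeze(val, axis=axis)
    out = _node(val, (x,))

    def backward():
        if x.requires_grad:
            g = out.grad
            if not keepdims:
                g = np.expand_dims(g, axis)
            x._accumulate(g * softmax)

    out._backward = backward
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    return x - logsumexp(x, axis=axis, keepdims=True)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return exp(log_softmax(x, axis=axis))


# -- parameters and optimiser -------------------------------------------


class Adam:
    """Adam optimiser over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
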