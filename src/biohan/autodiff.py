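"""A compact reverse-mode automatic differentiation engine on NumPy arrays.

The hyperbolic encoder needs gradients of losses through Möbius operations,
attention softmaxes and exponential/logarithmic maps.  This module provides
exactly the operator set those computations require: broadcasting arithmetic,
matrix products, reductions, the elementwise functions tanh/artanh/exp/log/
sqrt, piecewise-linear activations, clamping and row gathering.  Gradients are
accumulated by topological traversal of the recorded graph.

Every function in this module dispatches on its argument type: applied to a
:class:`Tensor` it records the operation, applied to a plain ndarray/scalar it
computes with NumPy.  Code written against these functions therefore runs both
under differentiation and as straight NumPy.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with a gradient slot and a recorded backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make numpy defer to Tensor's reflected operators (ndarray * Tensor etc.)
    __array_ufunc__ = None

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[Array], Iterable[Array | None]] | None = None,
    ) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Array | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph plumbing ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) tensor w.r.t. all leaves."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
            for parent, pgrad in zip(node._parents, node._backward(node.grad)):
                if pgrad is None or not parent.requires_grad:
                    continue
                pgrad = _unbroadcast(np.asarray(pgrad), parent.data.shape)
                parent.grad = pgrad if parent.grad is None else parent.grad + pgrad

    def zero_grad(self) -> None:
        self.grad = None

    # -- operators -----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data + other.data,
            parents=(self, other),
            backward=lambda g: (g, g),
        )

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data * other.data,
            parents=(self, other),
            backward=lambda g: (g * other.data, g * self.data),
        )

    __rmul__ = __mul__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data / other.data,
            parents=(self, other),
            backward=lambda g: (g / other.data, -g * self.data / other.data**2),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        return Tensor(
            self.data**exponent,
            parents=(self,),
            backward=lambda g: (g * exponent * self.data ** (exponent - 1),),
        )

    def __matmul__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data @ other.data,
            parents=(self, other),
            backward=lambda g: (g @ other.data.T, self.data.T @ g),
        )

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor(self.data[idx], parents=(self,), backward=backward)

    @property
    def T(self):
        return Tensor(self.data.T, parents=(self,), backward=lambda g: (g.T,))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor(
            self.data.reshape(shape),
            parents=(self,),
            backward=lambda g: (g.reshape(self.data.shape),),
        )


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


# ---------------------------------------------------------------------------
# dispatching elementwise functions and reductions
# ---------------------------------------------------------------------------


def _unary(x, value_fn, grad_fn):
    if isinstance(x, Tensor):
        out = value_fn(x.data)
        return Tensor(out, parents=(x,), backward=lambda g: (g * grad_fn(x.data, out),))
    return value_fn(np.asarray(x, dtype=np.float64))


def tanh(x):
    return _unary(x, np.tanh, lambda d, out: 1.0 - out**2)


def atanh(x):
    return _unary(x, np.arctanh, lambda d, out: 1.0 / (1.0 - d**2))


def exp(x):
    return _unary(x, np.exp, lambda d, out: out)


def log(x):
    return _unary(x, np.log, lambda d, out: 1.0 / d)


def sqrt(x):
    return _unary(x, np.sqrt, lambda d, out: 0.5 / out)


def relu(x):
    return _unary(x, lambda d: np.maximum(d, 0.0), lambda d, out: (d > 0).astype(float))


def leaky_relu(x, negative_slope: float = 0.2):
    return _unary(
        x,
        lambda d: np.where(d > 0, d, negative_slope * d),
        lambda d, out: np.where(d > 0, 1.0, negative_slope),
    )


def clamp(x, min_value: float | None = None, max_value: float | None = None):
    def value_fn(d):
        return np.clip(d, min_value, max_value)

    def grad_fn(d, out):
        mask = np.ones_like(d)
        if min_value is not None:
            mask = mask * (d >= min_value)
        if max_value is not None:
            mask = mask * (d <= max_value)
        return mask

    return _unary(x, value_fn, grad_fn)


def sum(x, axis=None, keepdims: bool = False):  # noqa: A001 - mirrors np.sum
    if isinstance(x, Tensor):
        out = x.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, x.data.shape).copy(),)

        return Tensor(out, parents=(x,), backward=backward)
    return np.asarray(x).sum(axis=axis, keepdims=keepdims)


def norm(x, axis=-1, keepdims: bool = True, eps: float = 1e-15):
    """Smoothed L2 norm along ``axis``; differentiable at the origin."""
    return sqrt(sum(x * x, axis=axis, keepdims=keepdims) + eps)


def matmul(a, b):
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        return as_tensor(a) @ as_tensor(b)
    return np.asarray(a) @ np.asarray(b)


def data_of(x) -> Array:
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Standard Adam with bias correction over a list of parameter Tensors."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

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
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
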