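"""Minimal vectorized reverse-mode automatic differentiation.

Implements exactly the operations the model and its losses need: affine
maps, elementwise nonlinearities, (log-)softmax, reductions, concatenation
and the special functions of the negative-binomial likelihood. All data is
float64. Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, gammaln

__all__ = ["Tensor", "Adam", "concat", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that numpy broadcasting added or expanded."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _result(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- basic properties -----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor({self.data!r}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor._result(
            self.data + other.data,
            (self, other),
            lambda g: (self._accum(g), other._accum(g)),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor._result(-self.data, (self,), lambda g: self._accum(-g))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor._result(
            self.data * other.data,
            (self, other),
            lambda g: (self._accum(g * other.data), other._accum(g * self.data)),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor._result(
            self.data / other.data,
            (self, other),
            lambda g: (
                self._accum(g / other.data),
                other._accum(-g * self.data / other.data**2),
            ),
        )
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = Tensor._result(
            self.data**exponent,
            (self,),
            lambda g: self._accum(g * exponent * self.data ** (exponent - 1)),
        )
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor._result(
            self.data @ other.data,
            (self, other),
            lambda g: (self._accum(g @ other.data.T), other._accum(self.data.T @ g)),
        )
        return out

    # -- elementwise functions ------------------------------------------------

    def exp(self):
        y = np.exp(self.data)
        return Tensor._result(y, (self,), lambda g: self._accum(g * y))

    def log(self):
        return Tensor._result(
            np.log(self.data), (self,), lambda g: self._accum(g / self.data)
        )

    def tanh(self):
        y = np.tanh(self.data)
        return Tensor._result(y, (self,), lambda g: self._accum(g * (1.0 - y * y)))

    def relu(self):
        y = np.maximum(self.data, 0.0)
        return Tensor._result(
            y, (self,), lambda g: self._accum(g * (self.data > 0.0))
        )

    def softplus(self):
        # numerically stable log(1 + exp(x)); gradient is the logistic sigmoid
        x = self.data
        y = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
        sig = 1.0 / (1.0 + np.exp(-x))
        return Tensor._result(y, (self,), lambda g: self._accum(g * sig))

    def lgamma(self):
        return Tensor._result(
            gammaln(self.data),
            (self,),
            lambda g: self._accum(g * digamma(self.data)),
        )

    # -- reductions and shape ops ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        y = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._result(y, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        ls = z - lse
        sm = np.exp(ls)

        def backward(g):
            self._accum(g - sm * np.sum(g, axis=axis, keepdims=True))

        return Tensor._result(ls, (self,), backward)

    def softmax(self, axis: int = -1):
        return self.log_softmax(axis=axis).exp()

    # -- backward pass ----------------------------------------------------------

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep for many-layer nets
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
            if node._backward is not None:
                node._backward(node.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list, axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis``, splitting the gradient back."""
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accum(g[tuple(idx)])

    return Tensor._result(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
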