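"""Minimal vectorized reverse-mode automatic differentiation over NumPy arrays.

Provides exactly the operator set needed by the residual LassoNet network and
the GFLU stack: elementwise arithmetic with broadcasting, matrix products,
tanh/sigmoid/relu, row-wise log-softmax, concatenation, and reductions —
plus SGD(momentum) and Adam optimizers. All computation is float64 and fully
deterministic, so identical seeds give bitwise-identical trajectories.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "mse_loss", "cross_entropy", "SGD", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # -- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _make(self, data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if not self.requires_grad:
            return
        g = _unbroadcast(g, self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic ------------------------------------------------------
    @staticmethod
    def _wrap(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)

        def bwd(g):
            self._accum(g)
            other._accum(g)

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)

        def bwd(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __sub__(self, other):
        other = self._wrap(other)

        def bwd(g):
            self._accum(g)
            other._accum(-g)

        return self._make(self.data - other.data, (self, other), bwd)

    def __rsub__(self, other):
        return self._wrap(other) - self

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bwd)

    def __matmul__(self, other):
        other = self._wrap(other)

        def bwd(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bwd)

    def square(self):
        def bwd(g):
            self._accum(2.0 * self.data * g)

        return self._make(self.data**2, (self,), bwd)

    # -- nonlinearities --------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            self._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), bwd)

    def log_softmax(self):
        """Row-wise log-softmax (axis=1)."""
        z = self.data - self.data.max(axis=1, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
        out_data = z - lse
        sm = np.exp(out_data)

        def bwd(g):
            self._accum(g - sm * g.sum(axis=1, keepdims=True))

        return self._make(out_data, (self,), bwd)

    # -- reductions ------------------------------------------------------
    def sum(self):
        def bwd(g):
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(self.data.sum(), (self,), bwd)

    def mean(self):
        n = self.data.size

        def bwd(g):
            self._accum(np.broadcast_to(g / n, self.data.shape).copy())

        return self._make(self.data.mean(), (self,), bwd)


def concat(tensors, axis: int = 1) -> Tensor:
    """Concatenate tensors along `axis` (backward splits the gradient)."""
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offs[:-1], offs[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = bwd
    return out


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    return (pred - Tensor(target)).square().mean()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer labels under softmax logits."""
    labels = np.asarray(labels, dtype=int)
    onehot = np.zeros(logits.shape)
    onehot[np.arange(labels.size), labels] = 1.0
    ls = logits.log_softmax()
    return -(ls * Tensor(onehot)).sum() * (1.0 / labels.size)


class SGD:
    """Plain/momentum stochastic gradient descent on a list of Tensors."""

    def __init__(self, params, lr: float, momentum: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v


class Adam:
    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self):
        self._t += 1
        b1t = 1.0 - self.b1**self._t
        b2t = 1.0 - self.b2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
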