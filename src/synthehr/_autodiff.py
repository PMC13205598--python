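"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the sequence autoencoder: broadcast-aware
elementwise ops, matmul, the GRU nonlinearities, a numerically stable
binary-cross-entropy-with-logits primitive, and an Adam optimizer.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "bce_with_logits", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient back down to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = ()

    # -- construction helpers -------------------------------------------
    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(data, requires_grad=True)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing --------------------------------------------------
    def _make(self, data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def backward(self):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        if not self.requires_grad:
            return
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- operators --------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accum(g)
            other._accum(g)

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __matmul__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bw)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bw(g):
            self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), bw)

    def tanh(self):
        t = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - t * t))

        return self._make(t, (self,), bw)

    def relu(self):
        m = self.data > 0

        def bw(g):
            self._accum(g * m)

        return self._make(self.data * m, (self,), bw)

    def sum(self):
        def bw(g):
            self._accum(np.full_like(self.data, float(g)))

        return self._make(self.data.sum(), (self,), bw)

    def mean(self):
        n = self.data.size

        def bw(g):
            self._accum(np.full_like(self.data, float(g) / n))

        return self._make(self.data.mean(), (self,), bw)


def bce_with_logits(logits: Tensor, targets: np.ndarray, weights=None) -> Tensor:
    """Mean binary cross-entropy with logits, optionally weighted per element.

    Stable: softplus(l) - t*l with softplus(x) = max(x,0) + log1p(exp(-|x|)).
    The mean is over the total weight (element count when unweighted).
    """
    t = np.asarray(targets, dtype=np.float64)
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=np.float64)
    total = w.sum()
    if total <= 0:
        raise ValueError("bce_with_logits: zero total weight")
    x = logits.data
    softplus = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
    val = float((w * (softplus - t * x)).sum() / total)
    out = Tensor(val)
    out.requires_grad = logits.requires_grad
    if out.requires_grad:
        out._prev = (logits,)
        sig = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))

        def bw(g):
            logits._accum(float(g) * w * (sig - t) / total)

        out._backward = bw
    return out


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self, grads=None):
        """Apply one Adam update; ``grads`` overrides the accumulated ones
        (used by the differentially private path)."""
        self.t += 1
        for i, p in enumerate(self.params):
            g = grads[i] if grads is not None else p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
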