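"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operator set the model needs: broadcast arithmetic,
dense and sparse-dense matrix products, reductions, the elementwise
nonlinearities (ReLU, tanh, sigmoid, softplus, exp, log, log-gamma), value
clamping with a zero sub-gradient outside the interval, row gathering, and
an Adam optimizer with L2 weight decay and global-norm gradient clipping.

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`,
which topologically sorts the tape and is only callable on scalars.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse as sp
from scipy import special


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents
        )
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def T(self) -> "Tensor":
        def bw(g, out):
            return (g.T,)

        return _op((self,), self.data.T, bw)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data.item())

    def zero_grad(self):
        self.grad = None

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.ones_like(self.data)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and not t._parents:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for parent, pg in zip(t._parents, t._backward(g, t)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = _as_tensor(other)

        def bw(g, out):
            return (
                _unbroadcast(g, self.data.shape),
                _unbroadcast(g, other.data.shape),
            )

        return _op((self, other), self.data + other.data, bw)

    __radd__ = __add__

    def __neg__(self):
        return _op((self,), -self.data, lambda g, out: (-g,))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)

        def bw(g, out):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        return _op((self, other), self.data * other.data, bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)

        def bw(g, out):
            return (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            )

        return _op((self, other), self.data / other.data, bw)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        def bw(g, out):
            return (g * p * self.data ** (p - 1),)

        return _op((self,), self.data**p, bw)

    def __matmul__(self, other):
        other = _as_tensor(other)

        def bw(g, out):
            return (g @ other.data.T, self.data.T @ g)

        return _op((self, other), self.data @ other.data, bw)

    def __getitem__(self, idx):
        """Row gather by an integer array; repeated rows accumulate gradient."""
        idx = np.asarray(idx)

        def bw(g, out):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return _op((self,), self.data[idx], bw)

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        orig = self.data.shape

        def bw(g, out):
            return (g.reshape(orig),)

        return _op((self,), self.data.reshape(*shape), bw)

    def sum(self, axis=None, keepdims=False):
        def bw(g, out):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            ge = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(ge, self.data.shape).copy(),)

        return _op((self,), self.data.sum(axis=axis, keepdims=keepdims), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # ------------------------------------------------------------ elementwise
    def relu(self):
        def bw(g, out):
            return (g * (self.data > 0),)

        return _op((self,), np.maximum(self.data, 0.0), bw)

    def tanh(self):
        def bw(g, out):
            return (g * (1.0 - out.data**2),)

        return _op((self,), np.tanh(self.data), bw)

    def sigmoid(self):
        def bw(g, out):
            return (g * out.data * (1.0 - out.data),)

        return _op((self,), special.expit(self.data), bw)

    def softplus(self):
        def bw(g, out):
            return (g * special.expit(self.data),)

        return _op((self,), np.logaddexp(0.0, self.data), bw)

    def exp(self):
        with np.errstate(over="ignore"):
            val = np.exp(self.data)

        def bw(g, out):
            # overflow produces inf; those entries only ever reach the loss
            # through a clamp whose sub-gradient is zero there
            safe = np.where(np.isfinite(out.data), out.data, 0.0)
            return (g * safe,)

        return _op((self,), val, bw)

    def log(self):
        def bw(g, out):
            return (g / self.data,)

        return _op((self,), np.log(self.data), bw)

    def sqrt(self):
        def bw(g, out):
            return (g * 0.5 / out.data,)

        return _op((self,), np.sqrt(self.data), bw)

    def lgamma(self):
        def bw(g, out):
            return (g * special.digamma(self.data),)

        return _op((self,), special.gammaln(self.data), bw)

    def clamp(self, lo=None, hi=None):
        """Clip values; sub-gradient is zero outside [lo, hi]."""

        def bw(g, out):
            mask = np.ones_like(self.data, dtype=bool)
            if lo is not None:
                mask &= self.data >= lo
            if hi is not None:
                mask &= self.data <= hi
            return (g * mask,)

        return _op((self,), np.clip(self.data, lo, hi), bw)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _op(parents, data, backward) -> Tensor:
    out = Tensor(data, _parents=parents, _backward=backward)
    if not out.requires_grad:
        out._parents, out._backward = (), None
    return out


def spmm(A: sp.spmatrix, X: Tensor) -> Tensor:
    """Sparse (constant) @ dense (differentiable) matrix product."""
    A = sp.csr_matrix(A)
    AT = A.T.tocsr()

    def bw(g, out):
        return (AT @ g,)

    return _op((X,), A @ X.data, bw)


def dropout(X: Tensor, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    """Inverted dropout; identity when ``train`` is False or rate == 0."""
    if not train or rate <= 0.0:
        return X
    mask = (rng.random(X.data.shape) >= rate) / (1.0 - rate)
    return X * Tensor(mask)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    """Glorot/Xavier uniform initialization."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=(fan_in, fan_out)),
                  requires_grad=True)


def zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def clip_grad_norm(params: list, max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is at most max_norm."""
    total = np.sqrt(sum(float((p.grad**2).sum()) for p in params
                        if p.grad is not None))
    if max_norm is not None and total > max_norm > 0:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return total


class Adam:
    """Adam with (coupled) L2 weight decay added to the gradient."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
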