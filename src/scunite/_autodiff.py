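"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the training losses need (dense affine
layers, the ZINB likelihood, cross-entropy, pairwise cosine losses and the
spherical clustering loss). Tensors hold float32 or float64 data; plain
scalar/array operands adopt the tensor operand's dtype, so a float32
network stays float32 end to end. Gradients are accumulated by a
topological backward sweep.
"""

from __future__ import annotations

import numpy as np
from scipy import special


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over the axes that numpy broadcasting expanded."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    for _ in range(extra):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # ndarray <op> Tensor must defer to Tensor's reflected ops
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- graph construction helpers ------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def T(self):
        return Tensor(self.data.T, _parents=(self,), _backward=lambda g: (g.T,))

    def item(self) -> float:
        return float(self.data)

    def backward(self):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                g = _unbroadcast(np.asarray(g), parent.data.shape)
                parent.grad = g if parent.grad is None else parent.grad + g

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other, self.data.dtype)
        return Tensor(self.data + other.data, _parents=(self, other),
                      _backward=lambda g: (g, g))

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=(self,), _backward=lambda g: (-g,))

    def __sub__(self, other):
        other = as_tensor(other, self.data.dtype)
        return Tensor(self.data - other.data, _parents=(self, other),
                      _backward=lambda g: (g, -g))

    def __rsub__(self, other):
        return as_tensor(other, self.data.dtype) - self

    def __mul__(self, other):
        other = as_tensor(other, self.data.dtype)
        return Tensor(self.data * other.data, _parents=(self, other),
                      _backward=lambda g: (g * other.data, g * self.data))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other, self.data.dtype)
        return Tensor(self.data / other.data, _parents=(self, other),
                      _backward=lambda g: (g / other.data,
                                           -g * self.data / other.data ** 2))

    def __rtruediv__(self, other):
        return as_tensor(other, self.data.dtype) / self

    def __pow__(self, p: float):
        return Tensor(self.data ** p, _parents=(self,),
                      _backward=lambda g: (g * p * self.data ** (p - 1),))

    def __matmul__(self, other):
        other = as_tensor(other, self.data.dtype)
        return Tensor(self.data @ other.data, _parents=(self, other),
                      _backward=lambda g: (g @ other.data.T, self.data.T @ g))

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return Tensor(out, _parents=(self,), _backward=back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if dtype is not None and arr.dtype != dtype:
        arr = arr.astype(dtype)
    return Tensor(arr)


# -- elementwise functions ----------------------------------------------

def exp(t: Tensor) -> Tensor:
    with np.errstate(over="ignore"):
        out = np.exp(t.data)
    return Tensor(out, _parents=(t,), _backward=lambda g: (g * out,))


def log(t: Tensor) -> Tensor:
    return Tensor(np.log(t.data), _parents=(t,), _backward=lambda g: (g / t.data,))


def sqrt(t: Tensor) -> Tensor:
    out = np.sqrt(t.data)
    return Tensor(out, _parents=(t,), _backward=lambda g: (g * 0.5 / out,))


def sigmoid(t: Tensor) -> Tensor:
    out = special.expit(t.data)
    return Tensor(out, _parents=(t,), _backward=lambda g: (g * out * (1.0 - out),))


def softplus(t: Tensor) -> Tensor:
    out = np.logaddexp(0.0, t.data)
    return Tensor(out, _parents=(t,),
                  _backward=lambda g: (g * special.expit(t.data),))


def relu(t: Tensor) -> Tensor:
    return Tensor(np.maximum(t.data, 0.0), _parents=(t,),
                  _backward=lambda g: (g * (t.data > 0),))


def clip(t: Tensor, lo: float, hi: float) -> Tensor:
    out = np.clip(t.data, lo, hi)
    mask = (t.data > lo) & (t.data < hi)
    return Tensor(out, _parents=(t,), _backward=lambda g: (g * mask,))


def gammaln(t: Tensor) -> Tensor:
    dt = t.data.dtype
    return Tensor(special.gammaln(t.data).astype(dt, copy=False),
                  _parents=(t,),
                  _backward=lambda g: (
                      g * special.digamma(t.data).astype(dt, copy=False),))


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  _parents=tuple(tensors), _backward=back)


def log_softmax(t: Tensor, axis: int = 1) -> Tensor:
    m = t.data.max(axis=axis, keepdims=True)
    lse = m + np.log(np.exp(t.data - m).sum(axis=axis, keepdims=True))
    out = t.data - lse

    def back(g):
        return (g - np.exp(out) * g.sum(axis=axis, keepdims=True),)

    return Tensor(out, _parents=(t,), _backward=back)


def normalize_rows(t: Tensor, eps: float = 1e-12) -> Tensor:
    """Project each row onto the unit sphere (differentiable)."""
    norm = sqrt((t * t).sum(axis=1, keepdims=True) + eps)
    return t / norm


# -- optimizer ------------------------------------------------------------

class Adam:
    """Adam with optional global-gradient-norm clipping."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8,
                 clip_norm=None):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g ** 2).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))
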