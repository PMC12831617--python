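"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to train the small attention and graph-convolution
classifiers in this package with full-batch Adam: broadcasting
elementwise ops, batched matmul, reductions, indexing, softmax /
layer-norm building blocks, and a numerically stable softplus for the
binary cross-entropy loss.  Gradients for broadcast operands are summed
back to the operand's shape.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple["Tensor", ...] = ()
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    # -- graph bookkeeping -------------------------------------------
    def _make(self, data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- elementwise -------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.shape)

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.shape)

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __truediv__(self, other):
        return self * self._coerce(other).pow(-1.0)

    def __rtruediv__(self, other):
        return self._coerce(other) * self.pow(-1.0)

    def pow(self, exponent: float):
        def backward(g):
            if self.requires_grad:
                self.grad += g * exponent * np.power(self.data, exponent - 1.0)

        return self._make(np.power(self.data, exponent), (self,), backward)

    def sqrt(self):
        return self.pow(0.5)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self.grad += g * out_data

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self.grad += g / self.data

        return self._make(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self.grad += g * (1.0 - out_data**2)

        return self._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self.grad += g * mask

        return self._make(self.data * mask, (self,), backward)

    def softplus(self):
        """log(1 + exp(x)), numerically stable for large |x|."""
        out_data = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self.grad += g * sig

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self.grad += g * out_data * (1.0 - out_data)

        return self._make(out_data, (self,), backward)

    # -- shape ---------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape

        def backward(g):
            if self.requires_grad:
                self.grad += g.reshape(old)

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self.grad += g.transpose(inv)

        return self._make(self.data.transpose(axes), (self,), backward)

    def take(self, indices, axis: int = 0):
        """Integer indexing along one axis (embedding lookup)."""
        indices = np.asarray(indices)

        def backward(g):
            if self.requires_grad:
                np.add.at(
                    self.grad,
                    tuple(
                        indices if ax == axis else slice(None)
                        for ax in range(self.data.ndim)
                    ),
                    g,
                )

        return self._make(np.take(self.data, indices, axis=axis), (self,), backward)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += np.broadcast_to(g, self.shape)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.grad += np.broadcast_to(gg, self.shape)

        return self._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            denom = self.data.size
        else:
            denom = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / denom)

    # -- matmul ---------------------------------------------------------
    def matmul(self, other: "Tensor"):
        other = self._coerce(other)

        def _swap(a):
            return np.swapaxes(a, -1, -2)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, _swap(other.data))
                self.grad += _unbroadcast(ga, self.shape)
            if other.requires_grad:
                gb = np.matmul(_swap(self.data), g)
                other.grad += _unbroadcast(gb, other.shape)

        return self._make(np.matmul(self.data, other.data), (self, other), backward)

    __matmul__ = matmul


# ---------------------------------------------------------------------------
# composite layers
# ---------------------------------------------------------------------------


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Softmax along ``axis`` (max-shifted; the shift carries no gradient)."""
    shifted = x + Tensor(-x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered * (var + eps).pow(-0.5) * gamma + beta


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from logits: softplus(z) - y*z."""
    t = Tensor(np.asarray(targets, dtype=np.float64))
    return (logits.softplus() - t * logits).mean()


def cross_entropy(logits: Tensor, targets: np.ndarray, mask: np.ndarray | None = None) -> Tensor:
    """Mean multiclass cross-entropy over (optionally masked) rows."""
    shifted = logits + Tensor(-logits.data.max(axis=-1, keepdims=True))
    log_z = shifted.exp().sum(axis=-1, keepdims=True).log()
    log_probs = shifted - log_z
    n, k = logits.shape
    onehot = np.zeros((n, k))
    onehot[np.arange(n), np.asarray(targets, dtype=int)] = 1.0
    if mask is not None:
        onehot *= np.asarray(mask, dtype=float)[:, None]
        denom = max(float(np.sum(mask)), 1.0)
    else:
        denom = float(n)
    return -(log_probs * Tensor(onehot)).sum() * (1.0 / denom)


class Adam:
    """Standard Adam with bias correction; operates on Tensor parameters."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = np.zeros_like(p.data)
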