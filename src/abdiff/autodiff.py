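"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine carrying exactly the operations the denoiser
needs: broadcast arithmetic, batched matmul, softmax/log-softmax, GELU,
embedding lookup, gather, reductions and slicing. Gradient correctness is
pinned against central finite differences in the test suite.

float64 throughout; at the toy scales this library targets, clarity and
checkable gradients beat raw throughput.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
from scipy.special import erf


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    # -- autodiff core --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor) -> None:
            stack = [(node, iter(node._parents))]
            seen.add(id(node))
            while stack:
                cur, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(cur)
                    stack.pop()

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:  # leaf
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if not parent.requires_grad:
                        continue
                    key = id(parent)
                    grads[key] = pg if key not in grads else grads[key] + pg

    # -- operations -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            return (
                (self, _unbroadcast(g, self.shape)),
                (other, _unbroadcast(g, other.shape)),
            )

        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            return (
                (self, _unbroadcast(g * other.data, self.shape)),
                (other, _unbroadcast(g * self.data, other.shape)),
            )

        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __pow__(self, exponent: float):
        def bwd(g):
            return ((self, g * exponent * self.data ** (exponent - 1.0)),)

        return Tensor._make(self.data ** exponent, (self,), bwd)

    def matmul(self, other: "Tensor") -> "Tensor":
        def bwd(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return (
                (self, _unbroadcast(ga, self.shape)),
                (other, _unbroadcast(gb, other.shape)),
            )

        return Tensor._make(self.data @ other.data, (self, other), bwd)

    __matmul__ = matmul

    def swapaxes(self, a: int, b: int) -> "Tensor":
        def bwd(g):
            return ((self, np.swapaxes(g, a, b)),)

        return Tensor._make(np.swapaxes(self.data, a, b), (self,), bwd)

    def transpose_last(self) -> "Tensor":
        return self.swapaxes(-1, -2)

    def reshape(self, *shape) -> "Tensor":
        old = self.shape

        def bwd(g):
            return ((self, g.reshape(old)),)

        return Tensor._make(self.data.reshape(*shape), (self,), bwd)

    def __getitem__(self, key) -> "Tensor":
        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return ((self, full),)

        return Tensor._make(self.data[key], (self,), bwd)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bwd(g):
            if axis is None:
                return ((self, np.broadcast_to(g, self.shape).copy()),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return ((self, np.broadcast_to(gg, self.shape).copy()),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bwd(g):
            return ((self, g * out_data),)

        return Tensor._make(out_data, (self,), bwd)

    def log(self) -> "Tensor":
        def bwd(g):
            return ((self, g / self.data),)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def bwd(g):
            return ((self, g * (1.0 - out_data**2)),)

        return Tensor._make(out_data, (self,), bwd)


# -- composite / functional ops ------------------------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        return ((x, out_data * (g - dot)),)

    return Tensor._make(out_data, (x,), bwd)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse

    def bwd(g):
        return ((x, g - np.exp(out_data) * g.sum(axis=axis, keepdims=True)),)

    return Tensor._make(out_data, (x,), bwd)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf) Gaussian error linear unit."""
    cdf = 0.5 * (1.0 + erf(x.data / np.sqrt(2.0)))
    out_data = x.data * cdf

    def bwd(g):
        pdf = np.exp(-0.5 * x.data**2) / np.sqrt(2.0 * np.pi)
        return ((x, g * (cdf + x.data * pdf)),)

    return Tensor._make(out_data, (x,), bwd)


def embedding(table: Tensor, indices: np.ndarray) -> Tensor:
    idx = np.asarray(indices, dtype=np.int64)

    def bwd(g):
        full = np.zeros_like(table.data)
        np.add.at(full, idx, g)
        return ((table, full),)

    return Tensor._make(table.data[idx], (table,), bwd)


def gather_last(x: Tensor, indices: np.ndarray) -> Tensor:
    """Pick one entry along the last axis per leading position."""
    idx = np.asarray(indices, dtype=np.int64)
    picked = np.take_along_axis(x.data, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        full = np.zeros_like(x.data)
        np.put_along_axis(full, idx[..., None], g[..., None], axis=-1)
        return ((x, full),)

    return Tensor._make(picked, (x,), bwd)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis (composite; differentiable)."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    inv = (var + eps) ** -0.5
    return centered * inv * gain + bias


def dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when rng is None (eval mode) or p == 0."""
    if rng is None or p <= 0.0:
        return x
    keep = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(keep)


# -- optimizer -----------------------------------------------------------------

class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 3e-5,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data
            )


def clip_grad_norm(params: Iterable[Tensor], max_norm: float) -> float:
    """Scale gradients so their global L2 norm is at most ``max_norm``."""
    params = [p for p in params if p.grad is not None]
    total = float(np.sqrt(sum(float((p.grad**2).sum()) for p in params)))
    if total > max_norm > 0:
        scale = max_norm / (total + 1e-12)
        for p in params:
            p.grad *= scale
    return total
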