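"""Compact reverse-mode automatic differentiation over numpy arrays.

The denoising network in this package is small (a few hundred thousand
parameters at full size, a few thousand in the reduced configuration used
by the memorization experiment), so a tape-based engine over dense numpy
arrays is fast enough on one CPU and keeps the whole model stack
dependency-light and bit-reproducible.

Only the operations the model actually uses are implemented: broadcasted
arithmetic, (batched) matmul, reshape/transpose, reductions, GELU/SiLU,
softmax/log-softmax and layer normalisation.  Gradients are accumulated
into ``Tensor.grad`` by :meth:`Tensor.backward` via a topological sweep.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "matmul",
    "gelu",
    "silu",
    "softmax",
    "log_softmax",
    "layer_norm",
    "concat_rows",
]

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)
        self._backward = backward

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) tensor with seed 1."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
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
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------------
    # arithmetic
    def __add__(self, other: "Tensor | float") -> "Tensor":
        other = _as_tensor(other)
        out_data = self.data + other.data

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return _node(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(-g)

        return _node(-self.data, (self,), bwd)

    def __sub__(self, other: "Tensor | float") -> "Tensor":
        return self + (-_as_tensor(other))

    def __rsub__(self, other: float) -> "Tensor":
        return _as_tensor(other) + (-self)

    def __mul__(self, other: "Tensor | float") -> "Tensor":
        other = _as_tensor(other)
        out_data = self.data * other.data

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return _node(out_data, (self, other), bwd)

    __rmul__ = __mul__

    # ------------------------------------------------------------------
    # shape ops
    def reshape(self, *shape: int) -> "Tensor":
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return _node(out_data, (self,), bwd)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out_data = np.swapaxes(self.data, a, b)

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(np.swapaxes(g, a, b))

        return _node(out_data, (self,), bwd)

    def transpose(self, *axes: int) -> "Tensor":
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return _node(out_data, (self,), bwd)

    # ------------------------------------------------------------------
    # reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def bwd(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            gg = g
            if not keepdims and axis is not None:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, shape).copy())

        return _node(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def _as_tensor(x: "Tensor | float | np.ndarray") -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _node(data: np.ndarray, parents: tuple[Tensor, ...], bwd) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=parents if req else (),
                  backward=bwd if req else None)


def constant(x: np.ndarray) -> Tensor:
    return Tensor(np.asarray(x, dtype=np.float64))


def parameter(x: np.ndarray) -> Tensor:
    return Tensor(np.asarray(x, dtype=np.float64), requires_grad=True)


# ----------------------------------------------------------------------
def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product with numpy's stacked-batch semantics."""
    out_data = a.data @ b.data

    def bwd(g: np.ndarray) -> None:
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return _node(out_data, (a, b), bwd)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    cdf = 0.5 * (1.0 + erf(x.data * _INV_SQRT2))
    out_data = x.data * cdf

    def bwd(g: np.ndarray) -> None:
        if x.requires_grad:
            pdf = _INV_SQRT2PI * np.exp(-0.5 * x.data * x.data)
            x._accumulate(g * (cdf + x.data * pdf))

    return _node(out_data, (x,), bwd)


def silu(x: Tensor) -> Tensor:
    """SiLU / swish: x * sigmoid(x)."""
    s = 1.0 / (1.0 + np.exp(-x.data))
    out_data = x.data * s

    def bwd(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * (s * (1.0 + x.data * (1.0 - s))))

    return _node(out_data, (x,), bwd)


def softmax(x: Tensor) -> Tensor:
    """Softmax over the last axis."""
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=-1, keepdims=True)

    def bwd(g: np.ndarray) -> None:
        if x.requires_grad:
            dot = (g * y).sum(axis=-1, keepdims=True)
            x._accumulate(y * (g - dot))

    return _node(y, (x,), bwd)


def log_softmax(x: Tensor) -> Tensor:
    """Log-softmax over the last axis (stable)."""
    z = x.data - x.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    y = z - lse

    def bwd(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g - np.exp(y) * g.sum(axis=-1, keepdims=True))

    return _node(y, (x,), bwd)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis with learnable scale/shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gamma.data + beta.data

    def bwd(g: np.ndarray) -> None:
        if gamma.requires_grad:
            gamma._accumulate(_unbroadcast(g * xhat, gamma.data.shape))
        if beta.requires_grad:
            beta._accumulate(_unbroadcast(g, beta.data.shape))
        if x.requires_grad:
            gx = g * gamma.data
            m1 = gx.mean(axis=-1, keepdims=True)
            m2 = (gx * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(inv * (gx - m1 - xhat * m2))

    return _node(out_data, (x, gamma, beta), bwd)


def concat_rows(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate two matrices along the last (feature) axis."""
    na = a.data.shape[-1]
    out_data = np.concatenate([a.data, b.data], axis=-1)

    def bwd(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g[..., :na])
        if b.requires_grad:
            b._accumulate(g[..., na:])

    return _node(out_data, (a, b), bwd)


class Adam:
    """Adaptive-moment optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                g = np.zeros_like(p.data)
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
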