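"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the primitives the denoiser needs — dense matmul, pointwise
nonlinearities, layer normalization, softmax, gather/scatter for message
passing — plus parameter modules and an Adam optimizer with global-norm
gradient clipping.  Gradients flow to parameters only; geometric edge
features enter as constants.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # ------------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, float)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is not None:
                for parent, pg in t._backward(g):
                    if not parent.requires_grad:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg
            else:
                t.grad = g if t.grad is None else t.grad + g

    # -- operators ------------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, as_tensor(other) * -1.0)

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self):
        return tsum(self) * (1.0 / self.data.size)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))
    out._backward = lambda g: ((a, _unbroadcast(g, a.shape)),
                               (b, _unbroadcast(g, b.shape)))
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, parents=(a, b))
    out._backward = lambda g: ((a, _unbroadcast(g * b.data, a.shape)),
                               (b, _unbroadcast(g * a.data, b.shape)))
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, parents=(a, b))

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return ((a, _unbroadcast(ga, a.shape)), (b, _unbroadcast(gb, b.shape)))

    out._backward = backward
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, parents=(a,))
    out._backward = lambda g: ((a, g * mask),)
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(s, parents=(a,))
    out._backward = lambda g: ((a, g * s * (1.0 - s)),)
    return out


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,))

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return ((a, np.broadcast_to(g, a.shape).copy()),)

    out._backward = backward
    return out


def square(a: Tensor) -> Tensor:
    out = Tensor(a.data ** 2, parents=(a,))
    out._backward = lambda g: ((a, 2.0 * g * a.data),)
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    out._backward = backward
    return out


def gather_rows(a: Tensor, index: np.ndarray) -> Tensor:
    """Rows of a 2-D tensor at ``index`` (message-passing source lookup)."""
    index = np.asarray(index, dtype=int)
    out = Tensor(a.data[index], parents=(a,))

    def backward(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, index, g)
        return ((a, ga),)

    out._backward = backward
    return out


def scatter_sum(src: Tensor, index: np.ndarray, n_rows: int) -> Tensor:
    """Sum rows of ``src`` into ``n_rows`` buckets (message aggregation)."""
    index = np.asarray(index, dtype=int)
    data = np.zeros((n_rows,) + src.data.shape[1:])
    np.add.at(data, index, src.data)
    out = Tensor(data, parents=(src,))
    out._backward = lambda g: ((src, g[index]),)
    return out


def layer_norm(a: Tensor, gain: Tensor, bias: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Normalize the last axis to zero mean / unit variance, then affine."""
    mu = a.data.mean(axis=-1, keepdims=True)
    var = a.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (a.data - mu) * inv
    out = Tensor(xhat * gain.data + bias.data, parents=(a, gain, bias))
    d = a.data.shape[-1]

    def backward(g):
        gxhat = g * gain.data
        ga = inv * (gxhat - gxhat.mean(axis=-1, keepdims=True)
                    - xhat * (gxhat * xhat).mean(axis=-1, keepdims=True))
        ggain = _unbroadcast(g * xhat, gain.shape)
        gbias = _unbroadcast(g, bias.shape)
        return ((a, ga), (gain, ggain), (bias, gbias))

    out._backward = backward
    return out


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, parents=(a,))

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        return ((a, s * (g - dot)),)

    out._backward = backward
    return out


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(target)
    return square(diff).mean()


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: Iterable[np.ndarray]) -> None:
        for p, a in zip(self.parameters(), arrays, strict=True):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.array(a, dtype=np.float64)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        scale = 1.0 / math.sqrt(n_in)
        self.w = Tensor(rng.uniform(-scale, scale, (n_in, n_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.w
        return out + self.b if self.b is not None else out


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.bias = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gain, self.bias)


class MultiheadSelfAttention(Module):
    """Unmasked self-attention over all rows (atoms) of the input."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        n, d = x.shape
        q, k, v = self.wq(x), self.wk(x), self.wv(x)
        outs = []
        scale = 1.0 / math.sqrt(self.head_dim)
        for h in range(self.n_heads):
            sl = slice(h * self.head_dim, (h + 1) * self.head_dim)
            qh = slice_cols(q, sl)
            kh = slice_cols(k, sl)
            vh = slice_cols(v, sl)
            att = softmax(matmul(qh, transpose(kh)) * scale, axis=-1)
            outs.append(matmul(att, vh))
        return self.wo(concat(outs, axis=-1))


def slice_cols(a: Tensor, sl: slice) -> Tensor:
    out = Tensor(a.data[:, sl], parents=(a,))

    def backward(g):
        ga = np.zeros_like(a.data)
        ga[:, sl] = g
        return ((a, ga),)

    out._backward = backward
    return out


def transpose(a: Tensor) -> Tensor:
    out = Tensor(a.data.T, parents=(a,))
    out._backward = lambda g: ((a, g.T),)
    return out


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

def clip_grad_norm(params: list[Tensor], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = math.sqrt(sum(float((p.grad ** 2).sum())
                          for p in params if p.grad is not None))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return total


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
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
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
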