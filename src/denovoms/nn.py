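"""A compact reverse-mode autograd engine and transformer layers on numpy.

Scope is deliberately small: exactly the operations the spectrum encoder,
the autoregressive peptide decoder and the diffusion refiner need, each
with a closed-form backward pass (fused softmax, layer norm and
cross-entropy for speed). Everything is float32 and fully seeded.
"""

from __future__ import annotations

import math
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "MultiHeadAttention",
    "TransformerLayer",
    "Adam",
    "softmax",
    "log_softmax_np",
    "cross_entropy_logits",
    "sinusoidal_embedding",
    "positional_encoding",
]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autograd graph wrapping a float32 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: Tuple["Tensor", ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: np.ndarray, own: bool = False) -> None:
        # ``own=True`` promises grad is a fresh array no one else holds,
        # so it can be adopted without a defensive copy
        if self.grad is None:
            if own and grad.dtype == np.float32 and grad.base is None:
                self.grad = grad
            else:
                self.grad = grad.astype(np.float32)  # always copies
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            stack = [(t, False)]
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
                    stack.append((p, False))

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data)
        out._parents = (self, other)

        def bwd(g):
            if self.requires_grad or self._backward:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._backward:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data)
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(-g, own=True)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data)
        out._parents = (self, other)

        def bwd(g):
            if self.requires_grad or self._backward:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape), own=True)
            if other.requires_grad or other._backward:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape), own=True)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * (1.0 / other)

    def __pow__(self, p: float):
        out = Tensor(self.data ** p)
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1.0), own=True)
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data)
        out._parents = (self, other)

        def bwd(g):
            if self.requires_grad or self._backward:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape), own=True)
            if other.requires_grad or other._backward:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape), own=True)

        out._backward = bwd
        return out

    __matmul__ = matmul

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data))
        out._parents = (self,)
        val = out.data  # capture the array, not the node (avoids ref cycles)
        out._backward = lambda g: self._accumulate(g * val, own=True)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data))
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(g / self.data, own=True)
        return out

    def tanh(self) -> "Tensor":
        out = Tensor(np.tanh(self.data))
        out._parents = (self,)
        val = out.data
        out._backward = lambda g: self._accumulate(g * (1.0 - val ** 2), own=True)
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0))
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(g * (self.data > 0), own=True)
        return out

    def gelu(self) -> "Tensor":
        # tanh approximation of GELU
        c = math.sqrt(2.0 / math.pi)
        inner = (Tensor(c) * (self + self * self * self * 0.044715)).tanh()
        return self * 0.5 * (inner + 1.0)

    # -- reductions & shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        out._parents = (self,)

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape))
        out._parents = (self,)
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes) -> "Tensor":
        out = Tensor(self.data.transpose(*axes))
        out._parents = (self,)
        inv = np.argsort(axes)
        out._backward = lambda g: self._accumulate(g.transpose(*inv))
        return out


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def softmax(x: Tensor, axis: int = -1, mask: Optional[np.ndarray] = None) -> Tensor:
    """Softmax with optional additive masking (True = masked out)."""
    data = x.data
    if mask is not None:
        data = np.where(mask, np.float32(-1e9), data)
    shifted = data - data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s)
    out._parents = (x,)

    def bwd(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        gx = s * (g - dot)
        if mask is not None:
            gx = np.where(mask, 0.0, gx)
        x._accumulate(gx, own=True)

    out._backward = bwd
    return out


def log_softmax_np(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable log-softmax on raw arrays (inference paths)."""
    shifted = logits - logits.max(axis=axis, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=axis, keepdims=True))


def cross_entropy_logits(
    logits: Tensor,
    targets: np.ndarray,
    mask: Optional[np.ndarray] = None,
    label_smoothing: float = 0.0,
) -> Tensor:
    """Mean token-level cross-entropy; fused softmax backward.

    logits: (..., V); targets: integer array (...); mask: boolean (...) with
    True = include. With label smoothing eps the target distribution is
    (1-eps) * onehot + eps/V. Returns a scalar Tensor (mean over included
    tokens).
    """
    V = logits.data.shape[-1]
    flat = logits.data.reshape(-1, V)
    tgt = targets.reshape(-1)
    inc = np.ones(tgt.shape, dtype=bool) if mask is None else mask.reshape(-1)
    n = max(int(inc.sum()), 1)
    eps = label_smoothing
    logp = log_softmax_np(flat)
    nll = -logp[np.arange(tgt.size), tgt]
    if eps:
        nll = (1.0 - eps) * nll + eps * (-logp.mean(axis=-1))
    loss_val = float((nll * inc).sum() / n)
    out = Tensor(loss_val)
    out._parents = (logits,)

    def bwd(g):
        p = np.exp(logp)
        p[np.arange(tgt.size), tgt] -= 1.0 - eps
        if eps:
            p -= eps / V
        p *= (inc / n)[:, None] * float(g)
        p.shape = logits.data.shape  # in-place reshape keeps ownership
        logits._accumulate(p, own=True)

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


class Module:
    def parameters(self) -> List[Parameter]:
        params: List[Parameter] = []
        seen = set()
        for value in self.__dict__.values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {str(i): p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = state[str(i)]
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i} shape mismatch: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(np.float32)


def _collect(value) -> Iterable[Parameter]:
    if isinstance(value, Parameter):
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)


class Linear(Module):
    def __init__(
        self,
        d_in: int,
        d_out: int,
        rng: np.random.Generator,
        bias: bool = True,
        init: str = "uniform",
    ):
        scale = math.sqrt(1.0 / d_in)
        w = rng.uniform(-scale, scale, size=(d_in, d_out))
        if init == "identity":  # near-identity start (requires d_in == d_out)
            w = 0.1 * w + np.eye(d_in, d_out)
        self.w = Parameter(w)
        self.b = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.w
        if self.b is not None:
            out = out + self.b
        return out


class Embedding(Module):
    def __init__(self, n: int, dim: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, 0.02, size=(n, dim)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        idx = np.asarray(idx, dtype=np.int64)
        w = self.weight
        out = Tensor(w.data[idx])
        out._parents = (w,)

        def bwd(g):
            gw = np.zeros_like(w.data)
            np.add.at(gw, idx.reshape(-1), g.reshape(-1, w.data.shape[-1]))
            w._accumulate(gw, own=True)

        out._backward = bwd
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.data.mean(axis=-1, keepdims=True)
        var = x.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv
        out = Tensor(xhat * self.gamma.data + self.beta.data)
        out._parents = (x, self.gamma, self.beta)
        d = x.data.shape[-1]

        def bwd(g):
            self.beta._accumulate(g.sum(axis=tuple(range(g.ndim - 1))))
            self.gamma._accumulate((g * xhat).sum(axis=tuple(range(g.ndim - 1))))
            gx_hat = g * self.gamma.data
            gx = (
                gx_hat
                - gx_hat.mean(axis=-1, keepdims=True)
                - xhat * (gx_hat * xhat).mean(axis=-1, keepdims=True)
            ) * inv
            x._accumulate(gx.astype(np.float32), own=True)

        out._backward = bwd
        return out


class MultiHeadAttention(Module):
    """Batched multi-head attention; self- or cross-attention."""

    def __init__(
        self, dim: int, heads: int, rng: np.random.Generator, qk_init: str = "uniform"
    ):
        if dim % heads:
            raise ValueError(f"hidden dim {dim} not divisible by {heads} heads")
        self.heads = heads
        self.dk = dim // heads
        # near-identity q/k start turns the initial attention scores into a
        # matched filter between query and key encodings of the same family
        self.wq = Linear(dim, dim, rng, init=qk_init)
        self.wk = Linear(dim, dim, rng, init=qk_init)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def __call__(
        self,
        x: Tensor,
        context: Optional[Tensor] = None,
        mask: Optional[np.ndarray] = None,
    ) -> Tensor:
        """mask: broadcastable to (B, heads, Tq, Tk); True = disallow."""
        ctx = x if context is None else context
        B, Tq, D = x.shape
        Tk = ctx.shape[1]
        h, dk = self.heads, self.dk

        def split(t: Tensor, T: int) -> Tensor:
            return t.reshape(B, T, h, dk).transpose(0, 2, 1, 3)

        q = split(self.wq(x), Tq)
        k = split(self.wk(ctx), Tk)
        v = split(self.wv(ctx), Tk)
        scores = q @ k.transpose(0, 1, 3, 2) * (1.0 / math.sqrt(dk))
        attn = softmax(scores, axis=-1, mask=mask)
        out = attn @ v  # (B, h, Tq, dk)
        merged = out.transpose(0, 2, 1, 3).reshape(B, Tq, D)
        return self.wo(merged)


class TransformerLayer(Module):
    """Pre-norm transformer block: (optional causal) self-attn,
    optional cross-attn, feed-forward."""

    def __init__(
        self,
        dim: int,
        heads: int,
        ff_dim: int,
        rng: np.random.Generator,
        cross: bool = False,
        cross_qk_init: str = "uniform",
    ):
        self.self_attn = MultiHeadAttention(dim, heads, rng)
        self.norm1 = LayerNorm(dim)
        self.cross_attn = (
            MultiHeadAttention(dim, heads, rng, qk_init=cross_qk_init) if cross else None
        )
        self.norm_cross = LayerNorm(dim) if cross else None
        self.ff1 = Linear(dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, dim, rng)
        self.norm2 = LayerNorm(dim)

    def __call__(
        self,
        x: Tensor,
        self_mask: Optional[np.ndarray] = None,
        context: Optional[Tensor] = None,
        cross_mask: Optional[np.ndarray] = None,
    ) -> Tensor:
        x = x + self.self_attn(self.norm1(x), mask=self_mask)
        if self.cross_attn is not None and context is not None:
            x = x + self.cross_attn(self.norm_cross(x), context=context, mask=cross_mask)
        x = x + self.ff2(self.ff1(self.norm2(x)).gelu())
        return x


class Adam:
    """Adam optimizer (bias-corrected), with optional gradient clipping
    and decoupled weight decay."""

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 3e-4,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        clip_norm: Optional[float] = 1.0,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        if self.clip_norm is not None:
            total = math.sqrt(
                sum(float((p.grad ** 2).sum()) for p in self.params if p.grad is not None)
            )
            scale = self.clip_norm / (total + 1e-12) if total > self.clip_norm else 1.0
        else:
            scale = 1.0
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            step = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and p.data.ndim > 1:  # decay matrices only
                step = step + self.lr * self.weight_decay * p.data
            p.data -= step.astype(np.float32)


# ---------------------------------------------------------------------------
# fixed (non-learned) encodings
# ---------------------------------------------------------------------------


def sinusoidal_embedding(
    values: np.ndarray, dim: int, wavelength_min: float, wavelength_max: float
) -> np.ndarray:
    """Multi-scale sinusoidal encoding of scalar values (m/z, mass, time).

    ``dim/2`` wavelengths are geometrically spaced in
    [wavelength_min, wavelength_max]; each contributes a (sin, cos) pair.
    All components lie in [-1, 1].
    """
    values = np.atleast_1d(np.asarray(values, dtype=np.float64))
    half = dim // 2
    exponents = np.arange(half) / max(half - 1, 1)
    wavelengths = wavelength_min * (wavelength_max / wavelength_min) ** exponents
    phase = 2.0 * np.pi * values[..., None] / wavelengths  # (..., half)
    out = np.empty(values.shape + (dim,), dtype=np.float32)
    out[..., 0::2] = np.sin(phase)
    out[..., 1::2] = np.cos(phase)
    return out


def positional_encoding(length: int, dim: int, base: float = 10000.0) -> np.ndarray:
    """Standard transformer positional encoding, shape (length, dim)."""
    pos = np.arange(length, dtype=np.float64)[:, None]
    half = dim // 2
    freqs = base ** (-np.arange(half) / half)
    phase = pos * freqs
    out = np.empty((length, dim), dtype=np.float32)
    out[:, 0::2] = np.sin(phase)
    out[:, 1::2] = np.cos(phase)
    return out
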