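"""Minimal reverse-mode automatic differentiation on numpy arrays, plus the
layers and optimizer used by the detector.

This is deliberately a small engine, not a framework: float32 throughout,
define-by-run graphs of :class:`Tensor` nodes, each op storing a closure that
accumulates gradients into its parents. Convolution, pooling, upsampling and
the wavelet-LL downsampling are hand-written primitives with explicit
adjoints; everything else (norms, attention, losses) composes from
elementwise ops, matmul and reductions.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

from . import wavelet as _wavelet

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "Conv2d",
    "GroupNorm",
    "LayerNorm",
    "Sequential",
    "ReLU",
    "Adam",
    "relu",
    "sigmoid",
    "softmax",
    "log_softmax",
    "conv2d",
    "maxpool2x",
    "upsample2x",
    "ll_downsample",
    "concat",
    "cross_entropy",
]


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping ----------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray, own: bool = False) -> None:
        # `own=True` donates a freshly allocated array (no aliasing risk),
        # avoiding a copy on the first accumulation.
        if self.grad is None:
            if own and g.dtype == np.float32:
                self.grad = g
            else:
                self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:  # iterative DFS; graphs can be deep
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = _wrap(other)
        out = _node(self.data + other.data, self, other)

        def bw():
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(out.grad, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, self)
        out._backward = lambda: self._accum(-out.grad, own=True)
        return out

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)
        out = _node(self.data * other.data, self, other)

        def bw():
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(out.grad * other.data, self.shape), own=True)
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(out.grad * self.data, other.shape), own=True)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        out = _node(self.data / other.data, self, other)

        def bw():
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(out.grad / other.data, self.shape), own=True)
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(-out.grad * self.data / (other.data**2), other.shape), own=True)

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return _wrap(other) / self

    def __pow__(self, p: float):
        out = _node(self.data**p, self)
        out._backward = lambda: self._accum(out.grad * p * self.data ** (p - 1), own=True)
        return out

    def __matmul__(self, other):
        other = _wrap(other)
        out = _node(np.matmul(self.data, other.data), self, other)

        def bw():
            g = out.grad
            if self.requires_grad or self._parents:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape), own=True)
            if other.requires_grad or other._parents:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape), own=True)

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = _node(self.data[idx], self)

        def bw():
            g = np.zeros_like(self.data)
            np.add.at(g, idx, out.grad)
            self._accum(g)

        out._backward = bw
        return out

    # -- reductions / shaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), self)

        def bw():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy(), own=True)

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _node(self.data.reshape(shape), self)
        out._backward = lambda: self._accum(out.grad.reshape(self.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = _node(self.data.transpose(axes), self)
        out._backward = lambda: self._accum(out.grad.transpose(inv))
        return out

    def exp(self):
        out = _node(np.exp(self.data), self)
        out._backward = lambda: self._accum(out.grad * out.data, own=True)
        return out

    def log(self):
        out = _node(np.log(self.data), self)
        out._backward = lambda: self._accum(out.grad / self.data, own=True)
        return out

    def sqrt(self):
        return self**0.5


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _node(data: np.ndarray, *parents: Tensor) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(p for p in parents if isinstance(p, Tensor))
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that numpy broadcasting expanded."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (gs, ss) in enumerate(zip(g.shape, shape)) if ss == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# --- elementwise / activation ops -------------------------------------------


def relu(x: Tensor) -> Tensor:
    out = _node(np.maximum(x.data, 0.0), x)
    out._backward = lambda: x._accum(out.grad * (x.data > 0), own=True)
    return out


def sigmoid(x: Tensor) -> Tensor:
    out = _node(1.0 / (1.0 + np.exp(-x.data)), x)
    out._backward = lambda: x._accum(out.grad * out.data * (1.0 - out.data), own=True)
    return out


def maximum(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = _node(np.maximum(a.data, b.data), a, b)

    def bw():
        mask = (a.data >= b.data).astype(np.float32)
        a._accum(_unbroadcast(out.grad * mask, a.shape), own=True)
        b._accum(_unbroadcast(out.grad * (1.0 - mask), b.shape), own=True)

    out._backward = bw
    return out


def minimum(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = _node(np.minimum(a.data, b.data), a, b)

    def bw():
        mask = (a.data <= b.data).astype(np.float32)
        a._accum(_unbroadcast(out.grad * mask, a.shape), own=True)
        b._accum(_unbroadcast(out.grad * (1.0 - mask), b.shape), own=True)

    out._backward = bw
    return out


def clamp_min(x: Tensor, lo: float) -> Tensor:
    return maximum(x, Tensor(np.full((), lo, dtype=np.float32)))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = _node(y, x)

    def bw():
        g = out.grad
        x._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)), own=True)

    out._backward = bw
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = _node(z - lse, x)

    def bw():
        g = out.grad
        x._accum(g - np.exp(out.data) * g.sum(axis=axis, keepdims=True), own=True)

    out._backward = bw
    return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), *tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw():
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * out.grad.ndim
            sl[axis] = slice(a, b)
            t._accum(out.grad[tuple(sl)])

    out._backward = bw
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out = _node(np.stack([t.data for t in tensors], axis=axis), *tensors)

    def bw():
        for i, t in enumerate(tensors):
            t._accum(np.take(out.grad, i, axis=axis))

    out._backward = bw
    return out


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """x[(arange(N), idx)] for a 2-D tensor; backward scatters."""
    rows = np.arange(x.shape[0])
    out = _node(x.data[rows, idx], x)

    def bw():
        g = np.zeros_like(x.data)
        np.add.at(g, (rows, idx), out.grad)
        x._accum(g)

    out._backward = bw
    return out


# --- structured primitives ---------------------------------------------------


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int = 0) -> Tensor:
    """NCHW convolution (cross-correlation) with square stride/padding."""
    B, C, H, W = x.shape
    O, C2, kh, kw = w.shape
    assert C == C2, f"channel mismatch {C} vs {C2}"
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    Ho = (xp.shape[2] - kh) // stride + 1
    Wo = (xp.shape[3] - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * kh * kw)
    y = (cols @ w.data.reshape(O, -1).T).reshape(B, Ho, Wo, O).transpose(0, 3, 1, 2)
    if b is not None:
        y = y + b.data[None, :, None, None]
    parents = (x, w) + ((b,) if b is not None else ())
    out = _node(np.ascontiguousarray(y), *parents)

    def bw():
        gy = out.grad  # B,O,Ho,Wo
        gy_cols = gy.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, O)
        if w.requires_grad or w._parents:
            gw = (gy_cols.T @ cols).reshape(O, C, kh, kw)
            w._accum(gw)
        if b is not None:
            b._accum(gy.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            gxp = np.zeros_like(xp)
            for k in range(kh):
                for l in range(kw):
                    # (B,O,Ho,Wo) x (O,C) -> (B,C,Ho,Wo)
                    contrib = np.einsum("bohw,oc->bchw", gy, w.data[:, :, k, l], optimize=True)
                    gxp[:, :, k : k + stride * Ho : stride, l : l + stride * Wo : stride] += contrib
            gx = gxp[:, :, padding : padding + H, padding : padding + W] if padding else gxp
            x._accum(gx)

    out._backward = bw
    return out


def maxpool2x(x: Tensor) -> Tensor:
    B, C, H, W = x.shape
    assert H % 2 == 0 and W % 2 == 0
    r = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H // 2, W // 2, 4)
    idx = r.argmax(axis=-1)
    out = _node(np.take_along_axis(r, idx[..., None], axis=-1)[..., 0], x)

    def bw():
        g = np.zeros((B, C, H // 2, W // 2, 4), dtype=np.float32)
        np.put_along_axis(g, idx[..., None], out.grad[..., None], axis=-1)
        g = g.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H, W)
        x._accum(g)

    out._backward = bw
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour x2 upsampling on the last two axes."""
    out = _node(x.data.repeat(2, axis=-2).repeat(2, axis=-1), x)

    def bw():
        g = out.grad
        B, C, H, W = g.shape
        x._accum(g.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5)))

    out._backward = bw
    return out


def ll_downsample(x: Tensor, filters=None) -> Tensor:
    """Depthwise wavelet LL sub-band of the last two axes (halves resolution).

    The adjoint of LL extraction for an orthonormal filter pair is synthesis
    with zeroed detail bands, which is what the backward pass applies.
    """
    filters = filters or _wavelet.haar_filters()
    out = _node(_wavelet.ll_downsample(x.data, filters).astype(np.float32), x)
    out._backward = lambda: x._accum(
        _wavelet.ll_upsample_adjoint(out.grad.astype(np.float64), filters).astype(np.float32)
    )
    return out


def _normalize_core(xr: np.ndarray, axes: tuple[int, ...], eps: float):
    mu = xr.mean(axis=axes, keepdims=True)
    xc = xr - mu
    var = (xc * xc).mean(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    return xc * inv, inv


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int, eps: float = 1e-5) -> Tensor:
    """Fused group normalization over (C/groups, H, W) slabs of an NCHW tensor."""
    B, C, H, W = x.shape
    g = groups
    xr = x.data.reshape(B, g, -1)
    xn, inv = _normalize_core(xr, (2,), eps)
    xn4 = xn.reshape(B, C, H, W)
    out = _node(xn4 * gamma.data.reshape(1, C, 1, 1) + beta.data.reshape(1, C, 1, 1), x, gamma, beta)

    def bw():
        gy = out.grad
        gamma._accum((gy * xn4).sum(axis=(0, 2, 3)), own=True)
        beta._accum(gy.sum(axis=(0, 2, 3)), own=True)
        dxn = (gy * gamma.data.reshape(1, C, 1, 1)).reshape(B, g, -1)
        m1 = dxn.mean(axis=2, keepdims=True)
        m2 = (dxn * xn).mean(axis=2, keepdims=True)
        dx = (dxn - m1 - xn * m2) * inv
        x._accum(dx.reshape(B, C, H, W), own=True)

    out._backward = bw
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Fused layer normalization over the last axis."""
    xn, inv = _normalize_core(x.data, (-1,), eps)
    out = _node(xn * gamma.data + beta.data, x, gamma, beta)

    def bw():
        gy = out.grad
        red = tuple(range(gy.ndim - 1))
        gamma._accum((gy * xn).sum(axis=red), own=True)
        beta._accum(gy.sum(axis=red), own=True)
        dxn = gy * gamma.data
        m1 = dxn.mean(axis=-1, keepdims=True)
        m2 = (dxn * xn).mean(axis=-1, keepdims=True)
        x._accum((dxn - m1 - xn * m2) * inv, own=True)

    out._backward = bw
    return out


def cross_entropy(logits: Tensor, targets: np.ndarray, class_weights: np.ndarray | None = None) -> Tensor:
    """Mean weighted negative log-likelihood over rows of a (N, C) tensor."""
    logp = log_softmax(logits, axis=-1)
    nll = -gather_rows(logp, targets)
    if class_weights is not None:
        wvec = np.asarray(class_weights, dtype=np.float32)[targets]
        return (nll * Tensor(wvec)).sum() / float(wvec.sum())
    return nll.mean()


# --- modules -----------------------------------------------------------------


class Module:
    """Base class; children/parameters discovered from instance attributes."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def visit(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    visit(v)

        visit(self)
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        seen: set[int] = set()

        def visit(obj, name):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    out.append((name, obj))
            elif isinstance(obj, Module):
                for k, v in vars(obj).items():
                    visit(v, f"{name}.{k}" if name else k)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    visit(v, f"{name}.{i}")
            elif isinstance(obj, dict):
                for k, v in obj.items():
                    visit(v, f"{name}.{k}")

        visit(self, prefix)
        return out

    def num_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.named_parameters():
            p.data = np.asarray(state[k], dtype=np.float32).reshape(p.shape)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True, zero_init: bool = False):
        s = math.sqrt(2.0 / d_in)
        self.w = Parameter(np.zeros((d_in, d_out)) if zero_init else rng.normal(0, s, (d_in, d_out)))
        self.b = Parameter(np.zeros(d_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.w
        return y + self.b if self.b is not None else y


class Conv2d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int | None = None,
        bias: bool = True,
        zero_init: bool = False,
    ):
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        s = math.sqrt(2.0 / (c_in * k * k))
        self.w = Parameter(np.zeros((c_out, c_in, k, k)) if zero_init else rng.normal(0, s, (c_out, c_in, k, k)))
        self.b = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class GroupNorm(Module):
    """Group normalization (batch-size independent; stable for tiny batches)."""

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5):
        self.groups = max(1, min(groups, channels))
        while channels % self.groups:
            self.groups -= 1
        self.eps = eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        return group_norm(x, self.gamma, self.beta, self.groups, self.eps)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return relu(x)


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class MultiheadAttention(Module):
    """Standard softmax attention (used by the decoder and the naive baseline)."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        assert dim % heads == 0
        self.heads = heads
        self.dim = dim
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.o = Linear(dim, dim, rng)

    def forward(self, query: Tensor, key: Tensor, value: Tensor) -> Tensor:
        B, nq, D = query.shape
        nk = key.shape[1]
        h, dh = self.heads, D // self.heads
        q = self.q(query).reshape(B, nq, h, dh).transpose(0, 2, 1, 3)
        k = self.k(key).reshape(B, nk, h, dh).transpose(0, 2, 1, 3)
        v = self.v(value).reshape(B, nk, h, dh).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        attn = softmax(scores, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, nq, D)
        return self.o(out)


class Adam:
    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0, grad_clip: float | None = None):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.grad_clip = grad_clip
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.post_step_hooks: list[Callable[[], None]] = []

    def step(self) -> None:
        self.t += 1
        if self.grad_clip is not None:
            total = math.sqrt(sum(float((p.grad**2).sum()) for p in self.params if p.grad is not None))
            scale = min(1.0, self.grad_clip / (total + 1e-12))
        else:
            scale = 1.0
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad * scale
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
        for hook in self.post_step_hooks:
            hook()

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
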