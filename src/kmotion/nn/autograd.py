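"""A minimal reverse-mode automatic-differentiation engine on numpy arrays.

Just enough machinery to train small convolutional encoder-decoder networks
and a patch discriminator on a CPU: a :class:`Tensor` wrapping a float32
array, a tape of parent links with per-op backward closures, and the
functional ops the models need (conv2d, 2x2 max-pool, nearest upsampling,
channel concat, batch norm, the usual activations, and reductions).

All ops operate on NCHW-shaped tensors where spatial layout matters.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "no_grad",
    "add", "sub", "mul", "neg", "mean", "summation", "absolute", "log",
    "clip", "relu", "leaky_relu", "sigmoid", "concat", "dropout",
    "conv2d", "maxpool2x2", "upsample2x", "batchnorm2d",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference / discriminator detach)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward_fn: Callable[[np.ndarray], tuple] | None = None):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward_fn = backward_fn

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-accumulate gradients from this (scalar or seeded) node."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = grad.astype(np.float32)
        for node in reversed(topo):
            if node._backward_fn is None or node.grad is None:
                continue
            for p, g in zip(node._parents, node._backward_fn(node.grad)):
                if g is None or not p.requires_grad:
                    continue
                g = g.astype(np.float32)
                p.grad = g if p.grad is None else p.grad + g


def _wrap(data: np.ndarray, parents: Sequence[Tensor],
          backward_fn: Callable[[np.ndarray], tuple]) -> Tensor:
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        return Tensor(data, requires_grad=True, parents=parents, backward_fn=backward_fn)
    return Tensor(data)


# ---------------------------------------------------------------------------
# elementwise / reductions


def add(a: Tensor, b: Tensor) -> Tensor:
    return _wrap(a.data + b.data, (a, b), lambda g: (g, g))


def sub(a: Tensor, b: Tensor) -> Tensor:
    return _wrap(a.data - b.data, (a, b), lambda g: (g, -g))


def mul(a: Tensor, b: "Tensor | float") -> Tensor:
    if isinstance(b, Tensor):
        return _wrap(a.data * b.data, (a, b), lambda g: (g * b.data, g * a.data))
    return _wrap(a.data * b, (a,), lambda g: (g * b,))


def neg(a: Tensor) -> Tensor:
    return _wrap(-a.data, (a,), lambda g: (-g,))


def mean(a: Tensor) -> Tensor:
    n = a.data.size
    return _wrap(a.data.mean(), (a,), lambda g: (np.broadcast_to(g / n, a.data.shape),))


def summation(a: Tensor) -> Tensor:
    return _wrap(a.data.sum(), (a,), lambda g: (np.broadcast_to(g, a.data.shape),))


def absolute(a: Tensor) -> Tensor:
    sign = np.sign(a.data)
    return _wrap(np.abs(a.data), (a,), lambda g: (g * sign,))


def log(a: Tensor) -> Tensor:
    return _wrap(np.log(a.data), (a,), lambda g: (g / a.data,))


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    mask = (a.data > lo) & (a.data < hi)
    return _wrap(np.clip(a.data, lo, hi), (a,), lambda g: (g * mask,))


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    return _wrap(a.data * mask, (a,), lambda g: (g * mask,))


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    factor = np.where(a.data > 0, 1.0, slope).astype(np.float32)
    return _wrap(a.data * factor, (a,), lambda g: (g * factor,))


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -30.0, 30.0)))
    return _wrap(s, (a,), lambda g: (g * s * (1.0 - s),))


def concat(a: Tensor, b: Tensor, axis: int = 1) -> Tensor:
    na = a.data.shape[axis]

    def bw(g):
        ga, gb = np.split(g, [na], axis=axis)
        return (ga, gb)

    return _wrap(np.concatenate([a.data, b.data], axis=axis), (a, b), bw)


def dropout(a: Tensor, p: float, rng: np.random.Generator,
            training: bool = True) -> Tensor:
    """Inverted dropout: active only when training, identity otherwise."""
    if not training or p <= 0.0:
        return a
    mask = (rng.random(a.data.shape) >= p).astype(np.float32) / (1.0 - p)
    return _wrap(a.data * mask, (a,), lambda g: (g * mask,))


# ---------------------------------------------------------------------------
# spatial ops (NCHW)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           pad: tuple[int, int, int, int] = (0, 0, 0, 0)) -> Tensor:
    """Cross-correlation of NCHW input with (Cout, Cin, kh, kw) weights.

    ``pad`` is (top, bottom, left, right), allowing the asymmetric padding a
    2x2 kernel needs to preserve spatial size.
    """
    N, C, H, W = x.data.shape
    Co, Ci, kh, kw = w.data.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Ci}")
    pt, pb, pl, pr = pad
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    out = np.einsum("nchwij,ocij->nohw", win, w.data, optimize=True)
    if b is not None:
        out = out + b.data[None, :, None, None]
    Ho, Wo = out.shape[2], out.shape[3]

    def bw(g):
        dw = np.einsum("nchwij,nohw->ocij", win, g, optimize=True)
        db = g.sum(axis=(0, 2, 3)) if b is not None else None
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += \
                    np.einsum("nohw,oc->nchw", g, w.data[:, :, i, j], optimize=True)
        dx = dxp[:, :, pt:pt + H, pl:pl + W]
        return (dx, dw, db) if b is not None else (dx, dw)

    parents = (x, w) if b is None else (x, w, b)
    return _wrap(out, parents, bw)


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; input H, W must be even."""
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2x2 requires even spatial dims, got {H}x{W}")
    win = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = win.reshape(N, C, H // 2, W // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
        dx = dflat.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return (dx.reshape(N, C, H, W),)

    return _wrap(out, (x,), bw)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    N, C, H, W = x.data.shape
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bw(g):
        return (g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)),)

    return _wrap(out, (x,), bw)


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
                running_var: np.ndarray, training: bool, momentum: float = 0.1,
                eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over the (N, H, W) axes.

    In training mode batch statistics are used and the running buffers are
    updated in place; in eval mode the running buffers normalize.
    """
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def bw(g):
        dgamma = (g * xhat).sum(axis=(0, 2, 3))
        dbeta = g.sum(axis=(0, 2, 3))
        dxhat = g * gamma.data[None, :, None, None]
        if training:
            # full backward through the batch statistics
            sum_dxhat = dxhat.sum(axis=(0, 2, 3))
            sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3))
            dx = (inv_std[None, :, None, None] / m) * (
                m * dxhat
                - sum_dxhat[None, :, None, None]
                - xhat * sum_dxhat_xhat[None, :, None, None]
            )
        else:
            dx = dxhat * inv_std[None, :, None, None]
        return (dx, dgamma, dbeta)

    return _wrap(out, (x, gamma, beta), bw)
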