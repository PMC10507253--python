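"""Differentiable building blocks on top of ``autograd``.

Everything here operates on plain numpy arrays (or autograd boxes) and on
nested dict/list parameter *trees*, so losses written with these primitives
can be differentiated with :func:`autograd.grad` and optimised with
:class:`Adam`.  Convolutions use NCHW layout with stride 1 and either
``"valid"`` (no padding) or ``"same"`` zero padding.
"""

from __future__ import annotations

from typing import Callable

import autograd.numpy as anp
import numpy as np

__all__ = [
    "relu",
    "leaky_relu",
    "sigmoid",
    "softmax",
    "dense",
    "conv2d",
    "avg_pool2d",
    "avg_pool_width",
    "bilinear_resize",
    "glorot",
    "tree_map",
    "Adam",
]


def relu(x):
    return anp.maximum(x, 0.0)


def leaky_relu(x, negative_slope: float = 0.01):
    return anp.where(x >= 0, x, negative_slope * x)


def sigmoid(x):
    # tanh form: numerically stable and cheap under autograd
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


def softmax(x, axis: int = -1):
    z = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(z)
    return e / anp.sum(e, axis=axis, keepdims=True)


def dense(x, w, b):
    """Affine map ``x @ w.T + b`` for ``x`` of shape (..., n_in)."""
    return anp.matmul(x, anp.swapaxes(w, -1, -2)) + b


def _same_pad_widths(k: int) -> tuple[int, int]:
    # even kernels pad one less on the leading side (torch convention)
    return (k - 1) // 2, k // 2


def conv2d(x, w, b=None, padding: str = "valid"):
    """Stride-1 2-D cross-correlation.

    Parameters
    ----------
    x : array of shape (B, C_in, H, W)
    w : array of shape (C_out, C_in, kH, kW)
    b : optional bias of shape (C_out,)
    padding : "valid" (no padding) or "same" (zero padding, output spatial
        shape equals input spatial shape)
    """
    if x.ndim != 4 or w.ndim != 4:
        raise ValueError(f"conv2d expects 4-D input/weights, got {x.ndim}-D and {w.ndim}-D")
    if x.shape[1] != w.shape[1]:
        raise ValueError(f"channel mismatch: input has {x.shape[1]}, weights expect {w.shape[1]}")
    n_out, c_in, kh, kw = w.shape
    if padding == "same":
        ph = _same_pad_widths(kh)
        pw = _same_pad_widths(kw)
        x = anp.pad(x, ((0, 0), (0, 0), ph, pw), mode="constant")
    elif padding != "valid":
        raise ValueError(f"unknown padding mode {padding!r}")
    bsz, _, h, wd = x.shape
    ho, wo = h - kh + 1, wd - kw + 1
    if ho < 1 or wo < 1:
        raise ValueError(
            f"input spatial extent {h}x{wd} too small for {kh}x{kw} valid convolution")
    # im2col: one big matmul instead of kh*kw small einsums
    cols = [x[:, :, i:i + ho, j:j + wo] for i in range(kh) for j in range(kw)]
    col = anp.reshape(anp.concatenate(cols, axis=1), (bsz, kh * kw * c_in, ho * wo))
    wf = anp.reshape(anp.reshape(w, (n_out, c_in, kh * kw)).transpose((0, 2, 1)),
                     (n_out, kh * kw * c_in))
    out = anp.reshape(anp.swapaxes(anp.matmul(anp.swapaxes(col, 1, 2), wf.T), 1, 2),
                      (bsz, n_out, ho, wo))
    if b is not None:
        out = out + anp.reshape(b, (1, n_out, 1, 1))
    return out


def avg_pool2d(x, window: tuple[int, int] = (2, 2)):
    """Non-overlapping average pooling; window is clipped to the spatial
    extent and trailing remainders are dropped (floor mode)."""
    if x.ndim != 4:
        raise ValueError("avg_pool2d expects 4-D NCHW input")
    wh = min(window[0], x.shape[2])
    ww = min(window[1], x.shape[3])
    ho = x.shape[2] // wh
    wo = x.shape[3] // ww
    if ho < 1 or wo < 1:
        raise ValueError("pooling window larger than input")
    x = x[:, :, : ho * wh, : wo * ww]
    x = anp.reshape(x, (x.shape[0], x.shape[1], ho, wh, wo, ww))
    return anp.mean(anp.mean(x, axis=5), axis=3)


def avg_pool_width(x, factor: int):
    """Average pooling along the last axis only, ceil mode (a trailing
    partial window is averaged over its actual length)."""
    if factor < 1:
        raise ValueError("pooling factor must be >= 1")
    w = x.shape[-1]
    if factor > w:
        raise ValueError(f"pooling factor {factor} exceeds spatial extent {w}")
    if w % factor == 0:
        out = anp.reshape(x, x.shape[:-1] + (w // factor, factor))
        return anp.mean(out, axis=-1)
    n_out = -(-w // factor)
    segs = [anp.mean(x[..., k * factor: min((k + 1) * factor, w)], axis=-1)
            for k in range(n_out)]
    return anp.stack(segs, axis=-1)


def _resize_axis(x, n_out: int, axis: int):
    n_in = x.shape[axis]
    if n_in == n_out:
        return x
    # interpolation as a constant (n_in, n_out) matrix so the VJP is a matmul
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    lo0 = np.floor(src)
    frac = src - lo0
    lo = np.clip(lo0.astype(int), 0, n_in - 1)
    hi = np.clip(lo0.astype(int) + 1, 0, n_in - 1)
    interp = np.zeros((n_in, n_out))
    np.add.at(interp, (lo, np.arange(n_out)), 1.0 - frac)
    np.add.at(interp, (hi, np.arange(n_out)), frac)
    out = anp.matmul(anp.moveaxis(x, axis, -1), interp)
    return anp.moveaxis(out, -1, axis)


def bilinear_resize(x, out_h: int, out_w: int):
    """Separable bilinear interpolation of the two trailing spatial axes,
    half-pixel-centres convention (align_corners=False) with edge clamping."""
    if x.ndim != 4:
        raise ValueError("bilinear_resize expects 4-D NCHW input")
    return _resize_axis(_resize_axis(x, out_h, 2), out_w, 3)


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Glorot-uniform initialisation; for conv kernels the fan counts the
    receptive field."""
    if len(shape) == 2:
        fan_in, fan_out = shape[1], shape[0]
    elif len(shape) == 4:
        rf = shape[2] * shape[3]
        fan_in, fan_out = shape[1] * rf, shape[0] * rf
    else:
        fan_in = fan_out = int(np.prod(shape))
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def tree_map(fn: Callable, *trees):
    """Apply ``fn`` leafwise over parallel nested dict/list/tuple trees."""
    first = trees[0]
    if isinstance(first, dict):
        return {k: tree_map(fn, *(t[k] for t in trees)) for k in first}
    if isinstance(first, (list, tuple)):
        return type(first)(tree_map(fn, *parts) for parts in zip(*trees))
    return fn(*trees)


class Adam:
    """Adam optimiser over nested parameter trees (functional: ``step``
    returns the updated tree)."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self._m = None
        self._v = None
        self._t = 0

    def step(self, params, grads):
        if self._m is None:
            self._m = tree_map(np.zeros_like, params)
            self._v = tree_map(np.zeros_like, params)
        self._t += 1
        t, b1, b2 = self._t, self.beta1, self.beta2
        self._m = tree_map(lambda m, g: b1 * m + (1 - b1) * g, self._m, grads)
        self._v = tree_map(lambda v, g: b2 * v + (1 - b2) * g * g, self._v, grads)
        scale = self.lr * np.sqrt(1 - b2 ** t) / (1 - b1 ** t)

        def upd(p, m, v):
            return p - scale * m / (np.sqrt(v) + self.eps)

        return tree_map(upd, params, self._m, self._v)
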