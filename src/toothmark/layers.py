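"""Functional neural-network layers on top of the autodiff engine.

Layers are *functional*: parameters live in a flat ``dict[str, Tensor]``
owned by the caller and are passed to every application.  This makes the
MAML inner loop trivial — an adapted parameter set is just another dict —
and keeps optimizers decoupled from model structure.

Convolutions are lowered to gather + matmul (im2col); the gather indices
are cached per geometry.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "he_init",
    "dense",
    "conv2d",
    "depthwise_conv2d",
    "separable_conv2d",
    "avg_pool2d",
    "global_avg_pool",
    "batch_norm",
    "dropout",
    "se_recalibrate",
    "conv2d_indices",
]


def he_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


# ---------------------------------------------------------------------------
# index plumbing for im2col convolutions (stride 1, 'same' padding)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _spatial_indices(h: int, w: int, k: int) -> np.ndarray:
    """(h*w, k*k) flat spatial indices into an h×w map; -1 marks padding."""
    pad = k // 2
    rows = np.arange(h)[:, None, None, None] + np.arange(k)[None, None, :, None] - pad
    cols = np.arange(w)[None, :, None, None] + np.arange(k)[None, None, None, :] - pad
    rows = np.broadcast_to(rows, (h, w, k, k))
    cols = np.broadcast_to(cols, (h, w, k, k))
    valid = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    flat = rows * w + cols
    return np.where(valid, flat, -1).reshape(h * w, k * k)


@lru_cache(maxsize=64)
def conv2d_indices(n: int, c: int, h: int, w: int, k: int) -> np.ndarray:
    """Gather indices of shape (n*h*w, c*k*k) into a flattened NCHW array."""
    sp = _spatial_indices(h, w, k)  # (P, k*k)
    p = h * w
    chan = np.arange(c) * p  # channel offsets
    # (P, c, k*k): spatial index + channel offset, padding stays -1
    per_img = np.where(sp[:, None, :] >= 0, sp[:, None, :] + chan[None, :, None], -1)
    per_img = per_img.reshape(p, c * k * k)
    img_off = (np.arange(n) * (c * p))[:, None, None]
    full = np.where(per_img[None] >= 0, per_img[None] + img_off, -1)
    return full.reshape(n * p, c * k * k)


@lru_cache(maxsize=64)
def _depthwise_indices(n: int, c: int, h: int, w: int, k: int) -> np.ndarray:
    """Gather indices of shape (n*c*h*w, k*k) for per-channel convolution."""
    sp = _spatial_indices(h, w, k)  # (P, k*k)
    p = h * w
    off = (np.arange(n * c) * p)[:, None, None]
    full = np.where(sp[None] >= 0, sp[None] + off, -1)
    return full.reshape(n * c * p, k * k)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def dense(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x: (n, d_in); w: (d_out, d_in); b: (d_out,)."""
    return ad.add(ad.matmul(x, ad.transpose(w)), b)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Standard convolution, stride 1, 'same' padding.

    x: (n, c, h, w); w: (f, c, k, k); b: (f,).
    """
    n, c, h, wd = x.shape
    f, cw, k, _ = w.shape
    if cw != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {cw}")
    idx = conv2d_indices(n, c, h, wd, k)
    col = ad.reshape(ad.gather(x, idx), (n * h * wd, c * k * k))
    w2 = ad.reshape(w, (f, c * k * k))
    out = ad.add(ad.matmul(col, ad.transpose(w2)), b)  # (n*p, f)
    out = ad.reshape(out, (n, h, wd, f))
    return ad.transpose(out, (0, 3, 1, 2))


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Per-channel spatial convolution, stride 1, 'same' padding.

    x: (n, c, h, w); w: (c, k, k); b: (c,).
    """
    n, c, h, wd = x.shape
    cw, k, _ = w.shape
    if cw != c:
        raise ValueError(f"depthwise channel mismatch: input {c}, weight {cw}")
    idx = _depthwise_indices(n, c, h, wd, k)
    col = ad.reshape(ad.gather(x, idx), (n, c, h * wd, k * k))
    wk = ad.reshape(w, (1, c, 1, k * k))
    out = ad.sum_(ad.mul(col, wk), axis=3)  # (n, c, p)
    out = ad.add(out, ad.reshape(b, (1, c, 1)))
    return ad.reshape(out, (n, c, h, wd))


def separable_conv2d(
    x: Tensor, w_dw: Tensor, b_dw: Tensor, w_pw: Tensor, b_pw: Tensor
) -> Tensor:
    """Depthwise-separable convolution: depthwise k×k then pointwise 1×1.

    w_pw: (f, c) pointwise mixing matrix.
    """
    y = depthwise_conv2d(x, w_dw, b_dw)
    n, c, h, wd = y.shape
    f = w_pw.shape[0]
    flat = ad.reshape(ad.transpose(ad.reshape(y, (n, c, h * wd)), (0, 2, 1)), (n * h * wd, c))
    out = ad.add(ad.matmul(flat, ad.transpose(w_pw)), b_pw)
    out = ad.reshape(out, (n, h * wd, f))
    return ad.reshape(ad.transpose(out, (0, 2, 1)), (n, f, h, wd))


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"avg_pool2d: spatial dims {(h, w)} not divisible by {k}")
    y = ad.reshape(x, (n, c, h // k, k, w // k, k))
    return ad.mean_(y, axis=(3, 5))


def global_avg_pool(x: Tensor) -> Tensor:
    """(n, c, h, w) -> (n, c) channel means."""
    return ad.mean_(x, axis=(2, 3))


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running: dict | None,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
    update_running: bool = True,
) -> Tensor:
    """Batch normalization over the batch (and spatial dims for 4-D input).

    ``running`` holds plain-ndarray ``mean``/``var`` side state; it is only
    mutated when ``training and update_running`` (MAML inner loops adapt on
    current-batch statistics without touching running estimates).
    """
    axes = (0,) if x.ndim == 2 else (0, 2, 3)
    pshape = (1, -1) if x.ndim == 2 else (1, -1, 1, 1)
    if training:
        mu = ad.mean_(x, axis=axes, keepdims=True)
        var = ad.mean_(ad.pow_const(ad.sub(x, mu), 2), axis=axes, keepdims=True)
        if running is not None and update_running:
            running["mean"] = (1 - momentum) * running["mean"] + momentum * mu.data.ravel()
            running["var"] = (1 - momentum) * running["var"] + momentum * var.data.ravel()
    else:
        mu = Tensor(running["mean"].reshape(pshape))
        var = Tensor(running["var"].reshape(pshape))
    xhat = ad.div(ad.sub(x, mu), ad.sqrt(ad.add(var, Tensor(eps))))
    return ad.add(ad.mul(xhat, ad.reshape(gamma, pshape)), ad.reshape(beta, pshape))


def dropout(x: Tensor, p: float, training: bool, rng: np.random.Generator) -> Tensor:
    if not training or p <= 0:
        return x
    keep = 1.0 - p
    mask = Tensor((rng.random(x.shape) < keep) / keep)
    return ad.mul(x, mask)


def se_recalibrate(x: Tensor, w1: Tensor, b1: Tensor, w2: Tensor, b2: Tensor) -> Tensor:
    """Squeeze-and-excitation channel gating.

    Gates are sigmoid(W2·ReLU(W1·GAP(x))) in (0,1)^c, applied channelwise;
    the feature-map shape is preserved.
    """
    n, c = x.shape[0], x.shape[1]
    s = global_avg_pool(x)  # (n, c)
    z = ad.relu(dense(s, w1, b1))
    g = ad.sigmoid(dense(z, w2, b2))  # (n, c)
    return ad.mul(x, ad.reshape(g, (n, c, 1, 1)))
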