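"""Stateless differentiable operations composed from autograd primitives."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concatenate, maximum, minimum


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - x.max(axis=axis, keepdims=True).detach()
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def silu(x: Tensor) -> Tensor:
    return x * x.sigmoid()


def gelu(x: Tensor) -> Tensor:
    # tanh approximation; smooth enough for gradient checks at 1e-4 step
    c = float(np.sqrt(2.0 / np.pi))
    return 0.5 * x * (1.0 + (c * (x + 0.044715 * x * x * x)).tanh())


def softplus(x: Tensor) -> Tensor:
    return maximum(x, 0.0) + (1.0 + (-abs_(x)).exp()).log()


def abs_(x: Tensor) -> Tensor:
    return maximum(x, -x)


def binary_cross_entropy_with_logits(
    logits: Tensor,
    targets: np.ndarray,
    pos_weight: float | np.ndarray = 1.0,
    weight: np.ndarray | None = None,
) -> Tensor:
    """Numerically stable BCE on raw logits, mean-reduced.

    ``pos_weight`` multiplies the positive-target term (the detector keeps it
    at 1 by default); ``weight`` is an optional per-element multiplier used
    for class-balanced losses.
    """
    t = np.asarray(targets, dtype=np.float32)
    # log(1+exp(-|x|)) + max(x,0) - x*t  with pos_weight on the t-term
    loss = softplus(-abs_(logits)) + maximum(logits, 0.0) - logits * t
    if np.any(np.asarray(pos_weight) != 1.0):
        pw = 1.0 + (np.asarray(pos_weight, dtype=np.float32) - 1.0) * t
        loss = loss * pw
    if weight is not None:
        loss = loss * np.asarray(weight, dtype=np.float32)
    return loss.mean()


def upsample2x_nearest(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of an (N, C, H, W) map."""
    h, w = x.shape[-2], x.shape[-1]
    rows = np.repeat(np.arange(h), 2)
    cols = np.repeat(np.arange(w), 2)
    return x[:, :, rows][:, :, :, cols]


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C, 1, 1)."""
    return x.mean(axis=(2, 3), keepdims=True)


def global_max_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C, 1, 1)."""
    return x.max(axis=2, keepdims=True).max(axis=3, keepdims=True)


def bilinear_sample(feat: Tensor, points: Tensor) -> Tensor:
    """Sample an (N, C, H, W) map at normalized points (N, P, 2) in [-1, 1].

    Points use (x, y) order with -1 mapping to column/row 0 and +1 to the last
    column/row (align-corners convention).  Out-of-range points clamp to the
    border.  Differentiable with respect to both the feature map and the
    sampling locations; returns (N, P, C).
    """
    n, c, h, w = feat.shape
    px = (points[:, :, 0] + 1.0) * ((w - 1) / 2.0)
    py = (points[:, :, 1] + 1.0) * ((h - 1) / 2.0)
    # clamp keeps the gather legal; gradients outside the grid vanish, which
    # is the correct subgradient of the clamped sampler
    px = minimum(maximum(px, 0.0), float(w - 1))
    py = minimum(maximum(py, 0.0), float(h - 1))
    x0 = np.floor(px.data).astype(np.int64)
    y0 = np.floor(py.data).astype(np.int64)
    x0 = np.minimum(x0, w - 2) if w > 1 else x0
    y0 = np.minimum(y0, h - 2) if h > 1 else y0
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    wx = (px - x0.astype(np.float32)).reshape(n, -1, 1)
    wy = (py - y0.astype(np.float32)).reshape(n, -1, 1)

    flat = feat.transpose(0, 2, 3, 1).reshape(n, h * w, c)
    b_idx = np.arange(n)[:, None]
    v00 = flat[b_idx, y0 * w + x0]
    v01 = flat[b_idx, y0 * w + x1]
    v10 = flat[b_idx, y1 * w + x0]
    v11 = flat[b_idx, y1 * w + x1]
    one = 1.0
    return (
        v00 * ((one - wx) * (one - wy))
        + v01 * (wx * (one - wy))
        + v10 * ((one - wx) * wy)
        + v11 * (wx * wy)
    )


def im2col_indices(c: int, kh: int, kw: int, oh: int, ow: int, stride: int):
    """Index arrays turning a padded (N,C,H,W) map into (N, C*kh*kw, oh*ow)."""
    i0 = np.tile(np.repeat(np.arange(kh), kw), c)
    j0 = np.tile(np.arange(kw), kh * c)
    i1 = stride * np.repeat(np.arange(oh), ow)
    j1 = stride * np.tile(np.arange(ow), oh)
    i = i0[:, None] + i1[None, :]
    j = j0[:, None] + j1[None, :]
    k = np.repeat(np.arange(c), kh * kw)[:, None]
    return k, i, j


def concat(tensors, axis=0):
    return concatenate(tensors, axis=axis)
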