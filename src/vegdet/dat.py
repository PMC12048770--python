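"""Deformable Attention Transformer (DAT) feature extractor.

A four-stage pyramid: a 4x4/stride-4 patch embedding, then stages whose
blocks use (shifted-)window local self-attention in stages 1–2 and
alternate window attention with *deformable* attention in stages 3–4.
Deformable attention replaces the fixed key/value grid with sampling
points deformed by a small query-conditioned offset network, letting the
later stages model long-range structure at a fraction of the cost of
global attention.

All blocks are pre-norm transformer blocks with an MLP; spatial extent
halves between stages while channel width doubles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import functional as F


@dataclass
class DATConfig:
    embed_dim: int = 32
    stage_depths: tuple[int, int, int, int] = (1, 1, 2, 2)
    heads_per_stage: tuple[int, int, int, int] = (2, 4, 8, 8)
    window_size: int = 4
    offset_groups: int = 1
    offset_range_factor: float = 0.5
    mlp_ratio: float = 2.0
    rpb_table_size: int = 9

    def __post_init__(self):
        for heads in self.heads_per_stage:
            if heads % self.offset_groups:
                raise ValueError("offset_groups must divide every head count")


def _to_tokens(x: nn.Tensor) -> nn.Tensor:
    n, c, h, w = x.shape
    return x.transpose(0, 2, 3, 1).reshape(n, h * w, c)


def _to_map(t: nn.Tensor, h: int, w: int) -> nn.Tensor:
    n, _, c = t.shape
    return t.reshape(n, h, w, c).transpose(0, 3, 1, 2)


class PatchEmbed(nn.Module):
    """4x4 non-overlapping convolution with stride 4, then layer norm."""

    def __init__(self, in_channels: int, embed_dim: int):
        super().__init__()
        self.proj = nn.Conv2d(in_channels, embed_dim, 4, stride=4)
        self.norm = nn.LayerNorm(embed_dim)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        n, c, h, w = x.shape
        pad_h = (-h) % 4
        pad_w = (-w) % 4
        if pad_h or pad_w:
            x = _pad_map(x, pad_h, pad_w)
        y = self.proj(x)
        _, cc, oh, ow = y.shape
        return _to_map(self.norm(_to_tokens(y)), oh, ow)


def _pad_map(x: nn.Tensor, pad_h: int, pad_w: int) -> nn.Tensor:
    n, c, h, w = x.shape
    if pad_h:
        zeros = nn.Tensor(np.zeros((n, c, pad_h, w), dtype=np.float32))
        x = nn.concatenate([x, zeros], axis=2)
    if pad_w:
        zeros = nn.Tensor(np.zeros((n, c, x.shape[2], pad_w), dtype=np.float32))
        x = nn.concatenate([x, zeros], axis=3)
    return x


def _window_mask(hp: int, wp: int, h: int, w: int, window: int, shift: int) -> np.ndarray | None:
    """Swin-style additive mask blocking cross-region and padded attention.

    Returns (num_windows, 1, T, T) with 0 where attention is allowed and a
    large negative value elsewhere, or None when no masking is needed.
    """
    if shift == 0 and hp == h and wp == w:
        return None
    labels = np.zeros((hp, wp), dtype=np.int64)
    if shift > 0:
        cnt = 0
        for hs in (slice(0, hp - window), slice(hp - window, hp - shift), slice(hp - shift, hp)):
            for ws in (slice(0, wp - window), slice(wp - window, wp - shift), slice(wp - shift, wp)):
                labels[hs, ws] = cnt
                cnt += 1
    labels[h:, :] = 99  # padded rows/cols get an isolated label
    labels[:, w:] = 99
    if shift > 0:
        labels = np.roll(labels, (-shift, -shift), axis=(0, 1))
    nh, nw = hp // window, wp // window
    win = labels.reshape(nh, window, nw, window).transpose(0, 2, 1, 3).reshape(-1, window * window)
    diff = win[:, :, None] != win[:, None, :]
    if not diff.any():
        return None
    return np.where(diff, np.float32(-1e9), np.float32(0.0))[:, None, :, :]


class WindowSelfAttention(nn.Module):
    """Multi-head self-attention inside non-overlapping (optionally shifted) windows."""

    def __init__(self, dim: int, window_size: int, heads: int, shift: int = 0):
        super().__init__()
        if dim % heads:
            raise ValueError("heads must divide dim")
        if shift not in (0, window_size // 2):
            raise ValueError("shift must be 0 or window_size//2")
        self.dim = dim
        self.window_size = window_size
        self.heads = heads
        self.shift = shift
        self.qkv = nn.Linear(dim, 3 * dim)
        self.proj = nn.Linear(dim, dim)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        n, c, h, w = x.shape
        ws = self.window_size
        hp, wp = h + (-h) % ws, w + (-w) % ws
        shift = self.shift if min(hp, wp) > ws else 0  # single window: shift is moot
        xm = _pad_map(x, hp - h, wp - w)
        if shift:
            xm = xm.roll((-shift, -shift), (2, 3))
        nh, nw = hp // ws, wp // ws
        t = xm.transpose(0, 2, 3, 1)  # (n, hp, wp, c)
        t = t.reshape(n, nh, ws, nw, ws, c).transpose(0, 1, 3, 2, 4, 5)
        t = t.reshape(n * nh * nw, ws * ws, c)
        dh = c // self.heads
        tt = t.shape[1]
        qkv = self.qkv(t).reshape(-1, tt, 3, self.heads, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]
        logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
        nn.add_macs(2 * n * nh * nw * self.heads * tt * tt * dh)
        mask = _window_mask(hp, wp, h, w, ws, shift)
        if mask is not None:
            logits = logits + np.tile(mask, (n, 1, 1, 1))
        attn = F.softmax(logits, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(n * nh * nw, tt, c)
        out = self.proj(out)
        out = out.reshape(n, nh, nw, ws, ws, c).transpose(0, 1, 3, 2, 4, 5)
        out = out.reshape(n, hp, wp, c).transpose(0, 3, 1, 2)
        if shift:
            out = out.roll((shift, shift), (2, 3))
        if hp != h or wp != w:
            out = out[:, :, :h, :w]
        return out


def reference_grid(s_h: int, s_w: int) -> np.ndarray:
    """Uniform (s_h*s_w, 2) grid of normalized (x, y) points spanning [-1, 1]."""
    xs = np.linspace(-1.0, 1.0, s_w, dtype=np.float32) if s_w > 1 else np.zeros(1, np.float32)
    ys = np.linspace(-1.0, 1.0, s_h, dtype=np.float32) if s_h > 1 else np.zeros(1, np.float32)
    gx, gy = np.meshgrid(xs, ys)
    return np.stack([gx.ravel(), gy.ravel()], axis=-1)


class DeformableAttention(nn.Module):
    """Scaled-dot-product attention over bilinearly sampled deformed points.

    Queries come from every spatial position; a depthwise-separable offset
    network predicts, per reference point, a tanh-squashed displacement
    scaled by ``offset_range_factor``.  Keys/values are projections of the
    feature map sampled at reference+offset, and a continuous relative
    position bias table (bilinearly interpolated, zero-initialized) is added
    to the logits.
    """

    def __init__(
        self,
        dim: int,
        heads: int = 4,
        offset_range_factor: float = 0.5,
        offset_groups: int = 1,
        sample_stride: int = 2,
        rpb_table_size: int = 9,
    ):
        super().__init__()
        if dim % heads:
            raise ValueError("heads must divide dim")
        if offset_groups != 1:
            raise ValueError("only offset_groups=1 is implemented")
        self.dim = dim
        self.heads = heads
        self.offset_range_factor = float(offset_range_factor)
        self.sample_stride = sample_stride
        self.q_proj = nn.Linear(dim, dim)
        self.k_proj = nn.Linear(dim, dim)
        self.v_proj = nn.Linear(dim, dim)
        self.out_proj = nn.Linear(dim, dim)
        self.offset_dw = nn.Conv2d(dim, dim, 3, stride=sample_stride, padding=1, groups=dim)
        self.offset_pw = nn.Conv2d(dim, 2, 1)
        # small init keeps early sampling near the reference grid without
        # silencing gradients into the depthwise stage
        self.offset_pw.weight.data *= 0.01
        b = rpb_table_size
        self.rpb = nn.Parameter(np.zeros((1, heads, b, b), dtype=np.float32))

    def sampling_points(self, x: nn.Tensor) -> tuple[nn.Tensor, np.ndarray]:
        """Deformed sampling points (N, P, 2) and the fixed reference grid."""
        n, c, h, w = x.shape
        q_map = x
        raw = self.offset_pw(F.gelu(self.offset_dw(q_map)))  # (N, 2, sh, sw)
        _, _, sh, sw = raw.shape
        offsets = raw.tanh() * self.offset_range_factor
        offsets = offsets.reshape(n, 2, sh * sw).transpose(0, 2, 1)  # (N, P, 2) as (x, y)
        ref = reference_grid(sh, sw)
        return offsets + ref, ref

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        n, c, h, w = x.shape
        tokens = _to_tokens(x)
        dh = c // self.heads
        q = self.q_proj(tokens).reshape(n, h * w, self.heads, dh).transpose(0, 2, 1, 3)
        points, _ = self.sampling_points(x)
        p = points.shape[1]
        sampled = F.bilinear_sample(x, points)  # (N, P, C)
        k = self.k_proj(sampled).reshape(n, p, self.heads, dh).transpose(0, 2, 1, 3)
        v = self.v_proj(sampled).reshape(n, p, self.heads, dh).transpose(0, 2, 1, 3)
        logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
        nn.add_macs(2 * n * self.heads * h * w * p * dh)
        logits = logits + self._position_bias(points, h, w)
        attn = F.softmax(logits, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(n, h * w, c)
        return self.out_proj(out)

    def _position_bias(self, points: nn.Tensor, h: int, w: int) -> nn.Tensor:
        """Continuous relative position bias between queries and sampled points."""
        n, p, _ = points.shape
        qpos = reference_grid(h, w)  # (L, 2)
        l = qpos.shape[0]
        delta = points.reshape(n, 1, p, 2) - qpos.reshape(1, l, 1, 2)
        # displacements live in [-2, 2]; halve to index the table in [-1, 1]
        table = self.rpb[np.zeros(n, dtype=np.int64)]
        bias = F.bilinear_sample(table, delta.reshape(n, l * p, 2) * 0.5)
        return bias.reshape(n, l, p, self.heads).transpose(0, 3, 1, 2)


class TransformerMLP(nn.Module):
    def __init__(self, dim: int, ratio: float):
        super().__init__()
        hidden = max(int(dim * ratio), 1)
        self.fc1 = nn.Linear(dim, hidden)
        self.fc2 = nn.Linear(hidden, dim)

    def forward(self, t: nn.Tensor) -> nn.Tensor:
        return self.fc2(F.gelu(self.fc1(t)))


class AttentionBlock(nn.Module):
    """Pre-norm residual block: x + Attn(LN(x)); x + MLP(LN(x))."""

    def __init__(self, dim: int, attn: nn.Module, mlp_ratio: float = 2.0):
        super().__init__()
        self.dim = dim
        self.norm1 = nn.LayerNorm(dim)
        self.attn = attn
        self.norm2 = nn.LayerNorm(dim)
        self.mlp = TransformerMLP(dim, mlp_ratio)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        n, c, h, w = x.shape
        t = _to_tokens(x)
        normed = _to_map(self.norm1(t), h, w)
        a = self.attn(normed)
        if isinstance(a, nn.Tensor) and a.ndim == 4:
            a = _to_tokens(a)
        t = t + a
        t = t + self.mlp(self.norm2(t))
        return _to_map(t, h, w)


def window_block(dim: int, window: int, heads: int, shift: int, mlp_ratio: float = 2.0) -> AttentionBlock:
    return AttentionBlock(dim, WindowSelfAttention(dim, window, heads, shift), mlp_ratio)


def deformable_block(
    dim: int,
    heads: int,
    offset_range_factor: float = 0.5,
    mlp_ratio: float = 2.0,
    rpb_table_size: int = 9,
) -> AttentionBlock:
    return AttentionBlock(
        dim,
        DeformableAttention(dim, heads, offset_range_factor, rpb_table_size=rpb_table_size),
        mlp_ratio,
    )


class DATBackbone(nn.Module):
    """Four-stage DAT pyramid returning one feature map per stage."""

    def __init__(self, cfg: DATConfig | None = None, in_channels: int = 3):
        super().__init__()
        self.cfg = cfg = cfg or DATConfig()
        dims = [cfg.embed_dim * (2**i) for i in range(4)]
        self.dims = dims
        self.patch_embed = PatchEmbed(in_channels, dims[0])
        self.stages = nn.ModuleList()
        self.downsamples = nn.ModuleList()
        for i in range(4):
            blocks = nn.ModuleList()
            for d in range(cfg.stage_depths[i]):
                if i < 2:
                    shift = 0 if d % 2 == 0 else cfg.window_size // 2
                    blocks.append(
                        window_block(dims[i], cfg.window_size, cfg.heads_per_stage[i], shift, cfg.mlp_ratio)
                    )
                else:
                    # later stages alternate local window and deformable blocks
                    if d % 2 == 0:
                        blocks.append(
                            window_block(dims[i], cfg.window_size, cfg.heads_per_stage[i], 0, cfg.mlp_ratio)
                        )
                    else:
                        blocks.append(
                            deformable_block(
                                dims[i],
                                cfg.heads_per_stage[i],
                                cfg.offset_range_factor,
                                cfg.mlp_ratio,
                                cfg.rpb_table_size,
                            )
                        )
            self.stages.append(nn.Sequential(blocks))
            if i < 3:
                self.downsamples.append(nn.Conv2d(dims[i], dims[i + 1], 2, stride=2))

    def forward(self, image: nn.Tensor) -> list[nn.Tensor]:
        x = image if isinstance(image, nn.Tensor) else nn.Tensor(image)
        x = self.patch_embed(x)
        outs = []
        for i in range(4):
            x = self.stages[i](x)
            outs.append(x)
            if i < 3:
                x = self.downsamples[i](x)
        return outs


def dat_forward(image, cfg: DATConfig | None = None) -> list[nn.Tensor]:
    """Run a freshly initialized DAT backbone over an image (convenience)."""
    return DATBackbone(cfg)(image)
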