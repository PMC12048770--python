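"""Channel–Spatial Adaptive Attention Module (CSAAM).

The block refines a feature map in two gated steps and a residual fusion:

    Xc  = Yc(X)  ⊙ X      channel gate, Yc ∈ (0,1)^{C×1×1}
    Xcs = Ys(Xc) ⊙ Xc     spatial gate, Ys ∈ (0,1)^{1×H×W}
    Y   = Xcs + X         identity residual

The channel gate pools the map globally by max and mean, pushes both
C-vectors through one shared bottleneck MLP and sums them before the
sigmoid.  The spatial gate stacks the channel-wise max and mean planes and
reduces them with three 3x3 convolutions (a cheap stand-in for a single
7x7, with the same effective receptive field) before the sigmoid.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import functional as F


class ChannelAttention(nn.Module):
    """Global max+avg pooled, shared-MLP channel gate: (N,C,H,W) -> (N,C,1,1)."""

    def __init__(self, channels: int, reduction: int = 16):
        super().__init__()
        hidden = max(channels // reduction, 4)
        self.fc1 = nn.Linear(channels, hidden)
        self.fc2 = nn.Linear(hidden, channels)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        n, c = x.shape[0], x.shape[1]
        mx = F.global_max_pool(x).reshape(n, c)
        av = F.global_avg_pool(x).reshape(n, c)
        y = self.fc2(F.silu(self.fc1(mx))) + self.fc2(F.silu(self.fc1(av)))
        return y.sigmoid().reshape(n, c, 1, 1)


class SpatialAttention(nn.Module):
    """Three stacked 3x3 convs over the [max, mean] channel descriptor."""

    def __init__(self, hidden: int = 4):
        super().__init__()
        self.conv1 = nn.Conv2d(2, hidden, 3, padding=1)
        self.conv2 = nn.Conv2d(hidden, hidden, 3, padding=1)
        self.conv3 = nn.Conv2d(hidden, 1, 3, padding=1)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        mx = x.max(axis=1, keepdims=True)
        av = x.mean(axis=1, keepdims=True)
        d = nn.concatenate([mx, av], axis=1)
        y = self.conv3(F.silu(self.conv2(F.silu(self.conv1(d)))))
        return y.sigmoid()


class CSAAM(nn.Module):
    def __init__(self, channels: int, reduction: int = 16, spatial_hidden: int = 4):
        super().__init__()
        self.channels = channels
        self.channel_attention = ChannelAttention(channels, reduction)
        self.spatial_attention = SpatialAttention(spatial_hidden)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        xc = self.channel_attention(x) * x
        xcs = self.spatial_attention(xc) * xc
        return xcs + x

    def zero_init_(self) -> None:
        """Zero all gate weights so both attention maps sit at sigmoid(0)=0.5."""
        for _, p in self.named_parameters():
            p.data = np.zeros_like(p.data)


def channel_attention(x: nn.Tensor, reduction: int = 16) -> nn.Tensor:
    """Functional form building a fresh gate (weights from the init stream)."""
    return ChannelAttention(x.shape[1], reduction)(x)


def spatial_attention(x: nn.Tensor) -> nn.Tensor:
    return SpatialAttention()(x)


def csaam_forward(x: nn.Tensor, module: CSAAM | None = None) -> nn.Tensor:
    return (module or CSAAM(x.shape[1]))(x)
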