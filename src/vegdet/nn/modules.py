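"""Layer zoo: parameter containers and the standard building blocks.

Modules mirror the familiar torch.nn surface at a much smaller scale:
``parameters()`` / ``named_parameters()`` walk the attribute tree,
``state_dict`` round-trips plain NumPy arrays, and ``train()`` / ``eval()``
toggle normalization statistics.  A lightweight multiply-accumulate counter
can be armed around a forward pass for analytic FLOP accounting.
"""

from __future__ import annotations

import contextlib
import math
from typing import Iterator

import numpy as np

from .autograd import Tensor
from . import functional as F

_MAC_COUNTER: list[int] | None = None


@contextlib.contextmanager
def count_macs():
    """Context arming a global multiply-accumulate counter.

    Usage: ``with count_macs() as c: model(x)``; ``c[0]`` then holds the MAC
    total of every Linear/Conv2d/attention matmul executed inside.
    """
    global _MAC_COUNTER
    prev = _MAC_COUNTER
    _MAC_COUNTER = [0]
    try:
        yield _MAC_COUNTER
    finally:
        _MAC_COUNTER = prev


def add_macs(n: int) -> None:
    if _MAC_COUNTER is not None:
        _MAC_COUNTER[0] += int(n)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- tree traversal -------------------------------------------------------
    def named_children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=full + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for _, child in self.named_children():
            yield from child.modules()

    # -- state ----------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        bufs = dict(self._named_buffer_slots())
        missing = (set(own) | set(bufs)) - set(state)
        extra = set(state) - (set(own) | set(bufs))
        if missing or extra:
            raise ValueError(
                f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}"
            )
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}"
                )
            p.data = state[name].astype(np.float32).copy()
        for name, (mod, attr) in bufs.items():
            setattr(mod, attr, state[name].astype(np.float32).copy())

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, (mod, attr) in self._named_buffer_slots(prefix):
            yield name, getattr(mod, attr)

    def _named_buffer_slots(self, prefix: str = ""):
        for attr in getattr(self, "_buffers", ()):  # type: ignore[attr-defined]
            yield f"{prefix}{attr}", (self, attr)
        for name, child in self.named_children():
            yield from child._named_buffer_slots(prefix=f"{prefix}{name}.")

    # -- modes ----------------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, items=()):
        super().__init__()
        for i, m in enumerate(items):
            setattr(self, str(i), m)
        self._n = len(tuple(items))

    def append(self, m: Module) -> None:
        setattr(self, str(self._n), m)
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def __iter__(self):
        return (getattr(self, str(i)) for i in range(self._n))

    def __getitem__(self, i: int) -> Module:
        return getattr(self, str(i))


class Sequential(ModuleList):
    def forward(self, x):
        for m in self:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class SiLU(Module):
    def forward(self, x):
        return F.silu(x)


class GELU(Module):
    def forward(self, x):
        return F.gelu(x)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


def _kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = math.sqrt(2.0 / max(fan_in, 1))
    return rng.normal(0.0, bound, size=shape).astype(np.float32)


_INIT_RNG = np.random.default_rng(0)


def set_init_seed(seed: int) -> None:
    """Reset the global weight-initialization stream (full determinism)."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(_kaiming(_INIT_RNG, in_features, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        add_macs(int(np.prod(x.shape[:-1])) * self.in_features * self.out_features)
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    """2-D convolution on (N, C, H, W) via im2col; supports depthwise groups."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        groups: int = 1,
        bias: bool = True,
    ):
        super().__init__()
        if groups not in (1, in_channels):
            raise ValueError("only groups=1 or depthwise (groups=in_channels) supported")
        if groups == in_channels and out_channels != in_channels:
            raise ValueError("depthwise conv requires out_channels == in_channels")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.groups = groups
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        self.weight = Parameter(
            _kaiming(
                _INIT_RNG,
                fan_in,
                (out_channels, in_channels // groups, kernel_size, kernel_size),
            )
        )
        self.bias = (
            Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None
        )

    def out_extent(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.kernel_size, self.stride, self.padding
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        k, s = self.kernel_size, self.stride
        oh, ow = self.out_extent(h, w)
        xp = x.pad2d(self.padding)
        if self.groups == 1:
            ck, ci, cj = F.im2col_indices(c, k, k, oh, ow, s)
            cols = xp[:, ck, ci, cj]  # (N, C*k*k, oh*ow)
            wmat = self.weight.reshape(self.out_channels, c * k * k)
            add_macs(n * self.out_channels * c * k * k * oh * ow)
            out = wmat @ cols
        else:  # depthwise
            ck, ci, cj = F.im2col_indices(1, k, k, oh, ow, s)
            # gather every channel's patches: (N, C, k*k, L)
            cols = xp[:, :, ci, cj]
            wmat = self.weight.reshape(1, c, 1, k * k)
            add_macs(n * c * k * k * oh * ow)
            out = (wmat @ cols).reshape(n, c, oh * ow)
        out = out.reshape(n, self.out_channels, oh, ow)
        if self.bias is not None:
            out = out + self.bias.reshape(1, self.out_channels, 1, 1)
        return out


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_features, dtype=np.float32))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)
        self._buffers = ("running_mean", "running_var")

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.weight.reshape(1, -1, 1, 1) + self.bias.reshape(1, -1, 1, 1)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.dim = dim
        self.eps = eps
        self.weight = Parameter(np.ones(dim, dtype=np.float32))
        self.bias = Parameter(np.zeros(dim, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return ((x - mu) / ((var + self.eps) ** 0.5)) * self.weight + self.bias


class ConvBnAct(Module):
    """Conv -> BatchNorm -> SiLU, the detector's basic convolutional unit."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, k, stride=stride, padding=k // 2, bias=False)
        self.bn = BatchNorm2d(c_out)
        self.act = SiLU()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))
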