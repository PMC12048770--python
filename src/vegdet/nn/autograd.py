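"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps a float32 ``ndarray`` and records the operations
applied to it; :meth:`Tensor.backward` replays the tape in reverse
topological order.  The primitive set is deliberately small — elementwise
arithmetic, (batched) matmul, reductions, indexing/reshaping and a handful
of nonlinearities — and every network layer in this package is composed
from it, so gradient correctness is testable primitive by primitive.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording inside the block (inference / data paths)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make ndarray <op> Tensor defer to the Tensor's reflected operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic protocol -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("called backward on a tensor that does not require grad")
        if grad is None:
            if self.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar outputs")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for long conv stacks
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float32)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        a, b = self, other
        return Tensor._make(
            a.data + b.data,
            (a, b),
            lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
        )

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        a, b = self, other
        return Tensor._make(
            a.data * b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g * b.data, a.shape),
                _unbroadcast(g * a.data, b.shape),
            ),
        )

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = _as_tensor(other)
        a, b = self, other
        return Tensor._make(
            a.data / b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g / b.data, a.shape),
                _unbroadcast(-g * a.data / (b.data**2), b.shape),
            ),
        )

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)
        return Tensor._make(
            a.data**e, (a,), lambda g: (g * e * a.data ** (e - 1.0),)
        )

    def __matmul__(self, other):
        other = _as_tensor(other)
        a, b = self, other

        def bwd(g):
            ga = _unbroadcast(g @ b.data.swapaxes(-1, -2), a.shape)
            gb = _unbroadcast(a.data.swapaxes(-1, -2) @ g, b.shape)
            return ga, gb

        return Tensor._make(a.data @ b.data, (a, b), bwd)

    # -- nonlinearities -------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g / (2.0 * out_data),))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * (1.0 - out_data**2),))

    def sigmoid(self):
        x = self.data
        out_data = np.empty_like(x)
        pos = x >= 0
        out_data[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out_data[~pos] = ex / (1.0 + ex)
        return Tensor._make(
            out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),)
        )

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bwd(g):
            if axis is None:
                return (np.broadcast_to(g, a.shape).astype(np.float32),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, a.shape).astype(np.float32),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[ax] for ax in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims: bool = False):
        a = self
        out_data = self.data.max(axis=axis, keepdims=True)
        # ties share the gradient equally (subgradient choice)
        mask = (self.data == out_data).astype(np.float32)
        mask /= mask.sum(axis=axis, keepdims=True)
        res = out_data if keepdims or axis is None else np.squeeze(out_data, axis=axis)
        if axis is None and not keepdims:
            res = np.asarray(res).reshape(())

        def bwd(g):
            if axis is None:
                return (mask * g,)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (mask * g2,)

        return Tensor._make(res, (a,), bwd)

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        return Tensor._make(
            self.data.reshape(shape), (a,), lambda g: (g.reshape(a.shape),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def swapaxes(self, ax1: int, ax2: int):
        axes = list(range(self.ndim))
        axes[ax1], axes[ax2] = axes[ax2], axes[ax1]
        return self.transpose(*axes)

    def __getitem__(self, key):
        a = self

        def bwd(g):
            out = np.zeros(a.shape, dtype=np.float32)
            np.add.at(out, key, g)
            return (out,)

        return Tensor._make(self.data[key], (a,), bwd)

    def roll(self, shift, axis):
        return Tensor._make(
            np.roll(self.data, shift, axis=axis),
            (self,),
            lambda g: (np.roll(g, tuple(-s for s in np.atleast_1d(shift)), axis=axis),),
        )

    def pad2d(self, pad: int):
        """Zero-pad the two trailing spatial axes symmetrically."""
        if pad == 0:
            return self
        a = self
        width = [(0, 0)] * (self.ndim - 2) + [(pad, pad), (pad, pad)]
        sl = tuple([slice(None)] * (self.ndim - 2) + [slice(pad, -pad)] * 2)
        return Tensor._make(
            np.pad(self.data, width), (a,), lambda g: (g[sl],)
        )


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        grads = []
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(start), int(stop))
            grads.append(g[tuple(sl)])
        return tuple(grads)

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, bwd
    )


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]

    def bwd(g):
        return tuple(np.take(g, i, axis=axis) for i in range(len(tensors)))

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tensors, bwd)


def maximum(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    amax = a.data >= b.data

    def bwd(g):
        return (
            _unbroadcast(g * amax, a.shape),
            _unbroadcast(g * (~amax), b.shape),
        )

    return Tensor._make(np.maximum(a.data, b.data), (a, b), bwd)


def minimum(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    amin = a.data <= b.data

    def bwd(g):
        return (
            _unbroadcast(g * amin, a.shape),
            _unbroadcast(g * (~amin), b.shape),
        )

    return Tensor._make(np.minimum(a.data, b.data), (a, b), bwd)


def where(cond: np.ndarray, a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    c = np.asarray(cond, dtype=bool)

    def bwd(g):
        return (_unbroadcast(g * c, a.shape), _unbroadcast(g * (~c), b.shape))

    return Tensor._make(np.where(c, a.data, b.data), (a, b), bwd)
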