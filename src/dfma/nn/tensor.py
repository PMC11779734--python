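"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the numerical substrate for the segmentation network: a small tape
of elementwise/linear-algebra primitives, each with a hand-written vector-
Jacobian product.  Convolution and the content-aware reassembly primitive
live in :mod:`dfma.nn.functional` and register themselves through the same
``_from_op`` mechanism.

Float32 is the working precision (matching common deep-learning practice);
tensors built from float64 input keep float64, which the gradient-check
tests rely on.
"""
from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

DEFAULT_DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(DEFAULT_DTYPE)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction -----------------------------------------------------
    @staticmethod
    def _from_op(data: np.ndarray, parents: Sequence["Tensor"],
                 backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def _accum(t: "Tensor", g: np.ndarray) -> None:
        if t.requires_grad:
            g = g.astype(t.data.dtype, copy=False)
            t.grad = g if t.grad is None else t.grad + g

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Run reverse-mode accumulation from this node."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bw(g):
            Tensor._accum(a, _unbroadcast(g, a.shape))
            Tensor._accum(b, _unbroadcast(g, b.shape))

        return Tensor._from_op(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._from_op(-a.data, (a,), lambda g: Tensor._accum(a, -g))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bw(g):
            Tensor._accum(a, _unbroadcast(g * b.data, a.shape))
            Tensor._accum(b, _unbroadcast(g * a.data, b.shape))

        return Tensor._from_op(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bw(g):
            Tensor._accum(a, _unbroadcast(g / b.data, a.shape))
            Tensor._accum(b, _unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor._from_op(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        a = self
        out = a.data ** p

        def bw(g):
            Tensor._accum(a, g * p * a.data ** (p - 1))

        return Tensor._from_op(out, (a,), bw)

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bw(g):
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            Tensor._accum(a, _unbroadcast(ga, a.shape))
            Tensor._accum(b, _unbroadcast(gb, b.shape))

        return Tensor._from_op(np.matmul(a.data, b.data), (a, b), bw)

    # -- elementwise nonlinearities --------------------------------------
    def exp(self):
        a = self
        out = np.exp(a.data)
        return Tensor._from_op(out, (a,), lambda g: Tensor._accum(a, g * out))

    def log(self):
        a = self
        return Tensor._from_op(np.log(a.data), (a,), lambda g: Tensor._accum(a, g / a.data))

    def sqrt(self):
        a = self
        out = np.sqrt(a.data)
        return Tensor._from_op(out, (a,), lambda g: Tensor._accum(a, g * 0.5 / out))

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._from_op(a.data * mask, (a,), lambda g: Tensor._accum(a, g * mask))

    def sigmoid(self):
        a = self
        # stable two-sided form avoids overflow in exp for large |x|
        e = np.exp(-np.abs(a.data))
        out = np.where(a.data >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
        return Tensor._from_op(out, (a,), lambda g: Tensor._accum(a, g * out * (1.0 - out)))

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is None:
                Tensor._accum(a, np.broadcast_to(g, a.shape).copy())
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(ax % a.ndim for ax in axes):
                    g = np.expand_dims(g, ax)
            Tensor._accum(a, np.broadcast_to(g, a.shape).copy())

        return Tensor._from_op(out, (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ----------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        return Tensor._from_op(a.data.reshape(shape), (a,),
                               lambda g: Tensor._accum(a, g.reshape(a.shape)))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)
        return Tensor._from_op(a.data.transpose(axes), (a,),
                               lambda g: Tensor._accum(a, g.transpose(inv)))

    def __getitem__(self, idx):
        a = self

        def bw(g):
            ga = np.zeros_like(a.data)
            ga[idx] = g
            Tensor._accum(a, ga)

        return Tensor._from_op(a.data[idx], (a,), bw)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in ts]
    out = np.concatenate([t.data for t in ts], axis=axis)

    def bw(g):
        offs = np.cumsum([0] + sizes)
        for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            Tensor._accum(t, g[tuple(sl)])

    return Tensor._from_op(out, ts, bw)
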