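"""Layer abstractions (Module tree, convolutions, normalization)."""
from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import DEFAULT_DTYPE, Tensor, concat


class Module:
    """Base class: a tree of sub-modules holding parameter/buffer tensors.

    Parameters are Tensors with ``requires_grad=True``; buffers (e.g. batch
    norm running statistics) are plain Tensors.  Both are discovered by
    attribute scan, so subclasses just assign them in ``__init__``.
    """

    def __init__(self):
        self.training = True

    # -- traversal --------------------------------------------------------
    def _children(self) -> Iterator[tuple[str, "Module"]]:
        def walk(name, val):
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    yield from walk(f"{name}.{i}", item)

        for name, val in vars(self).items():
            yield from walk(name, val)

    def named_tensors(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, val in vars(self).items():
            if isinstance(val, Tensor):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_tensors(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_tensors() if t.requires_grad]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.named_tensors()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        tensors = dict(self.named_tensors())
        missing = set(tensors) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, t in tensors.items():
            arr = np.asarray(state[k], dtype=t.data.dtype)
            if arr.shape != t.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {t.data.shape}")
            t.data = arr

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self._children():
            child.train(mode)
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


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.items = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.items:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape).astype(DEFAULT_DTYPE), requires_grad=True)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, dilation: int = 1, bias: bool = True,
                 pad_mode: str = "zero", rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng()
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.pad_mode = pad_mode
        self.weight = _he_init(rng, (out_ch, in_ch, kernel, kernel), in_ch * kernel * kernel)
        self.bias = Tensor(np.zeros(out_ch, dtype=DEFAULT_DTYPE), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding,
                        self.dilation, self.pad_mode)


class PartialConv2d(Module):
    """Convolve the first ``c_p`` channels, pass the remaining ``c - c_p`` through.

    A cheap spatial mixer: treating a contiguous channel slice as a proxy for
    the whole map cuts the multiply count by ``(c_p/c)^2`` versus a full
    convolution while keeping the tensor shape.
    """

    def __init__(self, channels: int, partial_channels: int, kernel: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if not (1 <= partial_channels <= channels):
            raise ValueError("partial_channels must satisfy 1 <= c_p <= c")
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.channels = channels
        self.partial_channels = partial_channels
        self.conv = Conv2d(partial_channels, partial_channels, kernel,
                           padding=kernel // 2, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        cp = self.partial_channels
        if cp == self.channels:
            return self.conv(x)
        head = self.conv(x[:, :cp])
        return concat([head, x[:, cp:]], axis=1)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(channels, dtype=DEFAULT_DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=DEFAULT_DTYPE), requires_grad=True)
        self.running_mean = Tensor(np.zeros(channels, dtype=DEFAULT_DTYPE))
        self.running_var = Tensor(np.ones(channels, dtype=DEFAULT_DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        C = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            d = x - mu
            var = (d * d).mean(axis=(0, 2, 3), keepdims=True)
            # running stats track the data, outside the autodiff tape
            m = self.momentum
            self.running_mean.data = (1 - m) * self.running_mean.data + m * mu.data.reshape(C)
            self.running_var.data = (1 - m) * self.running_var.data + m * var.data.reshape(C)
            xhat = d / (var + self.eps).sqrt()
        else:
            mu = self.running_mean.data.reshape(1, C, 1, 1)
            var = self.running_var.data.reshape(1, C, 1, 1)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / np.sqrt(var + self.eps))
        g = self.gamma.reshape(1, C, 1, 1)
        b = self.beta.reshape(1, C, 1, 1)
        return xhat * g + b


class GroupNorm(Module):
    def __init__(self, groups: int, channels: int, eps: float = 1e-5):
        super().__init__()
        if channels % groups != 0:
            raise ValueError("groups must divide channels")
        self.groups, self.eps = groups, eps
        self.gamma = Tensor(np.ones(channels, dtype=DEFAULT_DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=DEFAULT_DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        g = self.groups
        xg = x.reshape(B, g, (C // g) * H * W)
        mu = xg.mean(axis=2, keepdims=True)
        var = ((xg - mu) ** 2).mean(axis=2, keepdims=True)
        xhat = ((xg - mu) / (var + self.eps).sqrt()).reshape(B, C, H, W)
        return xhat * self.gamma.reshape(1, C, 1, 1) + self.beta.reshape(1, C, 1, 1)


class ConvBnRelu(Module):
    """The conv -> batch norm -> ReLU triple used throughout the network."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, stride, padding, dilation,
                           bias=False, rng=rng)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()
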