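"""Partial-convolution (FasterNet-style) feature extractor.

The backbone has four stages of residual blocks.  Each block applies a
partial convolution (a 3x3 convolution over only the first ``c_p`` of ``c``
channels, the rest passed through untouched) followed by two pointwise
convolutions with an expansion factor of 2:

    y = x + PWConv2(ReLU(BN(PWConv1(PConv(x)))))

A 4x4 stride-4 embedding precedes stage 1 and 2x2 stride-2 merges sit
between stages, so the stage-1 output has stride 4 (the "low-level" skip
feature) and the stage-4 output has stride 32 (the "high-level" feature).

FLOPs accounting: a full k x k convolution at resolution h x w with c
channels in and out costs h*w*k^2*c^2 multiply-accumulates; the partial
convolution touches only c_p channels and costs h*w*k^2*c_p^2, a fraction
(c_p/c)^2 of the full cost.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import BatchNorm2d, Conv2d, Module, PartialConv2d, Tensor


@dataclass(frozen=True)
class PConvSpec:
    """Shape contract of one partial convolution."""

    channels: int
    partial_channels: int
    kernel: int = 3

    def __post_init__(self):
        if not (1 <= self.partial_channels <= self.channels):
            raise ValueError("need 1 <= c_p <= c")
        if self.kernel % 2 != 1:
            raise ValueError("kernel must be odd")


@dataclass(frozen=True)
class BackboneConfig:
    depths: tuple[int, int, int, int] = (1, 2, 8, 2)
    widths: tuple[int, int, int, int] = (40, 80, 160, 320)
    partial_ratio: float = 0.25

    def __post_init__(self):
        if len(self.depths) != 4 or len(self.widths) != 4:
            raise ValueError("four stages required")
        if any(d < 1 for d in self.depths) or any(w < 1 for w in self.widths):
            raise ValueError("depths and widths must be >= 1")
        if not 0.0 < self.partial_ratio <= 1.0:
            raise ValueError("partial_ratio in (0, 1]")

    def partial_channels(self, width: int) -> int:
        return max(1, int(round(width * self.partial_ratio)))


def pconv_flops(spec: PConvSpec, h: int, w: int) -> int:
    """Multiply-accumulate count of the partial convolution at h x w."""
    if h < 1 or w < 1:
        raise ValueError("positive spatial dims required")
    return h * w * spec.kernel ** 2 * spec.partial_channels ** 2


def full_conv_flops(spec: PConvSpec, h: int, w: int) -> int:
    """Companion count for the full convolution over all c channels."""
    if h < 1 or w < 1:
        raise ValueError("positive spatial dims required")
    return h * w * spec.kernel ** 2 * spec.channels ** 2


def conv2d_flops(h: int, w: int, kernel: int, c_in: int, c_out: int) -> int:
    """Generic same-padded convolution MAC count (used by the pyramid audit)."""
    return h * w * kernel ** 2 * c_in * c_out


class FasterNetBlock(Module):
    """Residual block: PConv -> PWConv (expand) -> BN -> ReLU -> PWConv."""

    def __init__(self, channels: int, partial_ratio: float = 0.25,
                 expansion: int = 2, rng: np.random.Generator | None = None):
        super().__init__()
        cp = max(1, int(round(channels * partial_ratio)))
        hidden = channels * expansion
        self.pconv = PartialConv2d(channels, cp, kernel=3, rng=rng)
        self.pw1 = Conv2d(channels, hidden, 1, bias=False, rng=rng)
        self.bn = BatchNorm2d(hidden)
        self.pw2 = Conv2d(hidden, channels, 1, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.pw2(self.bn(self.pw1(self.pconv(x))).relu())
        return x + y


class FasterNetBackbone(Module):
    """Four-stage extractor emitting (stride-4, stride-32) feature maps."""

    def __init__(self, cfg: BackboneConfig = BackboneConfig(), in_ch: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng()
        self.cfg = cfg
        w = cfg.widths
        self.embed = Conv2d(in_ch, w[0], 4, stride=4, bias=False, rng=rng)
        self.embed_bn = BatchNorm2d(w[0])
        self.stages = [
            [FasterNetBlock(w[i], cfg.partial_ratio, rng=rng) for _ in range(cfg.depths[i])]
            for i in range(4)
        ]
        self.merges = [Conv2d(w[i], w[i + 1], 2, stride=2, bias=False, rng=rng)
                       for i in range(3)]
        self.merge_bns = [BatchNorm2d(w[i + 1]) for i in range(3)]

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        H, W = x.shape[2], x.shape[3]
        if H % 32 or W % 32:
            raise ValueError(f"input spatial dims must be divisible by 32, got {H}x{W}")
        y = self.embed_bn(self.embed(x))
        for blk in self.stages[0]:
            y = blk(y)
        low = y  # stride 4
        for i in range(3):
            y = self.merge_bns[i](self.merges[i](y))
            for blk in self.stages[i + 1]:
                y = blk(y)
        return low, y  # strides 4 and 32
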