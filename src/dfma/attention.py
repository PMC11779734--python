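"""Efficient Multi-scale Attention (EMA).

Channels are folded into ``g`` groups that are processed independently with
shared weights (the group axis is merged into the batch axis).  Per group,
three routes produce attention descriptors:

* 1x1 route: height-wise and width-wise global average pooling, concatenated
  along the pooled axis, passed through one shared 1x1 convolution, split
  back and applied as sigmoid gates in each direction; the gated map is
  group-normalized.
* 3x3 route: a single 3x3 convolution of the group features.
* cross-spatial aggregation: each route's globally pooled descriptor is
  softmax-normalized over channels and matrix-multiplied against the other
  route's flattened spatial map, yielding two spatial weight fields whose
  sum is squashed by a sigmoid into the final per-pixel attention in (0, 1).

The 3x3 convolution uses edge (replicate) padding so that a spatially
constant input yields spatially constant routes and hence a uniform
attention map - the symmetry the tests probe; zero padding would break it
at the image border.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2d, GroupNorm, Module, Tensor, concat
from .nn import functional as F


@dataclass(frozen=True)
class EmaConfig:
    groups: int = 8

    def __post_init__(self):
        if self.groups < 1:
            raise ValueError("groups must be >= 1")

    def validate(self, channels: int) -> None:
        if channels % self.groups != 0:
            raise ValueError(f"groups ({self.groups}) must divide channels ({channels})")


class EMA(Module):
    """Shape-preserving multiplicative attention over grouped channels."""

    def __init__(self, channels: int, cfg: EmaConfig = EmaConfig(),
                 rng: np.random.Generator | None = None):
        super().__init__()
        cfg.validate(channels)
        self.cfg = cfg
        self.channels = channels
        cg = channels // cfg.groups
        self.conv1x1 = Conv2d(cg, cg, 1, rng=rng)
        self.conv3x3 = Conv2d(cg, cg, 3, padding=1, pad_mode="edge", rng=rng)
        self.gn = GroupNorm(cg, cg)
        self.last_attention_: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        if C != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {C}")
        g = self.cfg.groups
        cg = C // g
        xg = x.reshape(B * g, cg, H, W)

        # 1x1 route: directional pooling -> shared 1x1 conv -> per-direction gates
        ph = F.pool_height(xg)                       # (Bg, cg, H, 1)
        pw = F.pool_width(xg).transpose(0, 1, 3, 2)  # (Bg, cg, W, 1)
        hw = self.conv1x1(concat([ph, pw], axis=2))  # (Bg, cg, H+W, 1)
        gate_h = hw[:, :, :H].sigmoid()              # (Bg, cg, H, 1)
        gate_w = hw[:, :, H:].transpose(0, 1, 3, 2).sigmoid()  # (Bg, cg, 1, W)
        x1 = self.gn(xg * gate_h * gate_w)

        # 3x3 route
        x2 = self.conv3x3(xg)

        # cross-spatial aggregation of softmax-pooled descriptors
        d1 = F.softmax(F.global_avg_pool(x1).reshape(B * g, cg, 1), axis=1)
        d2 = F.softmax(F.global_avg_pool(x2).reshape(B * g, cg, 1), axis=1)
        m1 = d1.transpose(0, 2, 1) @ x2.reshape(B * g, cg, H * W)  # (Bg, 1, HW)
        m2 = d2.transpose(0, 2, 1) @ x1.reshape(B * g, cg, H * W)
        weights = (m1 + m2).reshape(B * g, 1, H, W).sigmoid()
        self.last_attention_ = weights.data.reshape(B, g, 1, H, W)

        out = xg * weights
        return out.reshape(B, C, H, W)
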