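"""Series-parallel atrous pyramid (PSPA-ASPP) and the gridding diagnostic.

A standard atrous spatial pyramid applies parallel dilated 3x3 convolutions
at several rates plus image-level pooling.  Stacking dilated convolutions
that share a rate (or any common divisor > 1) produces the gridding effect:
some input positions can never influence an output position because every
layer samples the same sparse lattice.  This pyramid instead pairs small
coprime rates (2, 3) and (5, 7), halves each dilated branch to 128 kernels,
and replaces the 1x1 branch with a 3x3 partial convolution, so the stacked
receptive field is covered more densely at lower cost.

``grid_coverage`` quantifies the effect by brute force: it propagates the
set of input offsets reachable through a stack of dilated 3x3 convolutions
and reports the fraction of the stacked receptive field that participates.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .backbone import conv2d_flops
from .nn import BatchNorm2d, Conv2d, ConvBnRelu, Module, PartialConv2d, Tensor, concat
from .nn import functional as F

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PyramidConfig:
    branch_width: int = 128
    rate_pairs: tuple[tuple[int, int], ...] = ((2, 3), (5, 7))
    out_width: int = 256
    partial_ratio: float = 0.25
    serial: bool = False  # chain pair 2 onto pair 1's output instead of the input

    def __post_init__(self):
        for pair in self.rate_pairs:
            for r in pair:
                if r < 1:
                    raise ValueError("dilation rates must be >= 1")
            if len(pair) == 2 and math.gcd(*pair) > 1:
                raise ValueError(f"rates within a pair must be coprime, got {pair}")


class DilatedConv(Module):
    """Same-padded 3x3 convolution with dilation rate r (+ BN + ReLU)."""

    def __init__(self, in_ch: int, width: int, rate: int, kernel: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if rate < 1:
            raise ValueError("dilation rate must be >= 1")
        pad = rate * (kernel - 1) // 2
        self.rate = rate
        self.body = ConvBnRelu(in_ch, width, kernel, padding=pad, dilation=rate, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.body(x)


def effective_span(kernel: int, rate: int) -> int:
    """Receptive-field side of one dilated convolution: k + (k-1)(r-1)."""
    return kernel + (kernel - 1) * (rate - 1)


class PSPAPyramid(Module):
    """Four-branch pyramid producing a fixed 256-wide multi-scale map."""

    def __init__(self, in_ch: int, cfg: PyramidConfig = PyramidConfig(),
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        self.in_ch = in_ch
        self._warned_sizes: set[tuple[int, int]] = set()
        bw, ow = cfg.branch_width, cfg.out_width
        cp = max(1, int(round(in_ch * cfg.partial_ratio)))
        # branch A: 3x3 partial convolution, then pointwise to the output width
        self.pconv = PartialConv2d(in_ch, cp, kernel=3, rng=rng)
        self.pconv_proj = ConvBnRelu(in_ch, ow, 1, rng=rng)
        # branches B and C: paired dilated convolutions, 128 kernels each
        (r1, r2), (r3, r4) = cfg.rate_pairs
        self.dil_a1 = DilatedConv(in_ch, bw, r1, rng=rng)
        self.dil_a2 = DilatedConv(in_ch, bw, r2, rng=rng)
        pair2_in = 2 * bw if cfg.serial else in_ch
        self.dil_b1 = DilatedConv(pair2_in, bw, r3, rng=rng)
        self.dil_b2 = DilatedConv(pair2_in, bw, r4, rng=rng)
        # branch D: image-level pooling
        self.pool_proj = Conv2d(in_ch, ow, 1, bias=False, rng=rng)
        self.pool_bn = BatchNorm2d(ow)
        # fusion
        self.fuse = ConvBnRelu(ow + 4 * bw + ow, ow, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        H, W = x.shape[2], x.shape[3]
        largest = max(effective_span(3, r) for pair in self.cfg.rate_pairs for r in pair)
        if min(H, W) < largest and (H, W) not in self._warned_sizes:
            self._warned_sizes.add((H, W))
            logger.warning("pyramid input %dx%d smaller than largest effective span %d",
                           H, W, largest)
        a = self.pconv_proj(self.pconv(x))
        b = concat([self.dil_a1(x), self.dil_a2(x)], axis=1)
        c_in = b if self.cfg.serial else x
        c = concat([self.dil_b1(c_in), self.dil_b2(c_in)], axis=1)
        pooled = self.pool_bn(self.pool_proj(F.global_avg_pool(x))).relu()
        # broadcast the 1x1 pooled descriptor back to H x W
        d = pooled * Tensor(np.ones((1, 1, H, W), dtype=pooled.data.dtype))
        return self.fuse(concat([a, b, c, d], axis=1))


def grid_coverage(rates: tuple[int, ...] | list[int], kernel: int = 3) -> float:
    """Fraction of the stacked receptive field that can influence one output.

    Brute-force influence propagation: the set of reachable 1-D offsets is
    grown layer by layer as ``S_{i+1} = {s + r_i * d : s in S_i, |d| <= (k-1)/2}``;
    in 2-D the axes are independent, so coverage is the square of the 1-D
    fraction over the stacked receptive-field extent.
    """
    rates = tuple(rates)
    if not rates:
        raise ValueError("rates must be non-empty")
    half = (kernel - 1) // 2
    offsets = {0}
    for r in rates:
        offsets = {s + r * d for s in offsets for d in range(-half, half + 1)}
    extent = 1 + (kernel - 1) * sum(rates)  # full side length of the stacked field
    return (len(offsets) / extent) ** 2


def pspa_flops(in_ch: int, h: int, w: int, cfg: PyramidConfig = PyramidConfig()) -> int:
    """Analytic MAC count of the pyramid at an h x w input."""
    bw, ow = cfg.branch_width, cfg.out_width
    cp = max(1, int(round(in_ch * cfg.partial_ratio)))
    total = conv2d_flops(h, w, 3, cp, cp)          # partial conv
    total += conv2d_flops(h, w, 1, in_ch, ow)      # branch A projection
    pair2_in = 2 * bw if cfg.serial else in_ch
    for i, pair in enumerate(cfg.rate_pairs):
        src = in_ch if i == 0 else pair2_in
        for _ in pair:
            total += conv2d_flops(h, w, 3, src, bw)
    total += conv2d_flops(1, 1, 1, in_ch, ow)      # pooled projection
    total += conv2d_flops(h, w, 1, ow + 4 * bw + ow, ow)  # fusion
    return total


def standard_aspp_flops(in_ch: int, h: int, w: int, width: int = 256) -> int:
    """Reference: classic pyramid with a 1x1 branch, three 256-wide dilated
    3x3 branches, image pooling, and a 1x1 fusion."""
    total = conv2d_flops(h, w, 1, in_ch, width)
    total += 3 * conv2d_flops(h, w, 3, in_ch, width)
    total += conv2d_flops(1, 1, 1, in_ch, width)
    total += conv2d_flops(h, w, 1, 5 * width, width)
    return total
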