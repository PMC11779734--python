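"""Content-aware reassembly upsampler (CARAFE).

Upsampling by an integer factor sigma proceeds in two steps:

1. *Kernel prediction*: a 1x1 channel compressor (C -> C_m) followed by a
   k_encoder x k_encoder content encoder producing sigma^2 * k_up^2
   channels; pixel-shuffling rearranges these to one k_up x k_up kernel per
   output position (sigma*H x sigma*W of them), and a softmax over the
   k_up^2 logits makes each kernel a convex-combination weight set.
2. *Reassembly*: every output position l' maps back to the source position
   l = floor(l' / sigma); the output value is the dot product of the
   predicted kernel with the k_up x k_up neighbourhood of l (zero padding
   at the borders).  All channels at one position share one kernel.

Because the weights are non-negative and sum to one, each interior output
value is a convex combination of its source neighbourhood.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2d, Module, Tensor
from .nn import functional as F


@dataclass(frozen=True)
class CarafeConfig:
    sigma: int = 8
    k_up: int = 5
    k_encoder: int = 3
    c_m: int = 64

    def __post_init__(self):
        if self.sigma < 2:
            raise ValueError("upsampling factor sigma must be >= 2")
        if self.k_up % 2 != 1 or self.k_encoder % 2 != 1:
            raise ValueError("k_up and k_encoder must be odd")
        if self.c_m < 1:
            raise ValueError("c_m must be >= 1")


class Carafe(Module):
    """sigma-fold content-aware upsampling of an NCHW feature map."""

    def __init__(self, channels: int, cfg: CarafeConfig = CarafeConfig(),
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        self.channels = channels
        s, k = cfg.sigma, cfg.k_up
        self.compressor = Conv2d(channels, cfg.c_m, 1, rng=rng)
        self.encoder = Conv2d(cfg.c_m, s * s * k * k, cfg.k_encoder,
                              padding=cfg.k_encoder // 2, rng=rng)

    # -- step 1 -----------------------------------------------------------
    def predict_kernels(self, x: Tensor) -> Tensor:
        """Normalized reassembly kernels, shape (B, k_up^2, sigma*H, sigma*W)."""
        s, k = self.cfg.sigma, self.cfg.k_up
        logits = self.encoder(self.compressor(x))          # (B, s^2 k^2, H, W)
        logits = F.pixel_shuffle(logits, s)                # (B, k^2, sH, sW)
        return F.softmax(logits, axis=1)

    # -- step 2 -----------------------------------------------------------
    def reassemble(self, x: Tensor, kernels: Tensor) -> Tensor:
        """Apply per-position kernels to the source neighbourhoods of x."""
        s, k = self.cfg.sigma, self.cfg.k_up
        B, C, H, W = x.shape
        if kernels.shape != (B, k * k, s * H, s * W):
            raise ValueError(
                f"kernel grid {kernels.shape} does not match input {x.shape} "
                f"with sigma={s}, k_up={k}")
        # inverse pixel shuffle: (B, k^2, sH, sW) -> (B, s^2, k^2, H, W)
        kg = kernels.reshape(B, k * k, H, s, W, s)
        kg = kg.transpose(0, 3, 5, 1, 2, 4).reshape(B, s * s, k * k, H, W)
        out = F.carafe_reassemble_grouped(x, kg, k)        # (B, C, s^2, H, W)
        out = out.reshape(B, C * s * s, H, W)
        return F.pixel_shuffle(out, s)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        return self.reassemble(x, self.predict_kernels(x))
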