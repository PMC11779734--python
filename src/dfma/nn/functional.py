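"""Array-level neural-network primitives with hand-written backward passes.

Everything here operates on :class:`dfma.nn.tensor.Tensor` in NCHW layout.
``conv2d`` is an im2col/matmul implementation supporting stride, dilation
and zero or edge ("replicate") same-padding; ``carafe_reassemble_grouped``
is the content-aware reassembly inner loop shared by the upsampler.
"""
from __future__ import annotations

import numpy as np

from .tensor import Tensor


def _pad_spatial(xd: np.ndarray, padding: int, mode: str):
    """Pad the last two axes. Returns (padded, index maps or None)."""
    if padding == 0:
        return xd, None
    if mode == "zero":
        return np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding))), None
    if mode == "edge":
        H, W = xd.shape[-2:]
        ri = np.clip(np.arange(-padding, H + padding), 0, H - 1)
        ci = np.clip(np.arange(-padding, W + padding), 0, W - 1)
        return xd[:, :, ri[:, None], ci[None, :]], (ri, ci)
    raise ValueError(f"unknown pad mode {mode!r}")


def _unpad_grad(dxp: np.ndarray, padding: int, mode: str, idx, out_hw):
    """Map a gradient w.r.t. the padded array back to the source array."""
    H, W = out_hw
    if padding == 0:
        return dxp
    if mode == "zero":
        return dxp[:, :, padding:padding + H, padding:padding + W]
    ri, ci = idx
    flat_idx = (ri[:, None] * W + ci[None, :]).ravel()
    B, C, Hp, Wp = dxp.shape
    g2 = dxp.reshape(B * C, Hp * Wp).T  # (HpWp, BC)
    acc = np.zeros((H * W, B * C), dtype=dxp.dtype)
    np.add.at(acc, flat_idx, g2)
    return acc.T.reshape(B, C, H, W)


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, dilation: int):
    B, C, Hp, Wp = xp.shape
    eh = dilation * (kh - 1) + 1
    ew = dilation * (kw - 1) + 1
    ho = (Hp - eh) // stride + 1
    wo = (Wp - ew) // stride + 1
    s0, s1, s2, s3 = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, (B, C, kh, kw, ho, wo),
        (s0, s1, s2 * dilation, s3 * dilation, s2 * stride, s3 * stride))
    return view, ho, wo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, dilation: int = 1, pad_mode: str = "zero") -> Tensor:
    """Cross-correlation in NCHW layout (the deep-learning "convolution")."""
    xd = x.data
    if xd.ndim != 4:
        raise ValueError("conv2d expects (B, C, H, W) input")
    B, C, H, W = xd.shape
    O, Ck, kh, kw = w.shape
    if Ck != C:
        raise ValueError(f"channel mismatch: input has {C}, weight expects {Ck}")
    xp, idx = _pad_spatial(xd, padding, pad_mode)
    view, ho, wo = _im2col(xp, kh, kw, stride, dilation)
    colm = np.ascontiguousarray(view).reshape(B, C * kh * kw, ho * wo)
    wm = w.data.reshape(O, C * kh * kw)
    out = np.matmul(wm, colm).reshape(B, O, ho, wo)
    if b is not None:
        out = out + b.data.reshape(1, O, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        gm = g.reshape(B, O, ho * wo)
        if w.requires_grad:
            dw = np.matmul(gm, colm.transpose(0, 2, 1)).sum(axis=0).reshape(w.shape)
            Tensor._accum(w, dw)
        if b is not None and b.requires_grad:
            Tensor._accum(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcol = np.matmul(wm.T, gm).reshape(B, C, kh, kw, ho, wo)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    di, dj = i * dilation, j * dilation
                    dxp[:, :, di:di + ho * stride:stride,
                        dj:dj + wo * stride:stride] += dcol[:, :, i, j]
            Tensor._accum(x, _unpad_grad(dxp, padding, pad_mode, idx, (H, W)))

    return Tensor._from_op(out, parents, bw)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    """Integer-factor nearest-neighbour upsampling of an NCHW tensor."""
    if factor < 1:
        raise ValueError("upsample factor must be >= 1")
    B, C, H, W = x.shape
    out = x.data.repeat(factor, axis=2).repeat(factor, axis=3)

    def bw(g):
        Tensor._accum(x, g.reshape(B, C, H, factor, W, factor).sum(axis=(3, 5)))

    return Tensor._from_op(out, (x,), bw)


def carafe_reassemble_grouped(x: Tensor, kern: Tensor, k_up: int) -> Tensor:
    """Reassembly inner step: ``out[b,c,s,h,w] = sum_k N(x)[b,c,k,h,w] * kern[b,s,k,h,w]``.

    ``kern`` has shape (B, S, k_up^2, H, W) where S indexes the sigma^2
    sub-positions of one source pixel; neighbourhoods use zero padding.
    The caller pixel-shuffles the S axis into space afterwards.
    """
    B, C, H, W = x.shape
    Bk, S, K, Hk, Wk = kern.shape
    if (Bk, Hk, Wk) != (B, H, W) or K != k_up * k_up:
        raise ValueError("reassembly kernel grid does not match the input feature map")
    pad = k_up // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out = np.zeros((B, C, S, H, W), dtype=x.data.dtype)
    for k in range(K):
        dy, dx = divmod(k, k_up)
        xk = xp[:, :, dy:dy + H, dx:dx + W]
        out += xk[:, :, None] * kern.data[:, None, :, k]

    def bw(g):
        if kern.requires_grad:
            dkern = np.empty_like(kern.data)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
        for k in range(K):
            dy, dx = divmod(k, k_up)
            if kern.requires_grad:
                xk = xp[:, :, dy:dy + H, dx:dx + W]
                dkern[:, :, k] = (g * xk[:, :, None]).sum(axis=1)
            if x.requires_grad:
                dxp[:, :, dy:dy + H, dx:dx + W] += (g * kern.data[:, None, :, k]).sum(axis=2)
        if kern.requires_grad:
            Tensor._accum(kern, dkern)
        if x.requires_grad:
            Tensor._accum(x, dxp[:, :, pad:pad + H, pad:pad + W])

    return Tensor._from_op(out, (x, kern), bw)


# -- composite helpers (differentiable through primitive ops) -------------

def softmax(x: Tensor, axis: int) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant, exact value unchanged
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def global_avg_pool(x: Tensor) -> Tensor:
    return x.mean(axis=(2, 3), keepdims=True)


def pool_height(x: Tensor) -> Tensor:
    """Average over the width axis: (B,C,H,W) -> (B,C,H,1)."""
    return x.mean(axis=3, keepdims=True)


def pool_width(x: Tensor) -> Tensor:
    """Average over the height axis: (B,C,H,W) -> (B,C,1,W)."""
    return x.mean(axis=2, keepdims=True)


def pixel_shuffle(x: Tensor, factor: int) -> Tensor:
    """(B, C*f^2, H, W) -> (B, C, f*H, f*W) with (C, fy, fx) channel layout."""
    B, Cf, H, W = x.shape
    C = Cf // (factor * factor)
    if C * factor * factor != Cf:
        raise ValueError("channel count not divisible by factor^2")
    t = x.reshape(B, C, factor, factor, H, W)
    t = t.transpose(0, 1, 4, 2, 5, 3)
    return t.reshape(B, C, H * factor, W * factor)
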