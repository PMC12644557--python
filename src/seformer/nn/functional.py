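"""Differentiable NN primitives built on :class:`seformer.nn.tensor.Tensor`.

Convolution is im2col + matmul (the windows are gathered with
``sliding_window_view`` so the heavy lifting is a single BLAS call), with the
col2im scatter in the backward pass expressed as ``kh*kw`` strided
slice-adds.  Bilinear resampling is separable gather/scatter with
precomputed integer indices and fractional weights (half-pixel centre
convention), so its adjoint is exact.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

from .tensor import Tensor, as_tensor

__all__ = [
    "linear",
    "conv2d",
    "softmax",
    "layer_norm",
    "gelu",
    "global_avg_pool",
    "upsample_bilinear",
]


def linear(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Affine map on the last axis. ``weight`` has shape (in, out)."""
    y = x @ weight
    if bias is not None:
        y = y + bias
    return y


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation. x: (B,C,H,W), weight: (Co,C,kh,kw)."""
    x = as_tensor(x)
    weight = as_tensor(weight)
    B, C, H, W = x.shape
    Co, Ci, kh, kw = weight.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input has {C}, weight expects {Ci}")
    s, p = int(stride), int(padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    # (B, C, Ho, Wo, kh, kw)
    cols = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    cols2 = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B * Ho * Wo, C * kh * kw
    )
    wmat = weight.data.reshape(Co, C * kh * kw)
    out = (cols2 @ wmat.T).reshape(B, Ho, Wo, Co).transpose(0, 3, 1, 2)
    out = np.ascontiguousarray(out)

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * Ho * Wo, Co)
        if weight.requires_grad:
            gw = (gmat.T @ cols2).reshape(Co, C, kh, kw)
            weight._accum(gw)
        if x.requires_grad:
            gcols = (gmat @ wmat).reshape(B, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + Ho * s:s, j:j + Wo * s:s] += gcols[:, :, :, :, i, j]
            x._accum(gxp[:, :, p:p + H, p:p + W] if p else gxp)

    out_t = Tensor._make(out, (x, weight), backward)
    if bias is not None:
        out_t = out_t + bias.reshape(1, Co, 1, 1)
    return out_t


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Fused softmax; backward uses out * (g - sum(g * out))."""
    x = as_tensor(x)
    shifted = x.data - np.max(x.data, axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = np.sum(g * out, axis=axis, keepdims=True)
        x._accum(out * (g - dot))

    return Tensor._make(out, (x,), backward)


def layer_norm(x: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    y = xc / (var + eps).sqrt()
    return y * weight + bias


def gelu(x: Tensor) -> Tensor:
    """Exact Gaussian-error-linear unit: x * Phi(x)."""
    x = as_tensor(x)
    xd = x.data
    phi_cdf = 0.5 * (1.0 + erf(xd / np.sqrt(2.0)))
    out = xd * phi_cdf

    def backward(g):
        pdf = np.exp(-0.5 * xd * xd) / np.sqrt(2.0 * np.pi)
        x._accum(g * (phi_cdf + xd * pdf))

    return Tensor._make(out.astype(xd.dtype, copy=False), (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(B,C,H,W) -> (B,C,1,1) mean over space."""
    return x.mean(axis=(2, 3), keepdims=True)


from functools import lru_cache


@lru_cache(maxsize=64)
def _resample_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense (n_out, n_in) linear-interpolation matrix, half-pixel centres."""
    c = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    c = np.clip(c, 0.0, n_in - 1.0)
    i0 = np.floor(c).astype(np.int64)
    i0 = np.minimum(i0, n_in - 2) if n_in > 1 else i0
    i1 = i0 + (1 if n_in > 1 else 0)
    frac = c - i0
    m = np.zeros((n_out, n_in), dtype=np.float32)
    np.add.at(m, (np.arange(n_out), i0), 1.0 - frac)
    np.add.at(m, (np.arange(n_out), i1), frac)
    return m


def upsample_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of (B,C,H,W) to (B,C,out_h,out_w).

    Separable: one cached dense interpolation matrix per axis, applied as
    matmuls, so the backward pass is the exact transpose (no scatter).
    """
    x = as_tensor(x)
    B, C, H, W = x.shape
    mh = _resample_matrix(H, out_h).astype(x.dtype, copy=False)
    mw = _resample_matrix(W, out_w).astype(x.dtype, copy=False)
    rows = np.einsum("oh,bchw->bcow", mh, x.data, optimize=True)
    out = rows @ mw.T

    def backward(g):
        grows = g @ mw
        x._accum(np.einsum("oh,bcow->bchw", mh, grows, optimize=True))

    return Tensor._make(np.ascontiguousarray(out), (x,), backward)
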