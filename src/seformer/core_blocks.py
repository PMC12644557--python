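"""Reusable computational primitives of the dual-branch architecture.

Conventions
-----------
* A *feature map* is (B, C, H, W); a *token grid* is (B, Ht, Wt, E).  The
  two are related by a transpose bijection (`map_to_tokens` /
  `tokens_to_map`): token (row, col) maps to image (y, x), 0-based,
  row-major.
* The relative-position bias on attention logits is the additive
  row-offset + column-offset decomposition: B[i, j] = Er[dr + M - 1] +
  Ec[dc + M - 1], one shared (Er, Ec) pair per attention layer, shared
  across heads.  The bias is always added *inside* the softmax logits.
* Shifted windows are realised as a cyclic shift by (-s, -s) followed by a
  plain non-overlapping partition, with an additive mask that forbids
  attention between tokens that were not spatial neighbours before the
  shift.  Grids whose side is not a multiple of the window size are
  zero-padded bottom/right; padded tokens are isolated by the same mask and
  cropped afterwards.
* Patch merging concatenates each 2x2 token block in row-major order
  (top-left, top-right, bottom-left, bottom-right) and maps 4E -> 2E.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import functional as F
from .nn.modules import (GELU, Conv2d, LayerNorm, Linear, Module, ModuleList,
                         Parameter, ReLU, Sigmoid)
from .nn.tensor import Tensor, as_tensor, concatenate

MASK_NEG = -1e9


# ---------------------------------------------------------------------------
# token grid <-> feature map bijection
# ---------------------------------------------------------------------------

def tokens_to_map(t: Tensor) -> Tensor:
    """(B, Ht, Wt, E) -> (B, E, Ht, Wt)."""
    return as_tensor(t).transpose(0, 3, 1, 2)


def map_to_tokens(x: Tensor) -> Tensor:
    """(B, C, H, W) -> (B, H, W, C)."""
    return as_tensor(x).transpose(0, 2, 3, 1)


# ---------------------------------------------------------------------------
# squeeze-and-excitation
# ---------------------------------------------------------------------------

class SEBlock(Module):
    """Channel recalibration: GAP -> FC(C/r) -> ReLU -> FC(C) -> sigmoid -> scale.

    The sigmoid keeps every per-channel weight strictly in (0, 1), so
    recalibration never flips the sign of an activation and never amplifies
    its magnitude.
    """

    def __init__(self, channels: int, ratio: int = 16):
        super().__init__()
        if channels % ratio != 0:
            raise ValueError(
                f"SE ratio {ratio} must divide the channel count {channels}")
        self.channels = channels
        # The narrow squeeze layer (C/r units) behind global average pooling
        # sees a nearly input-independent vector at init, so a random wide
        # init can leave every bottleneck unit ReLU-dead for an entire run.
        # Zero weights with a positive bias start the gate neutral *and*
        # active: pre-activations equal the bias, and weight gradients are
        # proportional to the pooled features, so the gate trains normally.
        self.squeeze = Linear(channels, channels // ratio,
                              bias_init=0.1, init_std=0.0)
        self.excite = Linear(channels // ratio, channels)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(
                f"SE block built for {self.channels} channels, input has {x.shape[1]}")
        B, C = x.shape[:2]
        pooled = F.global_avg_pool(x).reshape(B, C)
        w = self.excite(self.squeeze(pooled).relu()).sigmoid()
        return x * w.reshape(B, C, 1, 1)


def se_recalibrate(x, block: SEBlock) -> Tensor:
    """Functional alias for applying an SE block to a feature map."""
    return block(as_tensor(x))


# ---------------------------------------------------------------------------
# patch embedding / merging
# ---------------------------------------------------------------------------

class PatchEmbed(Module):
    """Project non-overlapping patch x patch blocks to dim-vectors.

    A strided convolution with kernel = stride = patch; the output is a
    token grid of (H/patch) x (W/patch).  Inputs whose side is not a
    multiple of ``patch`` are zero-padded bottom/right first.
    """

    def __init__(self, patch: int, in_channels: int, dim: int):
        super().__init__()
        if patch <= 0 or dim <= 0:
            raise ValueError("patch size and embedding dim must be positive")
        self.patch = patch
        self.proj = Conv2d(in_channels, dim, kernel=patch, stride=patch)

    def forward(self, image: Tensor) -> Tensor:
        image = as_tensor(image)
        _, _, H, W = image.shape
        p = self.patch
        ph, pw = (-H) % p, (-W) % p
        if ph or pw:
            image = image.pad(((0, 0), (0, 0), (0, ph), (0, pw)))
        return map_to_tokens(self.proj(image))


class PatchMerge(Module):
    """Merge each 2x2 token block into one token of doubled dimension.

    Concatenation order is row-major (TL, TR, BL, BR); the affine map is
    4E -> 2E.  Odd grids are zero-padded to even before merging.
    """

    def __init__(self, dim: int):
        super().__init__()
        self.dim = dim
        self.reduce = Linear(4 * dim, 2 * dim)

    def forward(self, t: Tensor) -> Tensor:
        t = as_tensor(t)
        _, Ht, Wt, E = t.shape
        if Ht % 2 or Wt % 2:
            t = t.pad(((0, 0), (0, Ht % 2), (0, Wt % 2), (0, 0)))
            _, Ht, Wt, E = t.shape
        tl = t[:, 0::2, 0::2, :]
        tr = t[:, 0::2, 1::2, :]
        bl = t[:, 1::2, 0::2, :]
        br = t[:, 1::2, 1::2, :]
        merged = concatenate([tl, tr, bl, br], axis=-1)
        return self.reduce(merged)


# ---------------------------------------------------------------------------
# relative position bias
# ---------------------------------------------------------------------------

class RelPosBias(Module):
    """Additive row/column relative-position bias for an M x M window."""

    def __init__(self, window: int):
        super().__init__()
        self.window = window
        self.er = Parameter(np.zeros(2 * window - 1))
        self.ec = Parameter(np.zeros(2 * window - 1))

    def reset_parameters(self, rng):
        self.er.data[...] = rng.normal(0.0, 0.02, self.er.shape)
        self.ec.data[...] = rng.normal(0.0, 0.02, self.ec.shape)

    def forward(self) -> Tensor:
        return relpos_bias_matrix(self.er, self.ec, self.window)


def relpos_bias_matrix(er, ec, window: int) -> Tensor:
    """Materialize the (M^2, M^2) bias: B[i,j] = Er[ri-rj+M-1] + Ec[ci-cj+M-1]."""
    er, ec = as_tensor(er), as_tensor(ec)
    M = int(window)
    if er.shape != (2 * M - 1,) or ec.shape != (2 * M - 1,):
        raise ValueError(
            f"bias vectors must have length {2 * M - 1}, got {er.shape} / {ec.shape}")
    rows, cols = np.divmod(np.arange(M * M), M)
    dr = rows[:, None] - rows[None, :] + M - 1
    dc = cols[:, None] - cols[None, :] + M - 1
    return er[dr] + ec[dc]


# ---------------------------------------------------------------------------
# multi-head attention
# ---------------------------------------------------------------------------

def _split_heads(x: Tensor, heads: int) -> Tensor:
    *lead, L, E = x.shape
    d = E // heads
    return x.reshape(*lead, L, heads, d).transpose(
        *range(len(lead)), len(lead) + 1, len(lead), len(lead) + 2)


def _merge_heads(x: Tensor) -> Tensor:
    *lead, h, L, d = x.shape
    return x.transpose(*range(len(lead)), len(lead) + 1, len(lead),
                       len(lead) + 2).reshape(*lead, L, h * d)


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor, heads: int,
                         bias: Tensor | None = None) -> Tensor:
    """Multi-head scaled dot-product attention on (..., L, E) sequences.

    ``bias`` (if given) must broadcast against the logits
    (..., heads, Lq, Lk) and is added before the softmax.  Non-finite
    logits raise instead of propagating silently.
    """
    E = q.shape[-1]
    if E % heads:
        raise ValueError(f"head count {heads} must divide model dim {E}")
    d = E // heads
    qh, kh, vh = (_split_heads(t, heads) for t in (q, k, v))
    logits = (qh @ kh.transpose(*range(qh.ndim - 2), qh.ndim - 1, qh.ndim - 2)
              ) * (1.0 / np.sqrt(d))
    if bias is not None:
        bias = as_tensor(bias)
        try:
            np.broadcast_shapes(bias.shape, logits.shape)
        except ValueError as exc:
            raise ValueError(
                f"bias shape {bias.shape} does not broadcast to logits "
                f"{logits.shape}") from exc
        logits = logits + bias
    finite = np.isfinite(logits.data) | (logits.data <= MASK_NEG / 2)
    if not finite.all():
        raise FloatingPointError("non-finite attention logits")
    attn = F.softmax(logits, axis=-1)
    return _merge_heads(attn @ vh)


class MultiHeadAttention(Module):
    """Projected multi-head attention: per-head Q/K/V maps + output map."""

    def __init__(self, dim: int, heads: int):
        super().__init__()
        if dim % heads:
            raise ValueError(f"heads ({heads}) must divide dim ({dim})")
        self.heads = heads
        self.wq = Linear(dim, dim)
        self.wk = Linear(dim, dim)
        self.wv = Linear(dim, dim)
        self.wo = Linear(dim, dim)

    def forward(self, q, k, v, bias=None) -> Tensor:
        out = scaled_dot_attention(self.wq(q), self.wk(k), self.wv(v),
                                   self.heads, bias)
        return self.wo(out)


def multi_head_attention(q, k, v, params: MultiHeadAttention, bias=None) -> Tensor:
    """Functional alias matching the operation surface."""
    return params(as_tensor(q), as_tensor(k), as_tensor(v), bias)


# ---------------------------------------------------------------------------
# window layout / partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowLayout:
    """Window size M and cyclic shift s (0 for W-MSA, floor(M/2) for SW-MSA)."""

    window: int
    shift: int = 0

    def __post_init__(self):
        if self.window < 1:
            raise ValueError("window size must be >= 1")
        if not 0 <= self.shift < self.window:
            raise ValueError(f"shift {self.shift} must satisfy 0 <= s < M={self.window}")


def _padded_size(n: int, m: int) -> int:
    return n + (-n) % m


def window_partition(t: Tensor, layout: WindowLayout):
    """Split a token grid into flat (B*nW, M*M, E) window sequences.

    Pads bottom/right to a multiple of M, applies the cyclic shift, then
    partitions.  Returns (windows, geometry) where geometry is what
    :func:`window_reverse` needs to undo everything exactly.
    """
    t = as_tensor(t)
    B, Ht, Wt, E = t.shape
    M, s = layout.window, layout.shift
    Hp, Wp = _padded_size(Ht, M), _padded_size(Wt, M)
    if (Hp, Wp) != (Ht, Wt):
        t = t.pad(((0, 0), (0, Hp - Ht), (0, Wp - Wt), (0, 0)))
    if s:
        t = t.roll((-s, -s), (1, 2))
    nh, nw = Hp // M, Wp // M
    win = t.reshape(B, nh, M, nw, M, E).transpose(0, 1, 3, 2, 4, 5)
    win = win.reshape(B * nh * nw, M * M, E)
    return win, (B, Ht, Wt, Hp, Wp, E, M, s)


def window_reverse(windows: Tensor, geometry) -> Tensor:
    """Exact inverse of :func:`window_partition`."""
    B, Ht, Wt, Hp, Wp, E, M, s = geometry
    nh, nw = Hp // M, Wp // M
    t = windows.reshape(B, nh, nw, M, M, E).transpose(0, 1, 3, 2, 4, 5)
    t = t.reshape(B, Hp, Wp, E)
    if s:
        t = t.roll((s, s), (1, 2))
    if (Hp, Wp) != (Ht, Wt):
        t = t[:, :Ht, :Wt, :]
    return t


def window_attention_mask(height: int, width: int, layout: WindowLayout) -> np.ndarray | None:
    """Additive (nW, M^2, M^2) mask for a (height, width) grid, or None.

    Forbids attention between tokens that were not neighbours before the
    cyclic shift, and isolates zero-padded tokens (they attend only among
    themselves and contribute nothing to real tokens).
    """
    M, s = layout.window, layout.shift
    Hp, Wp = _padded_size(height, M), _padded_size(width, M)
    if s == 0 and (Hp, Wp) == (height, width):
        return None
    ids = np.zeros((Hp, Wp), dtype=np.int64)
    if s:
        # contiguity regions of the *shifted* layout (standard 3x3 slices)
        h_bounds = (slice(0, Hp - M), slice(Hp - M, Hp - s), slice(Hp - s, Hp))
        w_bounds = (slice(0, Wp - M), slice(Wp - M, Wp - s), slice(Wp - s, Wp))
        cnt = 0
        for hs in h_bounds:
            for ws in w_bounds:
                ids[hs, ws] = cnt
                cnt += 1
    if (Hp, Wp) != (height, width):
        pad = np.zeros((Hp, Wp), dtype=bool)
        pad[height:, :] = True
        pad[:, width:] = True
        if s:
            pad = np.roll(pad, (-s, -s), (0, 1))
        ids[pad] = -1
    nh, nw = Hp // M, Wp // M
    idw = ids.reshape(nh, M, nw, M).transpose(0, 2, 1, 3).reshape(nh * nw, M * M)
    same = idw[:, :, None] == idw[:, None, :]
    return np.where(same, 0.0, MASK_NEG).astype(np.float32)


# ---------------------------------------------------------------------------
# Swin transformer block
# ---------------------------------------------------------------------------

class Mlp(Module):
    def __init__(self, dim: int, ratio: int = 4):
        super().__init__()
        self.fc1 = Linear(dim, dim * ratio)
        self.act = GELU()
        self.fc2 = Linear(dim * ratio, dim)

    def forward(self, x):
        return self.fc2(self.act(self.fc1(x)))


class SwinBlock(Module):
    """Pre-norm windowed-attention transformer block.

    y   = t + (S)W-MSA(LN(t))   with relative-position bias (and, for a
                                 shifted layout, the cross-boundary mask)
                                 added to the attention logits
    out = y + MLP(LN(y))
    """

    def __init__(self, dim: int, heads: int, layout: WindowLayout, mlp_ratio: int = 4):
        super().__init__()
        self.layout = layout
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, heads)
        self.bias = RelPosBias(layout.window)
        self.ln2 = LayerNorm(dim)
        self.mlp = Mlp(dim, mlp_ratio)

    def forward(self, t: Tensor) -> Tensor:
        t = as_tensor(t)
        B, Ht, Wt, E = t.shape
        win, geom = window_partition(self.ln1(t), self.layout)
        L = self.layout.window ** 2
        bias = self.bias().reshape(1, 1, L, L)
        mask = window_attention_mask(Ht, Wt, self.layout)
        if mask is not None:
            nW = mask.shape[0]
            # windows are laid out as (B, nW) flattened; lift to broadcast per window
            attn_out = self.attn(
                win.reshape(B, nW, L, E), win.reshape(B, nW, L, E),
                win.reshape(B, nW, L, E),
                bias + Tensor(mask[None, :, None, :, :]),
            ).reshape(B * nW, L, E)
        else:
            attn_out = self.attn(win, win, win, bias)
        y = t + window_reverse(attn_out, geom)
        return y + self.mlp(self.ln2(y))


def swin_block(t, layout: WindowLayout, block: SwinBlock) -> Tensor:
    """Functional alias: apply a configured block to a token grid."""
    if block.layout != layout:
        raise ValueError("block was built for a different window layout")
    return block(as_tensor(t))


# ---------------------------------------------------------------------------
# cross attention between pyramid extremes
# ---------------------------------------------------------------------------

class CrossAttention(Module):
    """Bidirectional cross-attention between the coarse (S3) and fine (S1) grids.

    Both grids are flattened to sequences, layer-normalized, and projected
    to a shared dimension d_c.  Direction A takes queries from S3 and
    keys/values from S1 (producing F3, shaped like S3); direction B is
    symmetric (producing F1, shaped like S1).  The attended output is
    projected back to the grid's own dimension and added residually, the
    standard pre-norm cross-attention layer: the scaled dot-product core
    stays exactly Attention(q_i, k_j) = q_i . k_j / sqrt(d_k) with
    per-query softmax normalization.  ``pool_fine`` optionally
    average-pools the fine grid's keys/values 2x per axis to bound memory
    at large inputs.
    """

    def __init__(self, dim_fine: int, dim_coarse: int, dim_common: int | None = None,
                 heads: int = 8, pool_fine: bool = False):
        super().__init__()
        d_c = dim_common if dim_common is not None else 2 * dim_fine
        if d_c % heads:
            raise ValueError(f"heads ({heads}) must divide common dim ({d_c})")
        self.heads = heads
        self.pool_fine = pool_fine
        self.norm_fine = LayerNorm(dim_fine)
        self.norm_coarse = LayerNorm(dim_coarse)
        self.q_coarse = Linear(dim_coarse, d_c)
        self.k_fine = Linear(dim_fine, d_c)
        self.v_fine = Linear(dim_fine, d_c)
        self.out_coarse = Linear(d_c, dim_coarse)
        self.q_fine = Linear(dim_fine, d_c)
        self.k_coarse = Linear(dim_coarse, d_c)
        self.v_coarse = Linear(dim_coarse, d_c)
        self.out_fine = Linear(d_c, dim_fine)

    def forward(self, s3: Tensor, s1: Tensor) -> tuple[Tensor, Tensor]:
        s3, s1 = as_tensor(s3), as_tensor(s1)
        if s3.shape[0] != s1.shape[0]:
            raise ValueError(
                f"batch mismatch: s3 has {s3.shape[0]}, s1 has {s1.shape[0]}")
        B, H3, W3, E3 = s3.shape
        _, H1, W1, E1 = s1.shape
        seq3 = self.norm_coarse(s3.reshape(B, H3 * W3, E3))
        seq1 = self.norm_fine(s1.reshape(B, H1 * W1, E1))
        kv1 = seq1
        if self.pool_fine and H1 % 2 == 0 and W1 % 2 == 0:
            pooled = seq1.reshape(B, H1 // 2, 2, W1 // 2, 2, E1).mean(axis=(2, 4))
            kv1 = pooled.reshape(B, (H1 // 2) * (W1 // 2), E1)
        f3 = self.out_coarse(scaled_dot_attention(
            self.q_coarse(seq3), self.k_fine(kv1), self.v_fine(kv1), self.heads))
        f1 = self.out_fine(scaled_dot_attention(
            self.q_fine(seq1), self.k_coarse(seq3), self.v_coarse(seq3), self.heads))
        return (s1 + f1.reshape(B, H1, W1, E1),
                s3 + f3.reshape(B, H3, W3, E3))


def cross_attention(s3, s1, module: CrossAttention) -> tuple[Tensor, Tensor]:
    """Functional alias matching the operation surface."""
    return module(s3, s1)
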