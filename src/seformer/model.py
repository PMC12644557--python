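"""The dual-branch segmentation model and its ablation variants.

Dataflow of the full model (input H x W, base attention dim D)::

    stem(x) ──► SE Conv 1 (C1, H/4) ──► SE Conv 2 (C2, H/8) ──► SE Conv 3 (C3, H/16) ─► GAP = g
                   │                        │                       │
    patch_embed ─ fuse1 ─► S1 ─ SE Swin 1 ─ fuse2 ─► SE Swin 2 ──── fuse3 ─► SE Swin 3 = S3
    (D, H/4)      (D,H/4)       (2D, H/8)            (4D, H/16)              (4D, H/16)

    (F1, F3) = cross_attention(S3, S1);  logits = decode(F1, F3, g)

Each fusion site channel-concatenates the (projected, spatially aligned)
conv and attention features, recalibrates the concatenation with an SE
block and projects to the receiving branch's width ("SE-fusion"); the
``skip_fusion`` variant replaces this with projected elementwise addition.

Ablation variants mirror the architecture study: ``se_swin_only`` drops the
conv branch and its fusions, ``se_conv_only`` drops the attention branch
(cross-attention then runs on 1x1-projected conv-level reshapes),
``no_cross_attention`` feeds S1 and S3 straight to the decoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import core_blocks as cb
from .nn import functional as F
from .nn.modules import (BatchNorm2d, Conv2d, Identity, LayerNorm, Module,
                         ModuleList, ReLU, Sequential, count_parameters)
from .nn.tensor import Tensor, as_tensor, concatenate

VARIANTS = ("full", "se_swin_only", "se_conv_only", "skip_fusion",
            "no_cross_attention")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Every architectural hyperparameter of the model.

    The reference scale is Swin-T-like: D=96, conv channels (96, 192, 384),
    two attention blocks per level with (3, 6, 12) heads, window 8 on a
    512 x 512 input (token grids 128/64/32 per level).  ``reduced()`` gives
    the desk-scale configuration used for CPU training experiments.
    """

    input_size: tuple[int, int] = (512, 512)
    dim: int = 96                                   # base attention dim D
    conv_channels: tuple[int, int, int] = (96, 192, 384)
    depths: tuple[int, int, int] = (2, 2, 2)
    heads: tuple[int, int, int] = (3, 6, 12)
    window: int = 8
    se_ratio: int = 16
    decoder_channels: tuple[int, int, int] = (192, 96, 48)
    cross_heads: int = 8
    pool_fine_kv: bool = False
    threshold: float = 0.5
    seed: int = 0

    @staticmethod
    def reduced(input_size=(128, 128), seed: int = 0) -> "ModelConfig":
        return ModelConfig(input_size=input_size, dim=24,
                           conv_channels=(24, 48, 96), se_ratio=8,
                           decoder_channels=(48, 24, 12), seed=seed)

    def validate(self):
        H, W = self.input_size
        if H % 16 or W % 16:
            raise ConfigError(f"input size {self.input_size} must be divisible by 16")
        if min(H, W) < 16:
            raise ConfigError("input too small")
        if len(self.conv_channels) != 3 or len(self.depths) != 3 or len(self.heads) != 3:
            raise ConfigError("conv_channels, depths and heads must each have 3 levels")
        counts = (self.dim, self.window, self.se_ratio, self.cross_heads,
                  *self.conv_channels, *self.heads, *self.decoder_channels)
        if any(c <= 0 for c in counts):
            raise ConfigError("all architectural counts must be positive")
        if any(d < 0 for d in self.depths):
            raise ConfigError("depths must be nonnegative")
        D = self.dim
        for lvl, h in enumerate(self.heads):
            if (D * 2 ** lvl) % h:
                raise ConfigError(
                    f"heads[{lvl}]={h} must divide level dim {D * 2 ** lvl}")
        if (2 * D) % self.cross_heads:
            raise ConfigError(
                f"cross_heads={self.cross_heads} must divide common dim {2 * D}")
        r = self.se_ratio
        se_sites = {
            "conv levels": self.conv_channels,
            "attention levels": (D, 2 * D, 4 * D),
            "fusion concats": tuple(c + D * 2 ** i
                                    for i, c in enumerate(self.conv_channels)),
            "decoder fusion": (2 * self.decoder_channels[0],),
        }
        for site, chans in se_sites.items():
            for c in chans:
                if c % r:
                    raise ConfigError(
                        f"SE ratio {r} must divide channel count {c} at {site}")
        if not 0.0 < self.threshold < 1.0:
            raise ConfigError("threshold must lie in (0,1)")


# ---------------------------------------------------------------------------
# building blocks of the conv branch
# ---------------------------------------------------------------------------

class ResidualBlock(Module):
    """3x3-3x3 residual block; 1x1 projection shortcut on shape change."""

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, bias=False)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, padding=1, bias=False)
        self.bn2 = BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.shortcut = Sequential(
                Conv2d(in_ch, out_ch, 1, stride=stride, bias=False),
                BatchNorm2d(out_ch))
        else:
            self.shortcut = Identity()

    def forward(self, x):
        y = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        return (y + self.shortcut(x)).relu()


class SEConvLevel(Module):
    """Two residual blocks + SE recalibration; stride-2 entry on levels 2/3."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, ratio: int):
        super().__init__()
        self.block1 = ResidualBlock(in_ch, out_ch, stride)
        self.block2 = ResidualBlock(out_ch, out_ch, 1)
        self.se = cb.SEBlock(out_ch, ratio)

    def forward(self, x):
        feat = self.se(self.block2(self.block1(x)))
        return feat, F.global_avg_pool(feat)


class SESwinLevel(Module):
    """``depth`` Swin blocks (alternating plain / shifted windows) + SE.

    ``merge=True`` appends patch merging on exit (levels 1 and 2), halving
    the grid and doubling the dimension.
    """

    def __init__(self, dim: int, depth: int, heads: int, window: int,
                 ratio: int, merge: bool):
        super().__init__()
        self.blocks = ModuleList([
            cb.SwinBlock(dim, heads,
                         cb.WindowLayout(window, 0 if i % 2 == 0 else window // 2))
            for i in range(depth)
        ])
        # stage-exit norm: the pre-norm residual stream is unbounded, so the
        # level output is normalized before it feeds fusion / cross-attention
        self.norm = LayerNorm(dim)
        self.se = cb.SEBlock(dim, ratio)
        self.merge = cb.PatchMerge(dim) if merge else None

    def forward(self, t):
        for block in self.blocks:
            t = block(t)
        t = cb.map_to_tokens(self.se(cb.tokens_to_map(self.norm(t))))
        if self.merge is not None:
            t = self.merge(t)
        return t


class FusionBlock(Module):
    """Fuse two spatially aligned maps into ``out_ch`` channels.

    mode='se':  channel-concat -> SE recalibration -> 1x1 projection.
    mode='add': 1x1-project both inputs to out_ch and add elementwise.
    """

    def __init__(self, ch_a: int, ch_b: int, out_ch: int, ratio: int, mode: str):
        super().__init__()
        if mode not in ("se", "add"):
            raise ConfigError(f"unknown fusion mode {mode!r}")
        self.mode = mode
        if mode == "se":
            self.se = cb.SEBlock(ch_a + ch_b, ratio)
            self.proj = Conv2d(ch_a + ch_b, out_ch, 1)
        else:
            self.proj_a = Conv2d(ch_a, out_ch, 1)
            self.proj_b = Conv2d(ch_b, out_ch, 1)

    def forward(self, a, b):
        if a.shape[2:] != b.shape[2:]:
            raise ValueError(
                f"fusion requires equal spatial sizes, got {a.shape} vs {b.shape}")
        if self.mode == "se":
            return self.proj(self.se(concatenate([a, b], axis=1)))
        return self.proj_a(a) + self.proj_b(b)


class Decoder(Module):
    """F1/F3/g -> full-resolution logits.

    F3 is projected and bilinearly upsampled x4 to H/4, fused with the
    projected F1 map, channel-gated by sigmoid(1x1(g)), then two
    (upsample x2 -> 3x3 conv -> BN -> ReLU) stages reach H x W and a final
    1x1 convolution emits one logit channel.
    """

    def __init__(self, fine_ch: int, coarse_ch: int, gate_ch: int,
                 dec: tuple[int, int, int], ratio: int, fusion_mode: str):
        super().__init__()
        d1, d2, d3 = dec
        self.proj_fine = Conv2d(fine_ch, d1, 1)
        self.proj_coarse = Conv2d(coarse_ch, d1, 1)
        self.fuse = FusionBlock(d1, d1, d1, ratio, fusion_mode)
        self.gate = Conv2d(gate_ch, d1, 1)
        self.conv_up1 = Conv2d(d1, d2, 3, padding=1, bias=False)
        self.bn1 = BatchNorm2d(d2)
        self.conv_up2 = Conv2d(d2, d3, 3, padding=1, bias=False)
        self.bn2 = BatchNorm2d(d3)
        self.head = Conv2d(d3, 1, 1)

    def forward(self, f1_map, f3_map, g):
        h4, w4 = f1_map.shape[2], f1_map.shape[3]
        if (f3_map.shape[2], f3_map.shape[3]) != (h4 // 4, w4 // 4):
            raise ValueError(
                f"decoder expects F3 at a quarter of F1's grid, got {f3_map.shape} vs {f1_map.shape}")
        up3 = F.upsample_bilinear(self.proj_coarse(f3_map), h4, w4)
        fused = self.fuse(self.proj_fine(f1_map), up3)
        fused = fused * self.gate(g).sigmoid()
        x = self.bn1(self.conv_up1(
            F.upsample_bilinear(fused, 2 * h4, 2 * w4))).relu()
        x = self.bn2(self.conv_up2(
            F.upsample_bilinear(x, 4 * h4, 4 * w4))).relu()
        return self.head(x)


# ---------------------------------------------------------------------------
# the assembled model
# ---------------------------------------------------------------------------

class SEFormer(Module):
    def __init__(self, cfg: ModelConfig = ModelConfig(), variant: str = "full"):
        super().__init__()
        cfg.validate()
        if variant not in VARIANTS:
            raise ConfigError(f"unknown variant {variant!r}; choose from {VARIANTS}")
        self.cfg = cfg
        self.variant = variant
        D = cfg.dim
        C1, C2, C3 = cfg.conv_channels
        r = cfg.se_ratio
        fusion_mode = "add" if variant == "skip_fusion" else "se"
        has_conv = variant != "se_swin_only"
        has_swin = variant != "se_conv_only"
        has_cross = variant != "no_cross_attention"

        if has_conv:
            self.stem = Sequential(
                Conv2d(3, max(C1 // 2, 8), 3, stride=2, padding=1, bias=False),
                BatchNorm2d(max(C1 // 2, 8)), ReLU(),
                Conv2d(max(C1 // 2, 8), C1, 3, stride=2, padding=1, bias=False),
                BatchNorm2d(C1), ReLU(),
            )
            self.conv1 = SEConvLevel(C1, C1, 1, r)
            self.conv2 = SEConvLevel(C1, C2, 2, r)
            self.conv3 = SEConvLevel(C2, C3, 2, r)

        if has_swin:
            self.embed = cb.PatchEmbed(4, 3, D)
            self.swin1 = SESwinLevel(D, cfg.depths[0], cfg.heads[0], cfg.window, r, True)
            self.swin2 = SESwinLevel(2 * D, cfg.depths[1], cfg.heads[1], cfg.window, r, True)
            self.swin3 = SESwinLevel(4 * D, cfg.depths[2], cfg.heads[2], cfg.window, r, False)
            if has_conv:
                self.fuse1 = FusionBlock(C1, D, D, r, fusion_mode)
                self.fuse2 = FusionBlock(C2, 2 * D, 2 * D, r, fusion_mode)
                self.fuse3 = FusionBlock(C3, 4 * D, 4 * D, r, fusion_mode)
        else:
            # cross-attention operates on 1x1-projected conv-level reshapes
            self.proj_s1 = Conv2d(C1, D, 1)
            self.proj_s3 = Conv2d(C3, 4 * D, 1)

        if has_cross:
            self.cross = cb.CrossAttention(D, 4 * D, 2 * D, cfg.cross_heads,
                                           cfg.pool_fine_kv)

        gate_ch = 4 * D if not has_conv else C3
        self.decoder = Decoder(D, 4 * D, gate_ch, cfg.decoder_channels, r,
                               fusion_mode)

    # -- wiring ---------------------------------------------------------------
    def forward(self, images) -> Tensor:
        x = as_tensor(images)
        H, W = self.cfg.input_size
        if x.ndim != 4 or x.shape[1] != 3 or x.shape[2:] != (H, W):
            raise ValueError(
                f"expected input of shape (B, 3, {H}, {W}), got {x.shape}")
        feats = self.pyramid_features(x)
        s1, s3, g = feats["s1"], feats["s3"], feats["g"]
        if self.variant != "no_cross_attention":
            f1, f3 = self.cross(s3, s1)
        else:
            f1, f3 = s1, s3
        return self.decoder(cb.tokens_to_map(f1), cb.tokens_to_map(f3), g)

    def pyramid_features(self, x: Tensor) -> dict:
        """Run both branches and the fusion sites; return S1/S3/g (+ conv levels)."""
        has_conv = self.variant != "se_swin_only"
        has_swin = self.variant != "se_conv_only"
        out: dict = {}
        if has_conv:
            c1, _ = self.conv1(self.stem(x))
            c2, _ = self.conv2(c1)
            c3, p3 = self.conv3(c2)
            out.update(c1=c1, c2=c2, c3=c3, g=p3)
        if has_swin:
            t0 = self.embed(x)
            if has_conv:
                s1 = cb.map_to_tokens(self.fuse1(c1, cb.tokens_to_map(t0)))
            else:
                s1 = t0
            z1 = self.swin1(s1)                      # H/8, 2D
            if has_conv:
                z1 = cb.map_to_tokens(self.fuse2(c2, cb.tokens_to_map(z1)))
            z2 = self.swin2(z1)                      # H/16, 4D
            if has_conv:
                z2 = cb.map_to_tokens(self.fuse3(c3, cb.tokens_to_map(z2)))
            s3 = self.swin3(z2)                      # H/16, 4D
            out.update(s1=s1, s3=s3)
            if not has_conv:
                out["g"] = F.global_avg_pool(cb.tokens_to_map(s3))
        else:
            out["s1"] = cb.map_to_tokens(self.proj_s1(c1))
            out["s3"] = cb.map_to_tokens(self.proj_s3(c3))
        return out

    def predict_proba(self, images) -> np.ndarray:
        """Eval-mode sigmoid probabilities, no graph recorded."""
        from .nn.tensor import no_grad
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                prob = self.forward(images).sigmoid().data
        finally:
            self.train(was_training)
        return prob

    def predict_mask(self, images) -> np.ndarray:
        return (self.predict_proba(images) >= self.cfg.threshold)[:, 0]


def build_model(cfg: ModelConfig = ModelConfig(), variant: str = "full",
                seed: int | None = None) -> SEFormer:
    """Construct and He-normal-initialize a model, seeded for bitwise rebuilds."""
    model = SEFormer(cfg, variant)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    model.initialize(rng)
    return model


__all__ = ["ModelConfig", "SEFormer", "build_model", "count_parameters",
           "VARIANTS", "ConfigError"]
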