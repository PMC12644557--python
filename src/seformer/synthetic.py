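"""Procedural fundus-like image/mask pairs for download-free testing.

Real retinal photographs show a circular field of view (FOV), a smooth
reddish-orange background with radial illumination falloff, and dark,
thin, branching curvilinear vessels occupying a small fraction of the
pixels.  The generator reproduces exactly this *statistical* structure —
connected width-tapering random binary trees stamped as anti-aliased
discs, rendered over a shaded background with additive noise — without
attempting photorealism (no optic disc, fovea or pathology).

Everything is deterministic given (config, seed): masks are bitwise
reproducible, images reproducible to float rounding.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["SynthConfig", "SamplePair", "grow_vessel_tree", "render_fundus",
           "generate_dataset", "write_dataset", "regenerate_from_manifest"]


@dataclass(frozen=True)
class SynthConfig:
    """Geometry, tree-growth and rendering parameters.

    Defaults are tuned so masks land in ``vessel_fraction_range`` —
    the class imbalance regime (vessels ~5-12% of pixels) that motivates
    the Dice term of the training loss.
    """

    side: int = 128                      # square image side, pixels
    fov_radius_frac: float = 0.48        # FOV radius as fraction of side
    trees: int = 3                       # roots started on the FOV boundary
    branch_prob: float = 0.05            # per-step bifurcation probability
    init_half_width: float = 2.0         # root half-width, pixels
    min_half_width: float = 0.55         # termination width, pixels
    step_length: float = 1.4             # walker advance per step, pixels
    curvature_jitter: float = 0.16       # heading jitter per step, radians
    width_taper: float = 0.987           # per-step multiplicative taper
    child_width_frac: tuple[float, float] = (0.6, 0.8)  # U(a,b) at branching
    branch_angle: tuple[float, float] = (0.35, 0.9)     # |Δheading| at branching
    contrast: float = 0.55               # vessel darkening factor
    illumination_strength: float = 0.35  # radial falloff amplitude
    noise_sigma: float = 0.02            # additive Gaussian noise
    vessel_fraction_range: tuple[float, float] = (0.05, 0.12)
    base_color: tuple[float, float, float] = (0.82, 0.42, 0.20)

    def __post_init__(self):
        if self.side < 16 or self.trees < 1:
            raise ValueError("degenerate config: side >= 16 and trees >= 1 required")
        if self.min_half_width < 0.5:
            raise ValueError("minimum half-width must be >= 0.5 px")
        if self.init_half_width <= self.min_half_width:
            raise ValueError("initial half-width must exceed the minimum")
        if self.step_length <= 0:
            raise ValueError("step length must be positive")
        lo, hi = self.vessel_fraction_range
        if not (0.0 < lo < hi < 0.35):
            raise ValueError("vessel fraction range must lie inside (0, 0.35)")


@dataclass
class SamplePair:
    """One image/mask pair: image (3,H,W) float32 in [0,1], mask (H,W) bool."""

    image: np.ndarray
    mask: np.ndarray
    id: str


def _fov_disc(side: int, radius: float) -> np.ndarray:
    c = (side - 1) / 2.0
    yy, xx = np.mgrid[0:side, 0:side]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def _stamp_disc(canvas: np.ndarray, y: float, x: float, r: float):
    """max-accumulate an anti-aliased disc of radius r at (y, x)."""
    side = canvas.shape[0]
    pad = int(np.ceil(r)) + 1
    y0, y1 = max(int(y) - pad, 0), min(int(y) + pad + 1, side)
    x0, x1 = max(int(x) - pad, 0), min(int(x) + pad + 1, side)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(yy - y, xx - x)
    cover = np.clip(r + 0.5 - dist, 0.0, 1.0)
    np.maximum(canvas[y0:y1, x0:x1], cover, out=canvas[y0:y1, x0:x1])


def grow_vessel_tree(cfg: SynthConfig, seed: int) -> np.ndarray:
    """Grow the vessel trees of one image; returns a binary (side, side) mask.

    Each tree root sits on the FOV boundary aiming inward; walkers advance
    by ``step_length`` with heading jittered by ``curvature_jitter``,
    bifurcate with ``branch_prob`` (children inherit a U(0.6, 0.8) width
    fraction), taper multiplicatively each step, and terminate below
    ``min_half_width`` or on leaving the FOV.  Discs are anti-aliased then
    thresholded at 0.5, keeping the mask strictly binary.
    """
    rng = np.random.default_rng(seed)
    side = cfg.side
    c = (side - 1) / 2.0
    R = cfg.fov_radius_frac * side
    canvas = np.zeros((side, side), dtype=np.float64)
    stack: list[tuple[float, float, float, float]] = []  # y, x, heading, half-width
    for _ in range(cfg.trees):
        theta = rng.uniform(0.0, 2 * np.pi)
        y, x = c + 0.98 * R * np.sin(theta), c + 0.98 * R * np.cos(theta)
        heading = theta + np.pi + rng.uniform(-0.4, 0.4)  # aimed inward
        stack.append((y, x, heading, cfg.init_half_width))
    max_segments = 4000  # safety bound, never reached at default scale
    segments = 0
    while stack and segments < max_segments:
        y, x, heading, w = stack.pop()
        segments += 1
        while w >= cfg.min_half_width:
            _stamp_disc(canvas, y, x, w)
            heading += rng.normal(0.0, cfg.curvature_jitter)
            y += cfg.step_length * np.sin(heading)
            x += cfg.step_length * np.cos(heading)
            if (y - c) ** 2 + (x - c) ** 2 > R**2:
                break
            w *= cfg.width_taper
            if rng.random() < cfg.branch_prob and w > 1.4 * cfg.min_half_width:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                dtheta = sign * rng.uniform(*cfg.branch_angle)
                frac = rng.uniform(*cfg.child_width_frac)
                stack.append((y, x, heading + dtheta, w * frac))
    mask = canvas >= 0.5
    mask &= _fov_disc(side, R)
    return mask


def render_fundus(mask: np.ndarray, cfg: SynthConfig, seed: int) -> np.ndarray:
    """Render a (3, side, side) float32 image in [0,1] for a vessel mask.

    Reddish-orange base field x radial illumination falloff + low-frequency
    shading; vessels darken the field by the contrast factor (blurred at
    sub-pixel widths); additive Gaussian noise; black outside the FOV.
    """
    rng = np.random.default_rng(seed)
    side = cfg.side
    c = (side - 1) / 2.0
    R = cfg.fov_radius_frac * side
    yy, xx = np.mgrid[0:side, 0:side]
    d2 = ((yy - c) ** 2 + (xx - c) ** 2) / R**2
    illum = 1.0 - cfg.illumination_strength * np.clip(d2, 0.0, 1.0)
    shading = gaussian_filter(rng.standard_normal((side, side)), sigma=side / 8.0)
    peak = np.abs(shading).max()
    if peak > 0:
        shading *= 0.5 * cfg.illumination_strength / peak
    field = illum * (1.0 + shading)
    vessel_soft = gaussian_filter(mask.astype(np.float64), sigma=0.7)
    attenuation = 1.0 - cfg.contrast * np.clip(vessel_soft, 0.0, 1.0)
    img = np.array(cfg.base_color, dtype=np.float64)[:, None, None] * field * attenuation
    if cfg.noise_sigma > 0:
        img = img + rng.normal(0.0, cfg.noise_sigma, img.shape)
    img *= _fov_disc(side, R)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def generate_dataset(n: int, cfg: SynthConfig = SynthConfig(), seed: int = 0
                     ) -> tuple[list[SamplePair], dict]:
    """n pairs with ids synth_0000..., per-sample seeds seed+index, + manifest."""
    if n < 1:
        raise ValueError("n must be >= 1")
    pairs = []
    for i in range(n):
        s = seed + i
        mask = grow_vessel_tree(cfg, s)
        image = render_fundus(mask, cfg, s + 500_000)
        pairs.append(SamplePair(image=image, mask=mask, id=f"synth_{i:04d}"))
    manifest = {
        "config": asdict(cfg),
        "seed": int(seed),
        "samples": [{"id": p.id, "seed": int(seed + i)} for i, p in enumerate(pairs)],
    }
    return pairs, manifest


def write_dataset(pairs: list[SamplePair], manifest: dict, out_dir,
                  mask_suffix: str = "_mask") -> Path:
    """Write paired PNGs (<id>.png / <id><mask_suffix>.png) and manifest.json."""
    from PIL import Image

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        for p in pairs:
            rgb = np.round(p.image.transpose(1, 2, 0) * 255.0).astype(np.uint8)
            Image.fromarray(rgb).save(out / f"{p.id}.png")
            Image.fromarray((p.mask * np.uint8(255))).save(
                out / f"{p.id}{mask_suffix}.png")
        manifest = dict(manifest, mask_suffix=mask_suffix)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except OSError as exc:
        raise OSError(f"failed writing synthetic dataset under {out}: {exc}") from exc
    return out


def regenerate_from_manifest(manifest: dict) -> list[SamplePair]:
    """Rebuild the exact pairs a manifest describes (bitwise for masks)."""
    cfg = SynthConfig(**{k: tuple(v) if isinstance(v, list) else v
                         for k, v in manifest["config"].items()})
    pairs, _ = generate_dataset(len(manifest["samples"]), cfg, manifest["seed"])
    return pairs
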