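"""Reading, resizing, augmenting and splitting image/mask pairs.

Supports the folder layouts of the public retinal datasets (CHASE_DB1,
DRIVE, STARE) and of the synthetic generator.  The training pipeline is:
read -> resize to the model's input size (bilinear image / nearest mask)
-> normalize to [0,1] -> (training only) stochastic augmentation.
Geometric transforms are applied identically to image and mask; the mask
is re-binarized after every interpolating step.  Evaluation loaders never
augment — there is deliberately no "augment at eval" switch to misuse.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .synthetic import SamplePair

__all__ = ["AugmentConfig", "SplitSpec", "read_pair", "resize_normalize",
           "augment", "split_dataset", "discover_pairs", "LAYOUTS"]


@dataclass(frozen=True)
class AugmentConfig:
    """Stochastic training-time augmentation.

    Flips (p=0.5 each), rotation uniform within ±10°, brightness/contrast
    within ±0.2 (image only), and — each independently with p=0.3 —
    elastic deformation (both channels) and additive Gaussian noise
    (image only).  Applied in exactly that order.
    """

    p_hflip: float = 0.5
    p_vflip: float = 0.5
    rotation_limit: float = 10.0          # degrees
    brightness_limit: float = 0.2
    contrast_limit: float = 0.2
    elastic_alpha: float = 40.0           # displacement amplitude, pixels
    elastic_sigma: float = 6.0            # displacement smoothness, pixels
    p_elastic: float = 0.3
    noise_sigma_range: tuple[float, float] = (0.01, 0.05)
    p_noise: float = 0.3
    enabled: bool = True

    def __post_init__(self):
        for p in (self.p_hflip, self.p_vflip, self.p_elastic, self.p_noise):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0,1]")
        if self.rotation_limit < 0 or self.brightness_limit < 0 or self.contrast_limit < 0:
            raise ValueError("augmentation limits must be nonnegative")


@dataclass(frozen=True)
class SplitSpec:
    """Deterministic train/val/test partition of a list of sample ids."""

    train: tuple[str, ...]
    val: tuple[str, ...]
    test: tuple[str, ...]
    fractions: tuple[float, float, float]
    seed: int

    def __post_init__(self):
        parts = (set(self.train), set(self.val), set(self.test))
        total = sum(len(p) for p in parts)
        if total != len(set().union(*parts)):
            raise ValueError("split partitions must be disjoint")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_pair(image_path, mask_path) -> SamplePair:
    """Load an image/mask pair; image (3,H,W) float in [0,1], mask binary.

    Grayscale images are replicated to 3 channels; the mask is binarized
    at half its dynamic range.
    """
    from PIL import Image, UnidentifiedImageError

    image_path, mask_path = Path(image_path), Path(mask_path)
    for p in (image_path, mask_path):
        if not p.exists():
            raise FileNotFoundError(f"no such file: {p}")
    try:
        img = np.asarray(Image.open(image_path))
    except UnidentifiedImageError as exc:
        raise ValueError(f"unreadable image format: {image_path}") from exc
    try:
        msk = np.asarray(Image.open(mask_path))
    except UnidentifiedImageError as exc:
        raise ValueError(f"unreadable mask format: {mask_path}") from exc
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    if img.shape[2] == 4:
        img = img[:, :, :3]
    if msk.ndim == 3:
        msk = msk[:, :, 0]
    if img.shape[:2] != msk.shape[:2]:
        raise ValueError(
            f"size mismatch: image {image_path} is {img.shape[:2]}, "
            f"mask {mask_path} is {msk.shape[:2]}")
    image = (img.astype(np.float32) / 255.0).transpose(2, 0, 1)
    lo, hi = float(msk.min()), float(msk.max())
    thr = lo + 0.5 * (hi - lo) if hi > lo else 0.5
    mask = msk.astype(np.float32) > thr if hi > lo else msk.astype(bool)
    return SamplePair(image=image, mask=mask, id=image_path.stem)


# ---------------------------------------------------------------------------
# dataset layouts
# ---------------------------------------------------------------------------

def _pairs_chasedb1(root: Path):
    for img in sorted(root.glob("Image_*")):
        if "_1stHO" in img.name or "_2ndHO" in img.name:
            continue
        mask = root / f"{img.stem}_1stHO.png"
        yield img, mask

def _pairs_drive(root: Path):
    for img in sorted((root / "images").glob("*")):
        num = img.name.split("_")[0]
        mask = root / "1st_manual" / f"{num}_manual1.gif"
        yield img, mask

def _pairs_stare(root: Path):
    for img in sorted((root / "images").glob("im*")):
        mask = root / "labels-ah" / f"{img.stem}.ah{img.suffix}"
        yield img, mask

def _pairs_synth(root: Path):
    for img in sorted(root.glob("synth_*.png")):
        if img.stem.endswith("_mask"):
            continue
        yield img, root / f"{img.stem}_mask.png"

LAYOUTS = {"chasedb1": _pairs_chasedb1, "drive": _pairs_drive,
           "stare": _pairs_stare, "synth": _pairs_synth}


def discover_pairs(root, layout: str) -> list[SamplePair]:
    """Walk a dataset root with the given layout rule and read every pair."""
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; choose from {sorted(LAYOUTS)}")
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(f"dataset root does not exist: {root}")
    pairs = [read_pair(i, m) for i, m in LAYOUTS[layout](root)]
    if not pairs:
        raise FileNotFoundError(f"no {layout}-layout pairs found under {root}")
    return pairs


# ---------------------------------------------------------------------------
# resize / augment
# ---------------------------------------------------------------------------

def resize_normalize(pair: SamplePair, target: tuple[int, int] = (512, 512)
                     ) -> SamplePair:
    """Bilinear-resize the image, nearest-resize + re-binarize the mask."""
    from skimage.transform import resize

    h, w = target
    if pair.image.shape[1:] == (h, w):
        return SamplePair(np.clip(pair.image, 0.0, 1.0).astype(np.float32),
                          pair.mask.astype(bool), pair.id)
    img = resize(pair.image, (3, h, w), order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    msk = resize(pair.mask.astype(np.float32), (h, w), order=0, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return SamplePair(np.clip(img, 0.0, 1.0).astype(np.float32),
                      msk > 0.5, pair.id)


def _rotate(channel: np.ndarray, angle: float, order: int) -> np.ndarray:
    return ndimage.rotate(channel, angle, reshape=False, order=order,
                          mode="reflect")


def _elastic_field(shape, alpha, sigma, rng):
    dy = ndimage.gaussian_filter(rng.uniform(-1, 1, shape), sigma) * alpha
    dx = ndimage.gaussian_filter(rng.uniform(-1, 1, shape), sigma) * alpha
    yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return yy + dy, xx + dx


def augment(pair: SamplePair, cfg: AugmentConfig, rng: np.random.Generator
            ) -> SamplePair:
    """One stochastic augmentation draw; deterministic given the rng state."""
    img = pair.image.copy()
    msk = pair.mask.astype(np.float32)
    if not cfg.enabled:
        return SamplePair(img, msk > 0.5, pair.id)
    if rng.random() < cfg.p_hflip:
        img, msk = img[:, :, ::-1], msk[:, ::-1]
    if rng.random() < cfg.p_vflip:
        img, msk = img[:, ::-1, :], msk[::-1, :]
    if cfg.rotation_limit > 0:
        angle = rng.uniform(-cfg.rotation_limit, cfg.rotation_limit)
        img = np.stack([_rotate(c, angle, 1) for c in img])
        msk = _rotate(msk, angle, 0)
    if cfg.brightness_limit > 0 or cfg.contrast_limit > 0:
        b = rng.uniform(-cfg.brightness_limit, cfg.brightness_limit)
        c = 1.0 + rng.uniform(-cfg.contrast_limit, cfg.contrast_limit)
        img = (img - 0.5) * c + 0.5 + b
    if rng.random() < cfg.p_elastic:
        coords = _elastic_field(msk.shape, cfg.elastic_alpha, cfg.elastic_sigma, rng)
        img = np.stack([
            ndimage.map_coordinates(ch, coords, order=1, mode="reflect")
            for ch in img])
        msk = ndimage.map_coordinates(msk, coords, order=0, mode="reflect")
    if rng.random() < cfg.p_noise:
        sigma = rng.uniform(*cfg.noise_sigma_range)
        img = img + rng.normal(0.0, sigma, img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return SamplePair(np.ascontiguousarray(img), msk > 0.5, pair.id)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(ids, fractions=(0.6, 0.2, 0.2), seed: int = 0) -> SplitSpec:
    """Shuffle ids by seed; nearest-round train and val sizes, remainder test.

    The rounding rule (round train, round val, remainder to test) is the
    simple rule reproducing both 28 -> (17, 6, 5) at (0.6, 0.2, 0.2) and
    20 -> (16, 0, 4) at (0.8, 0, 0.2).
    """
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ValueError("sample ids must be unique")
    f_train, f_val, f_test = fractions
    if min(fractions) < 0 or abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise ValueError("fractions must be nonnegative and sum to 1")
    n = len(ids)
    n_train = round(f_train * n)
    n_val = round(f_val * n)
    n_test = n - n_train - n_val
    if n_test < 0:
        raise ValueError(
            f"rounded train ({n_train}) + val ({n_val}) exceed n={n}; "
            "adjust the fractions")
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in order]
    return SplitSpec(
        train=tuple(shuffled[:n_train]),
        val=tuple(shuffled[n_train:n_train + n_val]),
        test=tuple(shuffled[n_train + n_val:]),
        fractions=tuple(fractions),
        seed=seed,
    )
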