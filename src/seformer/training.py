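"""Optimization loop, LR scheduling, early stopping, checkpoints, evaluation.

Protocol: Adam (beta1=0.9, beta2=0.999, weight decay 1e-5), batch 4, up to
200 epochs.  After each epoch the validation loss and validation Dice are
computed without augmentation; the learning rate is multiplied by 0.1 when
the validation loss fails to improve for 10 consecutive epochs
(reduce-on-plateau), training halts early after 20 epochs of stagnant
validation Dice, and the checkpoint with the highest validation Dice
(earliest epoch on ties) is kept.  "Improvement" everywhere means strictly
better than the best so far by more than a small tolerance — ties count as
stagnation.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .data import AugmentConfig, augment, resize_normalize
from .losses import LossConfig, combined_loss
from .metrics import MetricsReport, confusion_counts, segmentation_metrics
from .model import ModelConfig, SEFormer
from .nn.optim import Adam
from .nn.tensor import no_grad
from .synthetic import SamplePair

__all__ = ["TrainConfig", "History", "PlateauScheduler", "EarlyStopper",
           "train_loop", "evaluate", "predict", "save_checkpoint",
           "load_checkpoint", "TrainingDiverged"]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 1e-5
    batch_size: int = 4
    epochs: int = 200
    scheduler_factor: float = 0.1
    scheduler_patience: int = 10          # epochs of stagnant val loss
    early_stop_patience: int = 20         # epochs of stagnant val Dice
    improvement_tol: float = 1e-6
    mixed_precision: bool = False
    seed: int = 0
    checkpoint_dir: str | None = None

    def __post_init__(self):
        if self.lr <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("lr must be positive, batch_size >= 1, epochs >= 0")
        if self.scheduler_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patience values must be >= 1")


@dataclass
class History:
    """Per-epoch training record; epoch indices are 1-based."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    wall_time: list[float] = field(default_factory=list)
    best_epoch: int = 0
    lr_reductions: list[int] = field(default_factory=list)
    stopped_epoch: int = 0

    def __len__(self):
        return len(self.train_loss)

    def to_csv(self, path):
        lines = ["epoch,train_loss,val_loss,val_dice,lr,wall_time"]
        for i in range(len(self)):
            lines.append(f"{i + 1},{self.train_loss[i]:.6f},{self.val_loss[i]:.6f},"
                         f"{self.val_dice[i]:.6f},{self.lr[i]:.8g},{self.wall_time[i]:.3f}")
        Path(path).write_text("\n".join(lines) + "\n")


class PlateauScheduler:
    """Reduce-on-plateau: multiply lr by ``factor`` after ``patience``
    consecutive epochs without strict improvement of the monitored loss."""

    def __init__(self, optimizer: Adam | None, factor: float = 0.1,
                 patience: int = 10, tol: float = 1e-6):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.tol = tol
        self.best = np.inf
        self.stagnant = 0
        self.reduction_epochs: list[int] = []
        self._epoch = 0

    @property
    def lr(self):
        return self.optimizer.lr if self.optimizer is not None else None

    def step(self, value: float) -> bool:
        """Record one epoch's monitored value; returns True if lr was reduced."""
        self._epoch += 1
        if value < self.best - self.tol:
            self.best = value
            self.stagnant = 0
            return False
        self.stagnant += 1
        if self.stagnant >= self.patience:
            if self.optimizer is not None:
                self.optimizer.lr *= self.factor
            self.reduction_epochs.append(self._epoch)
            self.stagnant = 0
            return True
        return False


class EarlyStopper:
    """Stop after ``patience`` consecutive epochs of stagnant (maximized) score."""

    def __init__(self, patience: int = 20, tol: float = 1e-6):
        self.patience = patience
        self.tol = tol
        self.best = -np.inf
        self.best_epoch = 0
        self.stagnant = 0
        self._epoch = 0

    def step(self, value: float) -> bool:
        """Record one epoch's score; returns True if training should stop."""
        self._epoch += 1
        if value > self.best + self.tol:
            self.best = value
            self.best_epoch = self._epoch
            self.stagnant = 0
            return False
        self.stagnant += 1
        return self.stagnant >= self.patience


class TrainingDiverged(RuntimeError):
    """Raised on a non-finite loss; the last finite state was saved."""


# ---------------------------------------------------------------------------
# checkpoint format: a single .npz holding JSON metadata + parameter arrays
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: SEFormer, optimizer: Adam | None = None,
                    extra: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"model_config": asdict(model.cfg), "variant": model.variant,
            "extra": extra or {}}
    arrays = {f"state/{k}": v for k, v in model.state_dict().items()}
    if optimizer is not None:
        opt = optimizer.state_dict()
        meta["optimizer"] = {"t": opt["t"], "lr": opt["lr"]}
        for i, (m, v) in enumerate(zip(opt["m"], opt["v"])):
            arrays[f"opt_m/{i}"] = m
            arrays[f"opt_v/{i}"] = v
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def load_checkpoint(path) -> tuple[SEFormer, dict]:
    """Rebuild the model a checkpoint describes; returns (model, metadata)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no checkpoint at {path}")
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]))
        cfg_dict = {k: tuple(v) if isinstance(v, list) else v
                    for k, v in meta["model_config"].items()}
        model = SEFormer(ModelConfig(**cfg_dict), meta["variant"])
        model.load_state_dict({k[len("state/"):]: npz[k]
                               for k in npz.files if k.startswith("state/")})
    return model, meta


# ---------------------------------------------------------------------------
# batching helpers
# ---------------------------------------------------------------------------

def _batch_arrays(samples: list[SamplePair]):
    x = np.stack([s.image for s in samples]).astype(np.float32)
    y = np.stack([s.mask for s in samples]).astype(np.float32)[:, None]
    return x, y


def refresh_bn_stats(model, samples: list[SamplePair], batch_size: int = 4):
    """Re-estimate BatchNorm running statistics over ``samples`` (precise BN).

    With small batches and a fast-moving optimizer the exponential running
    stats lag the weights, so eval-mode behaviour drifts away from
    train-mode behaviour.  This pass resets the buffers and replaces them
    with the average batch statistics under the *current* weights.
    """
    from .nn.modules import BatchNorm2d

    bns = [m for _, m in model.named_modules() if isinstance(m, BatchNorm2d)]
    if not bns:
        return
    saved = [bn.momentum for bn in bns]
    for bn in bns:
        bn.running_mean[...] = 0.0
        bn.running_var[...] = 0.0
    was_training = model.training
    model.train()
    with no_grad():
        for t, i in enumerate(range(0, len(samples), batch_size), start=1):
            for bn in bns:
                bn.momentum = 1.0 / t   # cumulative average of batch stats
            x, _ = _batch_arrays(samples[i:i + batch_size])
            model(x)
    for bn, m in zip(bns, saved):
        bn.momentum = m
    model.train(was_training)


def _validate(model, val_set, loss_cfg, batch_size):
    model.eval()
    losses, counts = [], np.zeros(4, dtype=np.int64)
    with no_grad():
        for i in range(0, len(val_set), batch_size):
            x, y = _batch_arrays(val_set[i:i + batch_size])
            prob = model(x).sigmoid()
            losses.append(combined_loss(prob, y, loss_cfg).item() * len(y))
            pred = prob.data >= model.cfg.threshold
            counts += np.array(confusion_counts(pred, y.astype(bool)))
    model.train()
    tp, fp, fn, _ = counts
    dice = 1.0 if (2 * tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn)
    return float(np.sum(losses) / len(val_set)), float(dice)


def train_loop(model: SEFormer, train_set: list[SamplePair],
               val_set: list[SamplePair], cfg: TrainConfig = TrainConfig(),
               loss_cfg: LossConfig = LossConfig(),
               augment_cfg: AugmentConfig | None = None,
               run_dir=None, verbose: bool = False):
    """Train ``model``; returns (History, best_state_dict).

    ``augment_cfg`` (if given and enabled) is applied to training batches
    only; validation always runs clean.  The best checkpoint (highest
    validation Dice, earliest epoch on ties) is returned and, when
    ``run_dir`` is set, persisted to ``<run_dir>/best.npz`` along with
    ``history.csv``.
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    if cfg.mixed_precision:
        warnings.warn("the numpy backend has no half-precision kernels; "
                      "mixed_precision is accepted but runs in float32")
    run_dir = Path(run_dir) if run_dir is not None else None
    if run_dir is not None:
        run_dir.mkdir(parents=True, exist_ok=True)

    optimizer = Adam(model.parameters(), lr=cfg.lr, betas=cfg.betas,
                     weight_decay=cfg.weight_decay)
    scheduler = PlateauScheduler(optimizer, cfg.scheduler_factor,
                                 cfg.scheduler_patience, cfg.improvement_tol)
    stopper = EarlyStopper(cfg.early_stop_patience, cfg.improvement_tol)
    history = History()
    best_state = None
    best_dice = -np.inf
    t_start = time.time()

    model.train()
    for epoch in range(1, cfg.epochs + 1):
        order = np.random.default_rng([cfg.seed, epoch]).permutation(len(train_set))
        aug_rng = np.random.default_rng([cfg.seed, epoch, 7])
        epoch_losses = []
        for i in range(0, len(order), cfg.batch_size):
            batch = [train_set[j] for j in order[i:i + cfg.batch_size]]
            if augment_cfg is not None and augment_cfg.enabled:
                batch = [augment(s, augment_cfg, aug_rng) for s in batch]
            x, y = _batch_arrays(batch)
            model.zero_grad()
            loss = combined_loss(model(x).sigmoid(), y, loss_cfg)
            value = loss.item()
            if not np.isfinite(value):
                if run_dir is not None:
                    save_checkpoint(run_dir / "diverged.npz", model, optimizer)
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}; last finite state saved")
            loss.backward()
            optimizer.step()
            epoch_losses.append(value)

        refresh_bn_stats(model, train_set, cfg.batch_size)
        val_loss, val_dice = _validate(model, val_set, loss_cfg, cfg.batch_size)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        history.val_dice.append(val_dice)
        history.lr.append(optimizer.lr)
        history.wall_time.append(time.time() - t_start)
        if verbose:
            print(f"epoch {epoch:3d}  train {history.train_loss[-1]:.4f}  "
                  f"val {val_loss:.4f}  dice {val_dice:.4f}  lr {optimizer.lr:g}")

        # strict improvement required -> ties keep the earliest best epoch
        if best_state is None or val_dice > best_dice + cfg.improvement_tol:
            best_state = model.state_dict()
            best_dice = val_dice
            history.best_epoch = epoch
        scheduler.step(val_loss)
        history.lr_reductions = list(scheduler.reduction_epochs)
        if stopper.step(val_dice):
            history.stopped_epoch = epoch
            break

    if best_state is not None:
        model.load_state_dict(best_state)
    if run_dir is not None:
        history.to_csv(run_dir / "history.csv")
        if best_state is not None:
            save_checkpoint(run_dir / "best.npz", model, optimizer,
                            extra={"best_epoch": history.best_epoch})
    return history, best_state


# ---------------------------------------------------------------------------
# evaluation / prediction
# ---------------------------------------------------------------------------

def evaluate(model, dataset: list[SamplePair], threshold: float = 0.5,
             batch_size: int = 4) -> tuple[MetricsReport, list[MetricsReport]]:
    """Deterministic eval-mode metrics: micro-aggregated + per-image reports."""
    if not dataset:
        raise ValueError("cannot evaluate on an empty dataset")
    was_training = getattr(model, "training", False)
    if hasattr(model, "eval"):
        model.eval()
    per_image = []
    total = np.zeros(4, dtype=np.int64)
    try:
        with no_grad():
            for i in range(0, len(dataset), batch_size):
                chunk = dataset[i:i + batch_size]
                x, y = _batch_arrays(chunk)
                prob = model(x).sigmoid().data
                pred = prob >= threshold
                for b in range(len(chunk)):
                    counts = confusion_counts(pred[b, 0], y[b, 0].astype(bool))
                    per_image.append(segmentation_metrics(counts))
                    total += np.array(counts)
    finally:
        if hasattr(model, "train"):
            model.train(was_training)
    return segmentation_metrics(tuple(total)), per_image


def predict(checkpoint_path, image_paths, out_dir, write_prob: bool = False):
    """Segment images with a trained checkpoint; writes binary PNG masks.

    Each image is resized through the model's input resolution and the
    probability map resized back to the original size before thresholding.
    Per-file failures are reported and the batch continues.
    Returns (written mask paths, list of (path, error) failures).
    """
    from PIL import Image
    from skimage.transform import resize as sk_resize

    model, _ = load_checkpoint(checkpoint_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    H, W = model.cfg.input_size
    written, failures = [], []
    for path in map(Path, image_paths):
        try:
            img = np.asarray(Image.open(path))
            if img.ndim == 2:
                img = np.repeat(img[:, :, None], 3, axis=2)
            orig_h, orig_w = img.shape[:2]
            x = (img[:, :, :3].astype(np.float32) / 255.0).transpose(2, 0, 1)
            pair = SamplePair(image=x, mask=np.zeros((orig_h, orig_w), bool),
                              id=path.stem)
            x512 = resize_normalize(pair, (H, W)).image
            prob = model.predict_proba(x512[None])[0, 0]
            prob_full = sk_resize(prob, (orig_h, orig_w), order=1,
                                  mode="edge", anti_aliasing=False,
                                  preserve_range=True)
            mask = (prob_full >= model.cfg.threshold).astype(np.uint8) * 255
            mask_path = out_dir / f"{path.stem}_mask.png"
            Image.fromarray(mask).save(mask_path)
            if write_prob:
                Image.fromarray(np.round(prob_full * 255).astype(np.uint8)
                                ).save(out_dir / f"{path.stem}_prob.png")
            written.append(mask_path)
        except Exception as exc:  # noqa: BLE001 - per-file isolation is the contract
            failures.append((path, f"{type(exc).__name__}: {exc}"))
    return written, failures
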