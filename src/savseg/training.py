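"""Training loop, early stopping, and smoothed-curve model selection.

Adam (alpha 1e-4, beta1 0.9, beta2 0.999 by default) minimises the weighted
categorical cross-entropy; training runs for at most 300 epochs and stops
after 40 consecutive epochs without improvement of validation mIoU.  Model
parameters are snapshotted at the end of every epoch.  The best epoch is
chosen by smoothing the validation-mIoU curve with a local quadratic
(LOESS-style) regression and taking its maximum, which suppresses
small-scale epoch-to-epoch fluctuations.

Validation mIoU is computed over whole validation scenes with the base tile
grid only (zero offset) for speed; test-time inference uses the full 16-layer
offset vote.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .augment import AugmentParams, augment_pair
from .evaluation import miou
from .inference import predict_scene
from .models import image_to_input
from .nn.autodiff import Tensor, weighted_softmax_cross_entropy
from .nn.layers import Adam
from .weights import ClassWeightTable

__all__ = ["TrainConfig", "TrainingLog", "train", "select_best_epoch",
           "loess_smooth", "auto_batch_size"]


def auto_batch_size(tile_size: int, batch_at_1024: int = 4) -> int:
    """Batch size scaling inversely with tile area from a reference at 1024 px."""
    return max(1, int(round(batch_at_1024 * (1024 / tile_size) ** 2)))


@dataclass
class TrainConfig:
    tile_size: int = 512
    batch_size: int | None = None        # None -> inverse-area auto rule
    max_epochs: int = 300
    patience: int = 40                   # epochs without validation improvement
    learning_rate: float = 1e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    weight_exponent: float = 0.1
    seed: int = 0
    augment: AugmentParams | None = None
    loss_eps: float = 1e-7

    def __post_init__(self):
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.batch_size is None:
            self.batch_size = auto_batch_size(self.tile_size)


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_miou: float
    checkpoint: object  # state dict or path


@dataclass
class TrainingLog:
    records: list = field(default_factory=list)

    @property
    def epochs(self):
        return np.array([r.epoch for r in self.records])

    @property
    def val_mious(self):
        return np.array([r.val_miou for r in self.records])

    def checkpoint_for(self, epoch: int):
        for r in self.records:
            if r.epoch == epoch:
                return r.checkpoint
        raise KeyError(f"no checkpoint for epoch {epoch}")

    def save_csv(self, path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        lines = ["epoch,train_loss,val_miou"]
        lines += [f"{r.epoch},{r.train_loss:.8f},{r.val_miou:.8f}" for r in self.records]
        path.write_text("\n".join(lines) + "\n")


def train(model, train_tiles, val_scenes, weights: ClassWeightTable,
          config: TrainConfig, run_dir=None, verbose: bool = False) -> TrainingLog:
    """Train ``model`` on tiles, validating per epoch on whole scenes.

    Stops at min(max_epochs, first epoch at which ``patience`` epochs have
    passed without a new best validation mIoU).  One checkpoint per epoch:
    in-memory state dicts, or .npz files under ``run_dir`` if given.
    """
    train_tiles = list(train_tiles)
    if not train_tiles:
        raise ValueError("empty training set")
    if not val_scenes:
        raise ValueError("validation set must be non-empty")
    rng = np.random.default_rng(config.seed)
    optimiser = Adam(model.parameters(), lr=config.learning_rate,
                     beta1=config.adam_beta1, beta2=config.adam_beta2)
    n_classes = model.config.n_classes
    log = TrainingLog()
    best = -np.inf
    stale = 0
    if run_dir is not None:
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_tiles))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [train_tiles[i] for i in order[start:start + config.batch_size]]
            images, masks = [], []
            for tile in batch:
                img, msk = tile.image, tile.mask
                if config.augment is not None:
                    img, msk = augment_pair(img, msk, config.augment, rng)
                images.append(image_to_input(img))
                masks.append(np.asarray(msk))
            x = Tensor(np.stack(images))
            labels = np.stack(masks)
            optimiser.zero_grad()
            loss = weighted_softmax_cross_entropy(model(x), labels, weights.w,
                                                  eps=config.loss_eps)
            loss.backward()
            optimiser.step()
            losses.append(loss.data.item())
        val = float(np.mean([
            miou(scene.mask, predict_scene(model, scene, config.tile_size,
                                           fractions=(0.0,)), n_classes)
            for scene in val_scenes]))
        if run_dir is not None:
            ckpt = run_dir / f"epoch_{epoch:04d}.npz"
            np.savez(ckpt, **model.state_dict())
        else:
            ckpt = model.state_dict()
        log.records.append(EpochRecord(epoch, float(np.mean(losses)), val, ckpt))
        if verbose:
            print(f"epoch {epoch:3d}  loss {np.mean(losses):.4f}  val mIoU {val:.4f}")
        if val > best:
            best, stale = val, 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if run_dir is not None:
        manifest = [{"epoch": r.epoch, "val_miou": r.val_miou,
                     "checkpoint": str(r.checkpoint)} for r in log.records]
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return log


def loess_smooth(x, y, span: float = 0.3):
    """Tricube-weighted local quadratic regression evaluated at each x."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = x.size
    k = min(int(np.ceil(span * n)), n)
    if k < 3:
        raise ValueError(f"span {span} leaves fewer than 3 points per local "
                         "quadratic fit; increase the span")
    smoothed = np.empty(n)
    for i in range(n):
        dist = np.abs(x - x[i])
        idx = np.argsort(dist, kind="stable")[:k]
        dmax = dist[idx].max()
        if dmax == 0:
            smoothed[i] = y[idx].mean()
            continue
        wts = (1.0 - (dist[idx] / dmax) ** 3) ** 3
        wts = np.clip(wts, 1e-12, None)
        # weighted quadratic fit centred at x[i]
        t = x[idx] - x[i]
        design = np.stack([np.ones_like(t), t, t * t], axis=1)
        sw = np.sqrt(wts)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y[idx] * sw, rcond=None)
        smoothed[i] = coef[0]
    return smoothed


def select_best_epoch(log: TrainingLog, smoothing_span: float = 0.3) -> int:
    """Epoch at which the LOESS-smoothed validation-mIoU curve peaks.

    Ties are broken towards the earliest epoch.  Requires >= 3 logged epochs.
    """
    epochs = log.epochs
    if epochs.size < 3:
        raise ValueError("need at least 3 logged epochs to smooth the curve")
    smoothed = loess_smooth(epochs, log.val_mious, span=smoothing_span)
    best = int(np.argmax(np.round(smoothed, 12)))  # first index wins ties
    return int(epochs[best])
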