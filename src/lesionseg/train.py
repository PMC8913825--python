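"""ADAM training with a cosine-annealing warm-restart (SGDR) schedule.

The learning rate starts at 1e-2 and cosine-decays to 1e-4 within each
cycle.  The first cycle lasts 5 epochs and each restart stretches the
cycle by a factor of 1.5 (rounded half-up); the restart peak shrinks by
10% per cycle.  The cumulative budget is capped at 300 epochs, with early
stopping on the validation loss.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import augment as aug
from . import evaluate
from .fixtures import LesionSample
from .losses import LossConfig, get_loss
from .models import SegmentationModel
from .nn import Adam
from .nn.tensor import Tensor

__all__ = ["SgdrSchedule", "TrainConfig", "TrainingDiverged",
           "lr_at", "cycle_boundaries", "train"]


class TrainingDiverged(RuntimeError):
    pass


@dataclass(frozen=True)
class SgdrSchedule:
    lr_max_initial: float = 1e-2
    lr_min: float = 1e-4
    cycle0_epochs: int = 5
    cycle_growth: float = 1.5
    max_decay_per_cycle: float = 0.9  # "10% reduction" of the restart peak
    epoch_cap: int = 300

    def validate(self) -> None:
        if not (0 < self.lr_min < self.lr_max_initial):
            raise ValueError("need 0 < lr_min < lr_max_initial")
        if self.cycle_growth < 1:
            raise ValueError("cycle_growth must be >= 1")
        if not (0 < self.max_decay_per_cycle <= 1):
            raise ValueError("max_decay_per_cycle must be in (0, 1]")
        if self.cycle0_epochs < 1 or self.epoch_cap < 1:
            raise ValueError("epoch counts must be >= 1")


def cycle_boundaries(schedule: SgdrSchedule) -> list[int]:
    """Cycle lengths in epochs: T0 = 5, T_{k+1} = round-half-up(1.5 T_k),
    truncated so the cumulative sum equals the epoch cap exactly."""
    schedule.validate()
    lengths, total = [], 0
    t = int(schedule.cycle0_epochs)
    while total < schedule.epoch_cap:
        tk = min(t, schedule.epoch_cap - total)
        lengths.append(tk)
        total += tk
        t = int(np.floor(t * schedule.cycle_growth + 0.5))  # round half-up
    return lengths


def _locate(schedule: SgdrSchedule, epoch: float) -> tuple[int, float, int]:
    """(cycle index, local time, cycle length) for a fractional epoch."""
    if epoch < 0 or epoch >= schedule.epoch_cap:
        raise ValueError(f"epoch {epoch} outside [0, {schedule.epoch_cap})")
    start = 0
    for k, tk in enumerate(cycle_boundaries(schedule)):
        if epoch < start + tk:
            return k, epoch - start, tk
        start += tk
    raise AssertionError("unreachable: boundaries cover the cap")


def lr_at(schedule: SgdrSchedule, epoch: float) -> float:
    """Cosine-annealed learning rate with decaying warm restarts."""
    k, t, tk = _locate(schedule, epoch)
    lr_max_k = schedule.lr_max_initial * schedule.max_decay_per_cycle ** k
    return schedule.lr_min + (lr_max_k - schedule.lr_min) / 2.0 * (
        1.0 + np.cos(np.pi * t / tk))


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    epochs: int = 300
    loss: LossConfig = field(default_factory=LossConfig)
    augment: aug.AugmentationSpec = field(
        default_factory=lambda: aug.AugmentationSpec(preset="none"))
    early_stop_patience: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _to_arrays(samples: list[LesionSample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.image for s in samples]).astype(np.float32) / 255.0
    y = np.stack([s.mask for s in samples]).astype(np.float32)
    return x.transpose(0, 3, 1, 2), y[:, None]


def _validate_model(model: SegmentationModel, xv, yv, loss_fn,
                    batch_size: int) -> tuple[float, float]:
    """(val loss, mean per-image JAC) in inference mode."""
    model.net.eval()
    losses, jacs = [], []
    for i in range(0, len(xv), batch_size):
        xb, yb = xv[i:i + batch_size], yv[i:i + batch_size]
        probs = model.net(Tensor(xb)).data
        losses.append(float(loss_fn(yb, probs.astype(np.float32))) * len(xb))
        for j in range(len(xb)):
            pred = (probs[j, 0] >= 0.5).astype(np.uint8)
            jacs.append(evaluate.evaluate_pair(pred, yb[j, 0].astype(np.uint8)).jaccard)
    model.net.train()
    return sum(losses) / len(xv), float(np.mean(jacs))


@dataclass
class TrainResult:
    model: SegmentationModel
    history: pd.DataFrame
    best_epoch: int
    best_val_jaccard: float
    stopped_early: bool


def train(model: SegmentationModel, train_set: list[LesionSample],
          val_set: list[LesionSample], config: TrainConfig,
          schedule: SgdrSchedule | None = None) -> TrainResult:
    """Train under SGDR; retain the best-validation-JAC weights.

    Fully reproducible on one device for a fixed seed: data order, the
    augmentation stream and initialization are all seeded.
    """
    config.validate()
    schedule = schedule or SgdrSchedule()
    schedule.validate()
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be nonempty")

    rng = np.random.default_rng(config.seed)
    loss_fn = get_loss(config.loss)
    pipeline = aug.build_pipeline(config.augment)
    xv, yv = _to_arrays(val_set)
    opt = Adam(model.net.parameters(), lr=schedule.lr_max_initial)

    n_epochs = min(config.epochs, schedule.epoch_cap)
    rows = []
    best_jac, best_epoch, best_state = -1.0, -1, None
    best_val_loss, since_improve = np.inf, 0
    stopped = False

    model.net.train()
    for epoch in range(n_epochs):
        lr = lr_at(schedule, epoch)
        opt.lr = lr
        order = rng.permutation(len(train_set))
        epoch_losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            batch = [train_set[j] for j in idx]
            if pipeline.transforms:
                batch = [pipeline.apply(s, int(rng.integers(2 ** 31)))
                         for s in batch]
            xb, yb = _to_arrays(batch)
            probs = model.net(Tensor(xb))
            loss = loss_fn(Tensor(yb), probs)
            if not np.isfinite(float(loss.data)):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}: {float(loss.data)}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data) * len(idx))
        train_loss = sum(epoch_losses) / len(order)
        val_loss, val_jac = _validate_model(model, xv, yv, loss_fn,
                                            config.batch_size)
        rows.append({"epoch": epoch, "lr": lr, "train_loss": train_loss,
                     "val_loss": val_loss, "val_jaccard": val_jac})

        if val_jac > best_jac:
            best_jac, best_epoch = val_jac, epoch
            best_state = [a.copy() for a in model.net.state_arrays()]
        if val_loss < best_val_loss - 1e-6:
            best_val_loss, since_improve = val_loss, 0
        else:
            since_improve += 1
            if since_improve >= config.early_stop_patience:
                stopped = True
                break

    if best_state is not None:
        model.net.load_state_arrays(best_state)
    model.net.eval()
    return TrainResult(model=model, history=pd.DataFrame(rows),
                       best_epoch=best_epoch, best_val_jaccard=best_jac,
                       stopped_early=stopped)
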