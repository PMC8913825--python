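"""Segmentation loss functions.

Six losses over an actual binary mask ``X`` and a predicted probability map
``Y``: binary cross-entropy, dice loss, their 0.2/0.8 weighted combination,
focal loss, Tversky loss (beta = 1/2 by default) and focal Tversky loss.

Two historical formula variants are kept selectable where the literature
disagrees with itself:

* ``dice_form``: ``canonical_2x`` uses (2·ΣXY + s)/(ΣX + ΣY + s) so a
  perfect prediction scores a loss of exactly 0; ``as_printed`` drops the
  factor 2 (a variant that appears in print but is inconsistent with the
  Dice coefficient DC = 2TP/(2TP+FP+FN) it is meant to mirror).
* ``focal_form``: ``as_printed`` scales the cross-entropy by γ(1−p);
  ``canonical`` exponentiates, (1−p)^γ.
* ``focal_tversky`` as printed carries no focal exponent and coincides
  with the Tversky loss; the optional exponent mode (1 − TI)^(1/γ) is off
  by default.

All functions accept NumPy arrays (returning a float) or autodiff tensors
(returning a tensor, for training).  Inputs of more than two dimensions are
treated as batched with axis 0 the batch axis; overlap losses are computed
per sample and averaged, pixel losses are averaged over everything.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import tensor as F
from .nn.tensor import Tensor

__all__ = ["LossConfig", "bce_loss", "dice_loss", "bce_dice_loss",
           "bce_dice_combine", "focal_loss", "tversky_loss",
           "focal_tversky_loss", "get_loss"]

_EPS = 1e-7


@dataclass(frozen=True)
class LossConfig:
    name: str = "dice"            # bce|dice|bce_dice|focal|tversky|focal_tversky
    gamma: float = 0.75           # focal modulating factor (stated range 0-1)
    beta: float = 0.5             # Tversky FP/FN balance
    w_bce: float = 0.2
    w_dice: float = 0.8
    smooth: float = 1.0
    dice_form: str = "canonical_2x"   # canonical_2x | as_printed
    focal_form: str = "as_printed"    # as_printed | canonical
    ftl_exponent: bool = False

    def validate(self) -> None:
        if self.name not in ("bce", "dice", "bce_dice", "focal",
                             "tversky", "focal_tversky"):
            raise ValueError(f"unknown loss {self.name!r}")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must be in [0, 1]")
        if abs(self.w_bce + self.w_dice - 1.0) > 1e-9:
            raise ValueError("w_bce + w_dice must equal 1")
        if self.smooth <= 0:
            raise ValueError("smooth must be > 0")
        if self.dice_form not in ("canonical_2x", "as_printed"):
            raise ValueError(f"unknown dice_form {self.dice_form!r}")
        if self.focal_form not in ("as_printed", "canonical"):
            raise ValueError(f"unknown focal_form {self.focal_form!r}")


def _prepare(X, Y):
    """Wrap inputs; returns (X, Y, was_array, reduce_axes_for_overlap)."""
    was_array = not isinstance(Y, Tensor)
    xt = X if isinstance(X, Tensor) else Tensor(np.asarray(X, dtype=np.float32))
    yt = Y if isinstance(Y, Tensor) else Tensor(np.asarray(Y, dtype=np.float32))
    if xt.data.shape != yt.data.shape:
        raise ValueError(f"shape mismatch: {xt.data.shape} vs {yt.data.shape}")
    if yt.ndim > 2:
        axes = tuple(range(1, yt.ndim))  # per-sample reduction
    else:
        axes = None
    return xt, yt, was_array, axes


def _finish(t: Tensor, was_array: bool):
    return float(t.data) if was_array else t


def bce_loss(X, Y):
    """Mean per-pixel binary cross-entropy; Y clamped away from {0,1}."""
    xt, yt, arr, _ = _prepare(X, Y)
    yc = F.clip(yt, _EPS, 1.0 - _EPS)
    per = -(xt * F.log(yc) + (1.0 - xt) * F.log(1.0 - yc))
    return _finish(per.mean(), arr)


def dice_loss(X, Y, config: LossConfig | None = None):
    config = config or LossConfig()
    xt, yt, arr, axes = _prepare(X, Y)
    s = config.smooth
    inter = (xt * yt).sum(axis=axes) if axes else (xt * yt).sum()
    tot = (xt + yt).sum(axis=axes) if axes else (xt + yt).sum()
    if config.dice_form == "canonical_2x":
        per = 1.0 - (2.0 * inter + s) / (tot + s)
    else:  # as_printed: no 2x in the numerator
        per = 1.0 - (inter + s) / (tot + s)
    return _finish(per.mean(), arr)


def bce_dice_combine(bce_value, dice_value, config: LossConfig | None = None):
    """The weighted combiner on precomputed component values (0.2/0.8)."""
    config = config or LossConfig()
    return config.w_bce * bce_value + config.w_dice * dice_value


def bce_dice_loss(X, Y, config: LossConfig | None = None):
    config = config or LossConfig()
    xt, yt, arr, _ = _prepare(X, Y)
    out = bce_dice_combine(bce_loss(xt, yt), dice_loss(xt, yt, config), config)
    return _finish(out, arr)


def focal_loss(X, Y, config: LossConfig | None = None):
    """Focal loss on the true-class probability p = X·Y + (1−X)(1−Y)."""
    config = config or LossConfig()
    xt, yt, arr, _ = _prepare(X, Y)
    yc = F.clip(yt, _EPS, 1.0 - _EPS)
    p = xt * yc + (1.0 - xt) * (1.0 - yc)
    if config.focal_form == "as_printed":
        per = -config.gamma * (1.0 - p) * F.log(p)
    else:
        per = -((1.0 - p) ** config.gamma) * F.log(p)
    return _finish(per.mean(), arr)


def _tversky_index(xt, yt, beta, s, axes):
    inter = (xt * yt).sum(axis=axes) if axes else (xt * yt).sum()
    fp = ((1.0 - xt) * yt).sum(axis=axes) if axes else ((1.0 - xt) * yt).sum()
    fn = (xt * (1.0 - yt)).sum(axis=axes) if axes else (xt * (1.0 - yt)).sum()
    return (inter + s) / (inter + beta * fp + (1.0 - beta) * fn + s)


def tversky_loss(X, Y, config: LossConfig | None = None):
    config = config or LossConfig()
    xt, yt, arr, axes = _prepare(X, Y)
    per = 1.0 - _tversky_index(xt, yt, config.beta, config.smooth, axes)
    return _finish(per.mean(), arr)


def focal_tversky_loss(X, Y, config: LossConfig | None = None):
    config = config or LossConfig()
    xt, yt, arr, axes = _prepare(X, Y)
    ti = _tversky_index(xt, yt, config.beta, config.smooth, axes)
    if config.ftl_exponent and config.gamma > 0:
        per = (1.0 - ti) ** (1.0 / config.gamma)
    else:
        per = 1.0 - ti
    return _finish(per.mean(), arr)


_LOSSES = {
    "bce": lambda X, Y, c: bce_loss(X, Y),
    "dice": dice_loss,
    "bce_dice": bce_dice_loss,
    "focal": focal_loss,
    "tversky": tversky_loss,
    "focal_tversky": focal_tversky_loss,
}


def get_loss(config: LossConfig):
    """Callable (X, Y) -> scalar for the configured loss."""
    config.validate()
    fn = _LOSSES[config.name]
    if config.name == "bce":
        return lambda X, Y: bce_loss(X, Y)
    return lambda X, Y: fn(X, Y, config)
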