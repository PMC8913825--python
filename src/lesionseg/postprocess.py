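"""Prediction-time refinement: TTA averaging and dense-CRF relaxation.

Test-time augmentation runs the model on invertible geometric transforms
of the input and averages the back-transformed probability maps.  The CRF
is a fully connected two-label model with a unary term -log p and Gaussian
spatial plus bilateral appearance pairwise kernels, relaxed by mean-field
iteration; the bilateral message passing uses a bilateral-grid
approximation (splat / Gaussian blur / slice in the joint position–color
space).  The intended pipeline order is TTA first, CRF on the averaged map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .models import SegmentationModel

__all__ = ["TtaSpec", "CrfParams", "tta_predict", "crf_refine",
           "threshold_mask", "TTA_TRANSFORMS"]


# name -> (forward on HxW[xC], inverse on HxW[xC])
TTA_TRANSFORMS = {
    "identity": (lambda a: a, lambda a: a),
    "horizontal_flip": (lambda a: a[:, ::-1], lambda a: a[:, ::-1]),
    "vertical_flip": (lambda a: a[::-1], lambda a: a[::-1]),
    "rotate90": (lambda a: np.rot90(a, 1), lambda a: np.rot90(a, -1)),
    "rotate180": (lambda a: np.rot90(a, 2), lambda a: np.rot90(a, -2)),
    "rotate270": (lambda a: np.rot90(a, 3), lambda a: np.rot90(a, -3)),
}
_SQUARE_ONLY = {"rotate90", "rotate270"}


@dataclass(frozen=True)
class TtaSpec:
    """Invertible transform set; identity is always a member."""

    transforms: tuple[str, ...] = ("identity", "horizontal_flip",
                                   "vertical_flip", "rotate180")
    add_square_rotations: bool = True

    def validate(self) -> None:
        if "identity" not in self.transforms:
            raise ValueError("the identity transform must be included")
        unknown = set(self.transforms) - set(TTA_TRANSFORMS)
        if unknown:
            raise ValueError(f"non-invertible/unknown transforms: {unknown}")

    def resolved(self, h: int, w: int) -> list[str]:
        self.validate()
        names = list(self.transforms)
        if self.add_square_rotations and h == w:
            for extra in ("rotate90", "rotate270"):
                if extra not in names:
                    names.append(extra)
        if h != w:
            bad = [n for n in names if n in _SQUARE_ONLY]
            if bad:
                raise ValueError(
                    f"{bad} require a square image, got {h}x{w}")
        return names


def tta_predict(model: SegmentationModel, image: np.ndarray,
                spec: TtaSpec | None = None) -> np.ndarray:
    """Mean over transforms T of T^-1(model(T(image)))."""
    spec = spec or TtaSpec()
    h, w = image.shape[:2]
    names = spec.resolved(h, w)
    acc = np.zeros((h, w), dtype=np.float64)
    for name in names:
        fwd, inv = TTA_TRANSFORMS[name]
        prob = model.predict(np.ascontiguousarray(fwd(image)))
        acc += inv(prob)
    return (acc / len(names)).astype(np.float32)


@dataclass(frozen=True)
class CrfParams:
    n_iterations: int = 5
    w_spatial: float = 3.0
    sigma_spatial: float = 3.0
    w_bilateral: float = 5.0
    sigma_bilateral_space: float = 50.0
    sigma_bilateral_color: float = 13.0
    unary_clip: float = 1e-8

    def validate(self) -> None:
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if self.w_spatial < 0 or self.w_bilateral < 0:
            raise ValueError("pairwise weights must be >= 0")
        for s in (self.sigma_spatial, self.sigma_bilateral_space,
                  self.sigma_bilateral_color):
            if s <= 0:
                raise ValueError("sigmas must be > 0")
        if not (0 < self.unary_clip < 0.5):
            raise ValueError("unary_clip must be in (0, 0.5)")


def _bilateral_filter(q: np.ndarray, guide: np.ndarray,
                      sigma_space: float, sigma_color: float) -> np.ndarray:
    """Approximate Gaussian filtering in joint (x, y, r, g, b) space.

    Splat ``q`` (with homogeneous weights) into a coarse 5-D bilateral
    grid sampled at one cell per sigma, blur the grid with a unit-sigma
    Gaussian, and slice back with linear interpolation.
    """
    h, w = q.shape
    yy, xx = np.mgrid[0:h, 0:w]
    coords = [yy.ravel() / sigma_space, xx.ravel() / sigma_space]
    for c in range(3):
        coords.append(guide[..., c].ravel() / sigma_color)
    coords = np.stack(coords, axis=0)
    mins = coords.min(axis=1)
    idx = np.round(coords - mins[:, None]).astype(int)
    dims = idx.max(axis=1) + 3  # one-cell pad each side
    idx += 1

    flat = np.ravel_multi_index(idx, dims)
    num = np.bincount(flat, weights=q.ravel(), minlength=int(np.prod(dims))
                      ).reshape(dims)
    den = np.bincount(flat, minlength=int(np.prod(dims))).reshape(dims)
    num = ndimage.gaussian_filter(num, sigma=1.0, mode="constant")
    den = ndimage.gaussian_filter(den, sigma=1.0, mode="constant")

    sample = coords - mins[:, None] + 1.0
    fnum = ndimage.map_coordinates(num, sample, order=1, mode="nearest")
    fden = ndimage.map_coordinates(den, sample, order=1, mode="nearest")
    out = np.where(fden > 1e-12, fnum / np.maximum(fden, 1e-12), q.ravel())
    return out.reshape(h, w)


def crf_refine(image: np.ndarray, prob: np.ndarray,
               params: CrfParams | None = None) -> np.ndarray:
    """Mean-field relaxation of a two-label dense CRF.

    Unary = -log(clip(prob)); Potts pairwise with a Gaussian spatial kernel
    and a bilateral appearance kernel on the RGB guide image.  Returns the
    posterior lesion probability (the per-pixel pair sums to 1).
    """
    params = params or CrfParams()
    params.validate()
    prob = np.asarray(prob, dtype=np.float64)
    if image.shape[:2] != prob.shape:
        raise ValueError("image and probability map differ in spatial size")
    guide = image.astype(np.float64)
    if guide.ndim == 2:
        guide = np.stack([guide] * 3, axis=-1)

    p1 = np.clip(prob, params.unary_clip, 1.0 - params.unary_clip)
    unary = np.stack([-np.log(1.0 - p1), -np.log(p1)])  # [background, lesion]

    q = np.stack([1.0 - p1, p1])
    q /= q.sum(axis=0, keepdims=True)

    for _ in range(params.n_iterations):
        messages = np.zeros_like(q)
        for label in range(2):
            m = 0.0
            if params.w_spatial > 0:
                sp = ndimage.gaussian_filter(q[label], params.sigma_spatial,
                                             mode="constant")
                m = m + params.w_spatial * sp
            if params.w_bilateral > 0:
                bl = _bilateral_filter(q[label], guide,
                                       params.sigma_bilateral_space,
                                       params.sigma_bilateral_color)
                m = m + params.w_bilateral * bl
            messages[label] = m
        # Potts compatibility: a label is penalized by the other label's mass
        energy = unary.copy()
        energy[0] += messages[1]
        energy[1] += messages[0]
        energy -= energy.min(axis=0, keepdims=True)
        q = np.exp(-energy)
        q /= q.sum(axis=0, keepdims=True)

    return q[1].astype(np.float32)


def threshold_mask(prob: np.ndarray, t: float = 0.5) -> np.ndarray:
    """Binary mask: 1 where prob >= t."""
    if not (0.0 < t < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    return (np.asarray(prob) >= t).astype(np.uint8)
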