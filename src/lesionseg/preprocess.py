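"""Hair removal and resizing for dermoscopic images.

The hair-removal chain follows the classic morphological recipe: convert to
grayscale, apply a black top-hat filter (closing minus the image, which
responds to thin dark structures on a brighter background), threshold the
response into a binary hair mask, and inpaint the masked pixels from their
neighborhood.  Images are resized with nearest-neighbor interpolation so
masks stay strictly binary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .fixtures import LesionSample

__all__ = ["HairRemovalParams", "to_grayscale", "make_structuring_element",
           "black_tophat", "detect_hair_mask", "inpaint", "remove_hair",
           "resize_nn"]

# BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class HairRemovalParams:
    """Tunables of the hair-removal chain.

    ``se_size`` is the structuring-element width in pixels (odd, >= 3;
    default 9, wide enough to close 1–3 px hairs at 256x256).  ``threshold``
    is on the 0–255 top-hat response (default 10: a low bar — false
    positives are benign because inpainting is near-identity on smooth
    skin).  ``inpaint_method`` is ``nearest`` (fill each masked pixel from
    its nearest unmasked neighbor, then locally smooth) or ``biharmonic``.
    """

    se_shape: str = "rect"       # rect | disk | cross
    se_size: int = 9
    threshold: int = 10
    inpaint_radius: int = 3
    inpaint_method: str = "nearest"
    mask_dilation: int = 1

    def validate(self) -> None:
        if self.se_shape not in ("rect", "disk", "cross"):
            raise ValueError(f"unknown se_shape {self.se_shape!r}")
        if self.se_size < 3 or self.se_size % 2 == 0:
            raise ValueError(f"se_size must be odd and >= 3, got {self.se_size}")
        if not (0 < self.threshold < 255):
            raise ValueError(f"threshold must be in (0, 255), got {self.threshold}")
        if self.inpaint_radius < 1:
            raise ValueError("inpaint_radius must be >= 1")
        if self.inpaint_method not in ("nearest", "biharmonic"):
            raise ValueError(f"unknown inpaint_method {self.inpaint_method!r}")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """RGB -> 8-bit luma (BT.601 weights), rounded."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected HxWx3 input, got shape {image.shape}")
    g = image.astype(np.float64) @ _LUMA
    return np.clip(np.round(g), 0, 255).astype(np.uint8)


def make_structuring_element(shape: str, size: int) -> np.ndarray:
    if size < 3 or size % 2 == 0:
        raise ValueError("structuring element size must be odd and >= 3")
    if shape == "rect":
        return np.ones((size, size), dtype=bool)
    if shape == "disk":
        return disk(size // 2).astype(bool)
    if shape == "cross":
        se = np.zeros((size, size), dtype=bool)
        se[size // 2, :] = True
        se[:, size // 2] = True
        return se
    raise ValueError(f"unknown structuring element shape {shape!r}")


def black_tophat(x: np.ndarray, se: np.ndarray) -> np.ndarray:
    """closing(x) - x with reflect border handling, clipped at 0."""
    if se.shape[0] > x.shape[0] or se.shape[1] > x.shape[1]:
        raise ValueError("structuring element larger than image")
    closed = ndimage.grey_closing(x.astype(np.int16), footprint=se, mode="reflect")
    return np.clip(closed - x.astype(np.int16), 0, 255).astype(np.uint8)


def detect_hair_mask(x: np.ndarray, params: HairRemovalParams) -> np.ndarray:
    """Binary mask of thin dark structures: top-hat response > threshold."""
    params.validate()
    se = make_structuring_element(params.se_shape, params.se_size)
    bth = black_tophat(x, se)
    return (bth > params.threshold).astype(np.uint8)


def inpaint(image: np.ndarray, mask: np.ndarray,
            params: HairRemovalParams | None = None) -> np.ndarray:
    """Reconstruct masked pixels from their neighborhood.

    ``nearest``: each masked pixel takes the value of its nearest unmasked
    pixel (Euclidean distance transform), then the filled region is locally
    smoothed with a Gaussian of sigma ``inpaint_radius / 2`` to blend seams.
    ``biharmonic``: smooth PDE-based fill (skimage).
    Pixels outside the mask are returned unchanged.
    """
    params = params or HairRemovalParams()
    params.validate()
    mask = np.asarray(mask).astype(bool)
    if mask.shape != image.shape[:2]:
        raise ValueError("mask and image dimensions differ")
    if mask.all():
        raise ValueError("mask covers the whole image; nothing to propagate from")
    if not mask.any():
        return image.copy()

    if params.inpaint_method == "biharmonic":
        from skimage.restoration import inpaint_biharmonic
        out = inpaint_biharmonic(image, mask, channel_axis=-1 if image.ndim == 3 else None)
        return np.clip(np.round(out * 255 if out.max() <= 1.0 else out),
                       0, 255).astype(np.uint8)

    _, idx = ndimage.distance_transform_edt(mask, return_indices=True)
    filled = image[idx[0], idx[1]].astype(np.float64)
    sigma = params.inpaint_radius / 2.0
    if image.ndim == 3:
        sig = (sigma, sigma, 0)
    else:
        sig = sigma
    smooth = ndimage.gaussian_filter(filled, sigma=sig, mode="reflect")
    out = image.astype(np.float64).copy()
    out[mask] = smooth[mask]
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def remove_hair(image: np.ndarray,
                params: HairRemovalParams | None = None) -> np.ndarray:
    """Full chain: grayscale -> black top-hat -> threshold -> inpaint."""
    params = params or HairRemovalParams()
    params.validate()
    gray = to_grayscale(image)
    mask = detect_hair_mask(gray, params)
    if params.mask_dilation > 0 and mask.any():
        mask = ndimage.binary_dilation(
            mask, iterations=params.mask_dilation).astype(np.uint8)
    if not mask.any() or mask.all():
        return image.copy()
    return inpaint(image, mask, params)


def clean_sample(sample: LesionSample,
                 params: HairRemovalParams | None = None) -> LesionSample:
    """remove_hair on the image; the ground-truth mask is never touched."""
    return LesionSample(image=remove_hair(sample.image, params),
                        mask=sample.mask.copy(),
                        sample_id=sample.sample_id,
                        provenance=sample.provenance,
                        hair_mask=sample.hair_mask)


def _nn_resize_2d(a: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    h, w = a.shape[:2]
    h2, w2 = size
    rows = np.minimum(((np.arange(h2) + 0.5) * h / h2).astype(int), h - 1)
    cols = np.minimum(((np.arange(w2) + 0.5) * w / w2).astype(int), w - 1)
    return a[np.ix_(rows, cols)]


def resize_nn(sample: LesionSample, size: int | tuple[int, int]) -> LesionSample:
    """Nearest-neighbor resize of image and mask together (default 256x256
    in the pipeline); the mask stays strictly binary because nearest-neighbor
    never blends values."""
    if isinstance(size, int):
        size = (size, size)
    if min(size) < 8:
        raise ValueError("target size must be >= 8 pixels")
    out = LesionSample(
        image=_nn_resize_2d(sample.image, size),
        mask=_nn_resize_2d(sample.mask, size),
        sample_id=sample.sample_id,
        provenance=sample.provenance,
        hair_mask=(None if sample.hair_mask is None
                   else _nn_resize_2d(sample.hair_mask, size)),
    )
    out.validate()
    return out
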