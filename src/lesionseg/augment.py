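"""Train-time image augmentation.

Ten transform kinds, split into spatial transforms (applied identically to
image and mask) and pixel-level transforms (image only):

spatial:  random 90-degree rotation, vertical flip, horizontal flip
pixel:    HSV shift, RGB shift, random brightness, random contrast,
          grayscale, motion blur, random gamma

Three presets bundle them: ``geometric3`` (the spatial trio), ``combo7``
(spatial trio + HSV/RGB shift + brightness + contrast — the combination
that performs best in practice), and ``all10``.  Each transform fires
independently with probability ``p`` (default 0.5); pipelines are
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color

from .fixtures import LesionSample

__all__ = ["AugmentationSpec", "Pipeline", "build_pipeline", "apply",
           "PRESETS"]


@dataclass(frozen=True)
class AugmentationSpec:
    preset: str = "combo7"        # none | geometric3 | combo7 | all10
    p: float = 0.5                # per-transform application probability
    brightness_limit: float = 0.2
    contrast_limit: float = 0.2
    gamma_limit: tuple[int, int] = (80, 120)
    hsv_shift_limit: tuple[int, int, int] = (20, 30, 20)
    rgb_shift_limit: int = 20
    motion_blur_limit: tuple[int, int] = (3, 7)

    def validate(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; "
                             f"choose from {sorted(PRESETS)}")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must be in [0, 1]")


class Transform:
    """One augmentation kind.

    Parameter sampling is separated from application so the same sampled
    parameters can be replayed on image and mask (or on a mask alone),
    which is what makes geometric image/mask consistency testable.
    """

    name: str = ""
    kind: str = "pixel"  # "pixel" | "spatial"

    def sample_params(self, rng: np.random.Generator) -> dict:
        return {}

    def apply_image(self, img: np.ndarray, params: dict) -> np.ndarray:
        raise NotImplementedError

    def apply_mask(self, mask: np.ndarray, params: dict) -> np.ndarray:
        return mask  # pixel-level transforms leave geometry untouched


# -- spatial ---------------------------------------------------------------

class RandomRotate90(Transform):
    name, kind = "random_rotate90", "spatial"

    def sample_params(self, rng):
        return {"k": int(rng.integers(1, 4))}

    def apply_image(self, img, params):
        return np.ascontiguousarray(np.rot90(img, k=params["k"]))

    apply_mask = apply_image


class HorizontalFlip(Transform):
    name, kind = "horizontal_flip", "spatial"

    def apply_image(self, img, params):
        return np.ascontiguousarray(img[:, ::-1])

    apply_mask = apply_image


class VerticalFlip(Transform):
    name, kind = "vertical_flip", "spatial"

    def apply_image(self, img, params):
        return np.ascontiguousarray(img[::-1])

    apply_mask = apply_image


# -- pixel level -----------------------------------------------------------

def _to_uint8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


class RandomBrightness(Transform):
    name = "random_brightness"

    def __init__(self, limit=0.2):
        self.limit = limit

    def sample_params(self, rng):
        return {"factor": 1.0 + rng.uniform(-self.limit, self.limit)}

    def apply_image(self, img, params):
        return _to_uint8(img.astype(np.float64) * params["factor"])


class RandomContrast(Transform):
    name = "random_contrast"

    def __init__(self, limit=0.2):
        self.limit = limit

    def sample_params(self, rng):
        return {"factor": 1.0 + rng.uniform(-self.limit, self.limit)}

    def apply_image(self, img, params):
        f = img.astype(np.float64)
        mean = f.mean()
        return _to_uint8(mean + (f - mean) * params["factor"])


class RandomGamma(Transform):
    name = "random_gamma"

    def __init__(self, limit=(80, 120)):
        self.limit = limit

    def sample_params(self, rng):
        return {"gamma": rng.uniform(*self.limit) / 100.0}

    def apply_image(self, img, params):
        f = img.astype(np.float64) / 255.0
        return _to_uint8(255.0 * f ** params["gamma"])


class HueSaturationValue(Transform):
    name = "hue_saturation_value"

    def __init__(self, limit=(20, 30, 20)):
        self.limit = limit

    def sample_params(self, rng):
        h, s, v = self.limit
        return {"dh": rng.uniform(-h, h) / 360.0,
                "ds": rng.uniform(-s, s) / 255.0,
                "dv": rng.uniform(-v, v) / 255.0}

    def apply_image(self, img, params):
        hsv = color.rgb2hsv(img)
        hsv[..., 0] = (hsv[..., 0] + params["dh"]) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] + params["ds"], 0, 1)
        hsv[..., 2] = np.clip(hsv[..., 2] + params["dv"], 0, 1)
        return _to_uint8(color.hsv2rgb(hsv) * 255.0)


class RGBShift(Transform):
    name = "rgb_shift"

    def __init__(self, limit=20):
        self.limit = limit

    def sample_params(self, rng):
        return {"shift": rng.uniform(-self.limit, self.limit, size=3)}

    def apply_image(self, img, params):
        return _to_uint8(img.astype(np.float64) + params["shift"])


class ToGray(Transform):
    name = "grayscale"

    def apply_image(self, img, params):
        g = img.astype(np.float64) @ np.array([0.299, 0.587, 0.114])
        return _to_uint8(np.stack([g] * 3, axis=-1))


class MotionBlur(Transform):
    name = "motion_blur"

    def __init__(self, limit=(3, 7)):
        self.limit = limit

    def sample_params(self, rng):
        lo, hi = self.limit
        size = int(rng.integers(lo // 2, hi // 2 + 1)) * 2 + 1  # odd in [lo,hi]
        return {"size": size, "angle": rng.uniform(0, np.pi)}

    def apply_image(self, img, params):
        k = np.zeros((params["size"], params["size"]))
        c = params["size"] // 2
        t = np.linspace(-c, c, 4 * params["size"])
        ys = np.round(c + t * np.sin(params["angle"])).astype(int)
        xs = np.round(c + t * np.cos(params["angle"])).astype(int)
        k[ys, xs] = 1.0
        k /= k.sum()
        out = np.stack([ndimage.convolve(img[..., i].astype(np.float64), k,
                                         mode="reflect")
                        for i in range(img.shape[-1])], axis=-1)
        return _to_uint8(out)


# -- pipeline --------------------------------------------------------------

def _spatial_trio():
    return [RandomRotate90(), VerticalFlip(), HorizontalFlip()]


def _preset_transforms(spec: AugmentationSpec) -> list[Transform]:
    if spec.preset == "none":
        return []
    if spec.preset == "geometric3":
        return _spatial_trio()
    photometric4 = [HueSaturationValue(spec.hsv_shift_limit),
                    RGBShift(spec.rgb_shift_limit),
                    RandomBrightness(spec.brightness_limit),
                    RandomContrast(spec.contrast_limit)]
    if spec.preset == "combo7":
        return _spatial_trio() + photometric4
    if spec.preset == "all10":
        return (_spatial_trio() + photometric4
                + [ToGray(), MotionBlur(spec.motion_blur_limit),
                   RandomGamma(spec.gamma_limit)])
    raise ValueError(f"unknown preset {spec.preset!r}")


PRESETS = {"none": 0, "geometric3": 3, "combo7": 7, "all10": 10}


@dataclass
class Pipeline:
    transforms: list[Transform] = field(default_factory=list)
    p: float = 0.5

    def apply(self, sample: LesionSample, seed: int) -> LesionSample:
        rng = np.random.default_rng(seed)
        img, mask = sample.image, sample.mask
        for t in self.transforms:
            if rng.random() >= self.p:
                continue
            params = t.sample_params(rng)
            img = t.apply_image(img, params)
            mask = t.apply_mask(mask, params)
        return LesionSample(image=img, mask=mask,
                            sample_id=sample.sample_id,
                            provenance=sample.provenance)


def build_pipeline(spec: AugmentationSpec) -> Pipeline:
    """Assemble the transform pipeline for a preset."""
    spec.validate()
    return Pipeline(transforms=_preset_transforms(spec), p=spec.p)


def apply(pipeline: Pipeline, sample: LesionSample, seed: int) -> LesionSample:
    """Apply a pipeline deterministically under ``seed``."""
    return pipeline.apply(sample, seed)
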