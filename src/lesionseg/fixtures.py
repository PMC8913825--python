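"""Synthetic dermoscopy-like image generator with ground-truth masks.

Real dermoscopic archives (e.g. the ISIC collections) pair an RGB close-up
of a pigmented skin lesion with a binary expert-annotated mask; many images
carry dark body hairs crossing the lesion.  This module emulates those
characteristics so every downstream stage — hair removal, training,
postprocessing, evaluation — is exercisable without any download:

* skin-tone background with low-frequency mottle and fine grain noise,
* a darker, irregular elliptical lesion (radial Fourier perturbation of an
  ellipse, 3–6 harmonics) with a softened photographic boundary,
* optional dark curvilinear hair strokes composited over the image only,
* a crisp binary mask defined *before* boundary blurring, as an annotator
  would draw it.

Masks are {0,1} in memory and 0/255 single-channel PNG on disk.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = ["SynthSpec", "LesionSample", "generate_lesion_sample",
           "generate_dataset", "load_sample", "save_sample"]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic dermoscopy render.

    Intensities are on the 8-bit 0–255 scale.  ``lesion_area_fraction_range``
    bounds the realized lesion area as a fraction of the image area; the
    generator guarantees the realized fraction falls inside it.
    """

    image_size: tuple[int, int] = (256, 256)
    lesion_area_fraction_range: tuple[float, float] = (0.05, 0.30)
    lesion_contrast: float = 60.0
    boundary_softness: float = 2.0
    hair_count_range: tuple[int, int] = (0, 6)
    hair_thickness_px: int = 2
    hair_intensity: float = 40.0
    noise_sd: float = 3.0

    def validate(self) -> None:
        h, w = self.image_size
        if h < 8 or w < 8:
            raise ValueError(f"image_size too small: {self.image_size}")
        lo, hi = self.lesion_area_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(
                f"lesion_area_fraction_range must satisfy 0 < lo <= hi < 1, got {lo, hi}")
        for name in ("lesion_contrast", "hair_intensity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 255.0):
                raise ValueError(f"{name} must be in [0, 255], got {v}")
        if self.hair_count_range[0] < 0 or self.hair_count_range[0] > self.hair_count_range[1]:
            raise ValueError(f"bad hair_count_range {self.hair_count_range}")
        if self.hair_thickness_px < 1:
            raise ValueError("hair_thickness_px must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class LesionSample:
    """One image/mask pair flowing through the pipeline.

    ``hair_mask`` records the exact composited hair footprint for synthetic
    samples (None for external data); it is diagnostic only and never part
    of the ground truth.
    """

    image: np.ndarray              # H x W x 3 uint8
    mask: np.ndarray               # H x W uint8, values {0, 1}
    sample_id: str
    provenance: str = "synthetic"  # "synthetic" | "external"
    hair_mask: np.ndarray | None = field(default=None, repr=False)

    def validate(self) -> None:
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"image must be HxWx3, got {self.image.shape}")
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError("image and mask spatial dimensions differ")
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError(f"mask must contain only 0/1, got values {vals}")


def _lesion_mask(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Irregular elliptical support with an exact pixel-count area target."""
    h, w = spec.image_size
    total = h * w
    lo, hi = spec.lesion_area_fraction_range
    margin = 0.02 * (hi - lo)
    target_frac = rng.uniform(lo + margin, hi - margin)
    target_px = max(1, int(round(target_frac * total)))

    # base ellipse geometry
    aspect = rng.uniform(0.6, 1.0)
    angle = rng.uniform(0, np.pi)
    base_r = np.sqrt(target_frac * total / (np.pi * aspect))
    max_r = base_r * 1.5
    cy = rng.uniform(min(max_r, h / 2), max(h - max_r, h / 2))
    cx = rng.uniform(min(max_r, w / 2), max(w - max_r, w / 2))

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    v = (-sa * dx + ca * dy) / aspect
    r = np.hypot(u, v)
    theta = np.arctan2(v, u)

    # radial Fourier perturbation, 3-6 harmonics
    n_harm = rng.integers(3, 7)
    boundary = np.ones_like(theta)
    for k in rng.choice(np.arange(2, 9), size=n_harm, replace=False):
        amp = rng.uniform(0.02, 0.10) / np.sqrt(k)
        boundary += amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    ratio = r / (base_r * boundary)

    # threshold at the target_px-th smallest ratio -> exact area in pixels
    thresh = np.partition(ratio.ravel(), target_px - 1)[target_px - 1]
    return (ratio <= thresh).astype(np.uint8)


def _draw_hairs(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Footprint (H x W bool) of low-curvature dark strokes."""
    h, w = spec.image_size
    n_lo, n_hi = spec.hair_count_range
    n = int(rng.integers(n_lo, n_hi + 1))
    foot = np.zeros((h, w), dtype=bool)
    if n == 0:
        return foot
    rad = max(spec.hair_thickness_px // 2, 0)
    for _ in range(n):
        # quadratic Bezier spanning the frame with a gentle bow
        p0 = rng.uniform([0, 0], [h - 1, w - 1])
        ang = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(0.6, 1.3) * min(h, w)
        p2 = p0 + length * np.array([np.sin(ang), np.cos(ang)])
        mid = (p0 + p2) / 2
        normal = np.array([np.cos(ang), -np.sin(ang)])
        p1 = mid + rng.uniform(-0.25, 0.25) * length * normal
        t = np.linspace(0, 1, int(3 * length) + 2)[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2
        ys = np.round(pts[:, 0]).astype(int)
        xs = np.round(pts[:, 1]).astype(int)
        keep = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
        stroke = np.zeros_like(foot)
        stroke[ys[keep], xs[keep]] = True
        if rad > 0:
            from scipy.ndimage import binary_dilation
            stroke = binary_dilation(stroke, iterations=rad)
        foot |= stroke
    return foot


def generate_lesion_sample(spec: SynthSpec, seed: int) -> LesionSample:
    """Render one synthetic dermoscopy sample; bit-identical for equal seeds.

    The hair overlay draws from an RNG stream independent of the lesion and
    noise streams, so the same seed with ``hair_count_range=(0, 0)`` yields
    the pixel-identical hairless render of the same scene.
    """
    spec.validate()
    h, w = spec.image_size
    lesion_rng = np.random.default_rng([int(seed), 0])
    hair_rng = np.random.default_rng([int(seed), 1])

    mask = _lesion_mask(spec, lesion_rng)

    # skin background: warm tone + low-frequency mottle + fine grain
    base = np.array([205.0, 155.0, 135.0]) + lesion_rng.uniform(-12, 12, size=3)
    img = np.ones((h, w, 3), dtype=np.float64) * base
    mottle = gaussian_filter(lesion_rng.normal(0, 1, size=(h, w)), sigma=max(h, w) / 16)
    mstd = mottle.std()
    if mstd > 0:
        img += (mottle / mstd * 8.0)[:, :, None]

    # lesion: darker brownish region, photographic soft boundary
    lesion_color = base - spec.lesion_contrast * np.array([1.0, 1.15, 1.25])
    alpha = gaussian_filter(mask.astype(np.float64), sigma=spec.boundary_softness)
    img = img * (1 - alpha[:, :, None]) + lesion_color * alpha[:, :, None]

    if spec.noise_sd > 0:
        # sensor grain is spatially correlated in real captures
        # (demosaicing, compression); render it with a short-range blur
        grain = gaussian_filter(
            lesion_rng.normal(0, 1.0, size=(h, w, 3)), sigma=(0.8, 0.8, 0))
        img += grain * (spec.noise_sd / grain.std())

    # hair overlay: image only, mask untouched
    hair = _draw_hairs(spec, hair_rng)
    if hair.any():
        halo = gaussian_filter(hair.astype(np.float64), sigma=0.5)
        halo = np.clip(halo / halo.max(), 0, 1)
        img = img * (1 - halo[:, :, None]) + spec.hair_intensity * halo[:, :, None]

    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    sample = LesionSample(image=img, mask=mask,
                          sample_id=f"synth-{seed:08d}",
                          provenance="synthetic",
                          hair_mask=hair.astype(np.uint8))
    sample.validate()
    return sample


def hairless_render(spec: SynthSpec, seed: int) -> LesionSample:
    """The same scene as ``generate_lesion_sample`` but with no hair."""
    return generate_lesion_sample(replace(spec, hair_count_range=(0, 0)), seed)


# ---------------------------------------------------------------------------
# disk I/O

def save_sample(sample: LesionSample, image_path: Path, mask_path: Path) -> None:
    Image.fromarray(sample.image).save(image_path)
    Image.fromarray((sample.mask * 255).astype(np.uint8), mode="L").save(mask_path)


def load_sample(image_path: Path, mask_path: Path,
                sample_id: str | None = None,
                provenance: str = "external") -> LesionSample:
    img = np.asarray(Image.open(image_path).convert("RGB"))
    m = np.asarray(Image.open(mask_path).convert("L"))
    mask = (m >= 128).astype(np.uint8)
    sid = sample_id or Path(image_path).stem
    s = LesionSample(image=img, mask=mask, sample_id=sid, provenance=provenance)
    s.validate()
    return s


def _child_seed(seed: int, i: int) -> int:
    return int(np.random.SeedSequence([int(seed), int(i)]).generate_state(1)[0] % (2 ** 31))


def generate_dataset(n: int, spec: SynthSpec, seed: int, out_dir: Path) -> pd.DataFrame:
    """Write ``n`` image/mask PNG pairs plus a CSV manifest; reproducible."""
    if n < 1:
        raise ValueError("n must be >= 1")
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n):
        s = generate_lesion_sample(spec, _child_seed(seed, i))
        sid = f"{i:05d}"
        image_path = out_dir / f"{sid}_image.png"
        mask_path = out_dir / f"{sid}_mask.png"
        save_sample(s, image_path, mask_path)
        rows.append({
            "sample_id": sid,
            "image_path": image_path.name,
            "mask_path": mask_path.name,
            "lesion_px": int(s.mask.sum()),
            "hair_n": _hair_count(s),
        })
    manifest = pd.DataFrame(rows, columns=["sample_id", "image_path", "mask_path",
                                           "lesion_px", "hair_n"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def _hair_count(s: LesionSample) -> int:
    """Connected hair strokes in the diagnostic footprint."""
    if s.hair_mask is None or not s.hair_mask.any():
        return 0
    from scipy.ndimage import label
    _, n = label(s.hair_mask)
    return int(n)


def load_dataset(data_dir: Path) -> list[LesionSample]:
    """Read all samples referenced by ``manifest.csv`` in ``data_dir``."""
    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "manifest.csv")
    return [load_sample(data_dir / r.image_path, data_dir / r.mask_path,
                        sample_id=str(r.sample_id), provenance="synthetic")
            for r in manifest.itertuples()]


def file_checksum(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
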