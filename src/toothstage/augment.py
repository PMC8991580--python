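"""Label-preserving data augmentation for staged tooth crops.

Expands a labeled set by an integer factor (default 10, matching the
reference 240 -> 2400 expansion) using the stated transform families:
geometric zoom ("resize"), intensity rescaling, rotation, horizontal flip,
crop-and-resize, Gaussian filtering and brightness shifts. Magnitudes are
kept small enough that no transform can move an image across a stage
boundary (the stage is a shape property, and shapes are perturbed by at
most a few percent / a few degrees).

Every variant is drawn from a generator seeded by (plan seed, item id), so
augmentation is reproducible item-by-item and independent of list order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import transform as sk_transform

from toothstage.classifier import STAGES
from toothstage.image import as_gray

ALL_TRANSFORMS = ("resize", "rescale", "rotate", "flip", "crop", "filter", "brightness")


@dataclass(frozen=True)
class LabeledImage:
    """A grayscale crop with its Demirjian stage and provenance."""

    image: np.ndarray
    stage: str
    sex: str = "unknown"
    ident: str = ""

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.sex not in ("F", "M", "unknown"):
            raise ValueError(f"sex must be F, M or unknown, got {self.sex!r}")


@dataclass(frozen=True)
class AugmentPlan:
    """Expansion factor, enabled transform families and their magnitudes."""

    factor: int = 10
    transforms: tuple[str, ...] = ALL_TRANSFORMS
    rotate_deg: float = 15.0        # rotation drawn from +-rotate_deg
    zoom_range: tuple[float, float] = (0.9, 1.1)
    crop_range: tuple[float, float] = (0.9, 1.0)   # kept fraction of the side
    brightness: float = 0.10        # additive shift drawn from +-brightness
    intensity_scale: tuple[float, float] = (0.9, 1.1)
    blur_sigma: tuple[float, float] = (0.0, 1.0)
    flip_p: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.factor < 1:
            raise ValueError(f"factor must be >= 1, got {self.factor}")
        unknown = set(self.transforms) - set(ALL_TRANSFORMS)
        if unknown:
            raise ValueError(f"unknown transforms {sorted(unknown)}; "
                             f"choose from {ALL_TRANSFORMS}")
        if self.factor > 1 and not self.transforms:
            raise ValueError("factor > 1 needs at least one enabled transform")


def _zoom(img: np.ndarray, scale: float) -> np.ndarray:
    """Zoom about the center, keeping the output side fixed (edge-padded)."""
    side = img.shape[0]
    new = max(8, int(round(side * scale)))
    scaled = sk_transform.resize(img, (new, new), order=1, anti_aliasing=scale < 1.0)
    if new == side:
        return scaled
    if new > side:
        off = (new - side) // 2
        return scaled[off:off + side, off:off + side]
    pad0 = (side - new) // 2
    pad1 = side - new - pad0
    return np.pad(scaled, ((pad0, pad1), (pad0, pad1)), mode="edge")


def _variant(img: np.ndarray, plan: AugmentPlan, rng: np.random.Generator) -> np.ndarray:
    out = img
    t = plan.transforms
    if "resize" in t:
        out = _zoom(out, rng.uniform(*plan.zoom_range))
    if "crop" in t:
        keep = rng.uniform(*plan.crop_range)
        side = out.shape[0]
        k = max(8, int(round(side * keep)))
        r0 = rng.integers(0, side - k + 1)
        c0 = rng.integers(0, side - k + 1)
        out = sk_transform.resize(out[r0:r0 + k, c0:c0 + k], (side, side), order=1)
    if "rotate" in t:
        out = sk_transform.rotate(out, rng.uniform(-plan.rotate_deg, plan.rotate_deg),
                                  mode="edge", order=1)
    if "flip" in t and rng.random() < plan.flip_p:
        out = out[:, ::-1]
    if "filter" in t:
        sigma = rng.uniform(*plan.blur_sigma)
        if sigma > 1e-3:
            out = ndimage.gaussian_filter(out, sigma, mode="nearest")
    if "rescale" in t:
        out = out * rng.uniform(*plan.intensity_scale)
    if "brightness" in t:
        out = out + rng.uniform(-plan.brightness, plan.brightness)
    return np.clip(out, 0.0, 1.0)


def _item_rng(plan: AugmentPlan, item: LabeledImage) -> np.random.Generator:
    tag = zlib.crc32(f"{item.ident}|{item.stage}|{item.sex}".encode())
    return np.random.default_rng([plan.seed, tag])


def augment_image(item: LabeledImage, plan: AugmentPlan) -> list[LabeledImage]:
    """Exactly ``plan.factor`` variants; the original is variant 1.

    All variants keep the source stage, sex and a derived provenance id.
    """
    img = as_gray(item.image)
    rng = _item_rng(plan, item)
    out = [replace(item, image=img)]
    for k in range(1, plan.factor):
        out.append(replace(item, image=_variant(img, plan, rng),
                           ident=f"{item.ident}#aug{k}"))
    return out


def expand_dataset(items: list[LabeledImage], plan: AugmentPlan) -> list[LabeledImage]:
    """Apply :func:`augment_image` to every item: |out| = factor * |in|,
    and each (stage, sex) cell is multiplied by exactly the factor."""
    out: list[LabeledImage] = []
    for item in items:
        out.extend(augment_image(item, plan))
    return out
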