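"""ROI extraction and enhancement for cropped premolar radiographs.

The preprocessing chain is: crop a square box (default 250x250) around a
user-supplied seed point, stretch intensities between two percentiles,
then remove impulse noise with a 7x7 median filter. CLAHE is available as
an optional enhancement applied at segmentation time.

All border handling is by edge replication, which keeps medians well
defined and avoids introducing artificial dark frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure

from toothstage.image import as_gray


@dataclass(frozen=True)
class RoiBox:
    """Square region of interest: ``center`` (row, col) and ``side`` in pixels."""

    center: tuple[int, int]
    side: int = 250

    def __post_init__(self):
        if self.side <= 0:
            raise ValueError(f"box side must be positive, got {self.side}")


def crop_roi(image: np.ndarray, box: RoiBox) -> np.ndarray:
    """Crop a ``side x side`` window centered on ``box.center``.

    Pixels falling outside the source image are filled by replicating the
    nearest border pixel. The center must lie inside the image.
    """
    img = as_gray(image)
    r, c = box.center
    h, w = img.shape
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(
            f"box center ({r}, {c}) lies outside the {h}x{w} image"
        )
    half = box.side // 2
    r0, c0 = r - half, c - half
    rows = np.clip(np.arange(r0, r0 + box.side), 0, h - 1)
    cols = np.clip(np.arange(c0, c0 + box.side), 0, w - 1)
    return img[np.ix_(rows, cols)]


def adjust_intensity(image: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0) -> np.ndarray:
    """Percentile-linear contrast stretch, clipped to [0, 1].

    Maps the ``low_pct`` percentile to 0 and the ``high_pct`` percentile to 1.
    A constant image (degenerate percentile span) is returned unchanged.
    """
    img = as_gray(image)
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError(f"need 0 <= low < high <= 100, got ({low_pct}, {high_pct})")
    lo, hi = np.percentile(img, [low_pct, high_pct])
    if hi - lo <= 0:
        return img.copy()
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def median_filter(image: np.ndarray, kernel: int = 7) -> np.ndarray:
    """Square median filter with edge-replicated borders (default 7x7).

    Removes impulse noise while preserving edges; every output value is a
    member of some input window, so the [0, 1] range is preserved.
    """
    img = as_gray(image)
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError(f"kernel must be odd and >= 3, got {kernel}")
    return ndimage.median_filter(img, size=kernel, mode="nearest")


def clahe(image: np.ndarray, clip_limit: float = 0.01, tile_grid: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    ``tile_grid`` is the (rows, cols) tiling of the image; ``clip_limit`` is
    the normalized histogram clip fraction. A constant image comes back
    constant.
    """
    img = as_gray(image)
    if clip_limit <= 0:
        raise ValueError(f"clip_limit must be positive, got {clip_limit}")
    tr, tc = tile_grid
    if tr < 1 or tc < 1:
        raise ValueError(f"tile grid must be at least 1x1, got {tile_grid}")
    if tr > img.shape[0] or tc > img.shape[1]:
        raise ValueError(f"tile grid {tile_grid} exceeds image shape {img.shape}")
    if img.max() == img.min():
        return img.copy()
    kernel_size = (max(1, img.shape[0] // tr), max(1, img.shape[1] // tc))
    out = exposure.equalize_adapthist(img, kernel_size=kernel_size, clip_limit=clip_limit)
    return np.clip(out, 0.0, 1.0)


def preprocess_roi(
    image: np.ndarray,
    center: tuple[int, int],
    side: int = 250,
    low_pct: float = 1.0,
    high_pct: float = 99.0,
    kernel: int = 7,
    use_clahe: bool = False,
) -> np.ndarray:
    """Full preprocessing chain: crop, stretch, median-filter, optional CLAHE."""
    roi = crop_roi(image, RoiBox(center=center, side=side))
    roi = adjust_intensity(roi, low_pct, high_pct)
    roi = median_filter(roi, kernel)
    if use_clahe:
        roi = clahe(roi)
    return roi
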