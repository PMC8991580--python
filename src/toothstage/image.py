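"""Grayscale image carrier: plain 2-D float arrays with intensities in [0, 1].

Coordinate convention used everywhere in the package: (row, col), 0-based,
pixel centers at integer coordinates. Row increases downward, col to the
right; angle 0 points along +col and angles increase toward +row.
"""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio


def as_gray(pixels: np.ndarray) -> np.ndarray:
    """Validate and return a float64 grayscale image in [0, 1].

    Raises ``ValueError`` on wrong dimensionality or out-of-range values.
    """
    arr = np.asarray(pixels, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got ndim={arr.ndim}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"image must be at least 1x1, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError("image contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError(
            f"intensities must lie in [0, 1], got range [{arr.min():.4g}, {arr.max():.4g}]"
        )
    return arr


def read_gray(path) -> np.ndarray:
    """Read a PNG/TIFF image as grayscale in [0, 1] (8/16-bit rescaled)."""
    raw = iio.imread(path)
    arr = np.asarray(raw)
    if arr.ndim == 3:  # RGB(A) -> luma
        arr = arr[..., :3].astype(float).mean(axis=-1)
    arr = arr.astype(float)
    if raw.dtype == np.uint8:
        arr = arr / 255.0
    elif raw.dtype == np.uint16:
        arr = arr / 65535.0
    elif arr.max() > 1.0:
        arr = arr / arr.max()
    return as_gray(np.clip(arr, 0.0, 1.0))


def write_gray(path, pixels: np.ndarray) -> None:
    """Write a [0, 1] grayscale image as 8-bit PNG."""
    arr = as_gray(pixels)
    iio.imwrite(path, np.round(arr * 255.0).astype(np.uint8))


def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as a 0/255 8-bit PNG."""
    m = np.asarray(mask)
    iio.imwrite(path, (m > 0).astype(np.uint8) * 255)


def read_mask(path) -> np.ndarray:
    """Read a PNG as a binary {0, 1} mask (any nonzero pixel is foreground)."""
    return (np.asarray(iio.imread(path)) > 0).astype(np.uint8)
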