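"""Raster image ingest and conversion.

The pipeline's raw input is an H x W x 3 float array in [0, 255], R,G,B
channel order, 0-based row-major pixel grid (x = column, y = row).
"""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio

__all__ = ["as_raster", "load_image", "save_image", "to_luminance"]

#: ITU-R BT.601 luma weights used for grayscale conversion before feature
#: extraction.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def as_raster(arr: np.ndarray) -> np.ndarray:
    """Coerce an array to the pipeline's raster contract.

    Grayscale input is replicated to 3 channels; an alpha channel is dropped;
    values are scaled to [0, 255] floats (16-bit input divided by 257, floats
    in [0, 1] multiplied by 255). Non-finite values are rejected.
    """
    a = np.asarray(arr)
    if a.ndim == 2:
        a = np.stack([a] * 3, axis=-1)
    if a.ndim != 3 or a.shape[-1] not in (3, 4):
        raise ValueError(f"expected HxW, HxWx3 or HxWx4 array, got shape {a.shape}")
    if a.shape[0] < 1 or a.shape[1] < 1:
        raise ValueError("empty image")
    if a.shape[-1] == 4:
        a = a[..., :3]
    if a.dtype == np.uint8:
        a = a.astype(np.float64)
    elif a.dtype == np.uint16:
        a = a.astype(np.float64) / 257.0
    else:
        a = a.astype(np.float64)
        if not np.all(np.isfinite(a)):
            raise ValueError("image contains non-finite values")
        if a.size and a.max() <= 1.0 and a.min() >= 0.0:
            a = a * 255.0
    if not np.all(np.isfinite(a)):
        raise ValueError("image contains non-finite values")
    return np.clip(a, 0.0, 255.0)


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF file into a raster array."""
    return as_raster(iio.imread(path))


def save_image(path, image: np.ndarray) -> None:
    """Write a raster array as an 8-bit image file."""
    arr = np.clip(np.asarray(image), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)


def to_luminance(image: np.ndarray, scale: bool = True) -> np.ndarray:
    """BT.601 luminance of a raster image.

    With ``scale`` (default) the result is on [0, 1], the scale on which the
    keypoint-detector contrast threshold is defined.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        lum = img
    else:
        lum = img @ LUMA_WEIGHTS
    return lum / 255.0 if scale else lum
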