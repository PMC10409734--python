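"""Small image helpers used by several stages."""

from __future__ import annotations

import numpy as np
from skimage import exposure
from skimage.util import img_as_float


def as_float_gray(image: np.ndarray) -> np.ndarray:
    """Coerce an 8/16-bit or float image to float64 grayscale in [0, 1]."""
    arr = np.asarray(image)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    arr = img_as_float(arr)
    return arr.astype(float, copy=False)


def hist_equalize(image: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Global histogram equalization (applied to ROI crops before shape fits)."""
    return exposure.equalize_hist(as_float_gray(image), nbins=nbins)


def crop(image: np.ndarray, x_min: float, y_min: float, x_max: float, y_max: float):
    """Crop with integer rounding and clipping; returns (crop, (x0, y0))."""
    h, w = image.shape[:2]
    x0 = int(np.clip(np.floor(x_min), 0, w - 1))
    y0 = int(np.clip(np.floor(y_min), 0, h - 1))
    x1 = int(np.clip(np.ceil(x_max), x0 + 1, w))
    y1 = int(np.clip(np.ceil(y_max), y0 + 1, h))
    return image[y0:y1, x0:x1], (x0, y0)
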