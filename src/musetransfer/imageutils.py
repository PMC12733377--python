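"""Small shared helpers for raster images and binary masks."""

from __future__ import annotations

import numpy as np

__all__ = ["as_float_image", "require_binary", "to_grayscale"]

# Rec. 601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


def as_float_image(img: np.ndarray) -> np.ndarray:
    """Return the image as float64 in [0, 1].

    Integer images are assumed to span [0, 255]; float images must already
    lie in [0, 1].
    """
    arr = np.asarray(img)
    if arr.ndim not in (2, 3):
        raise ValueError(f"expected a 2-D or 3-D image array, got ndim={arr.ndim}")
    if arr.ndim == 3 and arr.shape[2] not in (1, 3):
        raise ValueError(f"expected 1 or 3 channels, got {arr.shape[2]}")
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / 255.0
    arr = arr.astype(float)
    if arr.size and (arr.min() < -1e-9 or arr.max() > 1.0 + 1e-9):
        raise ValueError(
            "float images must be scaled to [0, 1]; "
            f"got range [{arr.min():.4g}, {arr.max():.4g}]"
        )
    return np.clip(arr, 0.0, 1.0)


def require_binary(mask: np.ndarray) -> np.ndarray:
    """Validate and return a 2-D boolean mask."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"masks must be 2-D, got ndim={arr.ndim}")
    if arr.dtype == bool:
        return arr
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("mask values must be strictly binary (0/1 or boolean)")
    return arr.astype(bool)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Luma-weighted grayscale (0.299 R + 0.587 G + 0.114 B) in [0, 1]."""
    arr = as_float_image(img)
    if arr.ndim == 2:
        return arr
    if arr.shape[2] == 1:
        return arr[..., 0]
    return arr @ _LUMA
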