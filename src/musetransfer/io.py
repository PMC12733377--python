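"""Readers and writers for the pipeline's file formats.

Images: PNG/TIFF/JPEG rasters (masks as {0,255} single-channel PNG).
Control points: CSV with header ``fixed_x,fixed_y,moving_x,moving_y`` or a
JSON list of objects with the same keys, in raw pixel units so files stay
human-checkable against the images (normalization happens inside fitting).
Transforms: JSON via :class:`~musetransfer.geometry.PolynomialTransform2D`.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .geometry import MIN_PAIRS, ControlPointSet

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_points",
    "write_points",
]

_POINT_COLUMNS = ("fixed_x", "fixed_y", "moving_x", "moving_y")
_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG raster; channels and stored range are preserved."""
    path = Path(path)
    if path.suffix.lower() not in _IMAGE_SUFFIXES:
        raise ValueError(f"unsupported image format {path.suffix!r} ({path})")
    try:
        img = np.asarray(iio.imread(path))
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ValueError(f"could not read image {path}: {exc}") from exc
    if img.dtype not in (np.uint8, np.uint16) and not np.issubdtype(img.dtype, np.floating):
        raise ValueError(f"unsupported bit depth {img.dtype} in {path}")
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[..., :3]  # drop alpha
    return img


def write_image(img: np.ndarray, path) -> None:
    """Write an image; float arrays in [0, 1] are scaled to 8-bit."""
    path = Path(path)
    arr = np.asarray(img)
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    iio.imwrite(path, arr)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as a {0, 255} single-channel PNG."""
    path = Path(path)
    if path.suffix.lower() != ".png":
        raise ValueError("masks are written losslessly as PNG")
    arr = np.asarray(mask)
    if arr.dtype != bool:
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be binary")
        arr = arr.astype(bool)
    iio.imwrite(path, arr.astype(np.uint8) * 255)


def read_mask(path) -> np.ndarray:
    """Read a mask PNG back as boolean; any nonzero stored value is True."""
    img = read_image(path)
    if img.ndim == 3:
        img = img[..., 0]
    vals = np.unique(img)
    if not np.all(np.isin(vals, (0, 255))):
        raise ValueError(f"{path} is not a binary {{0,255}} mask (values {vals[:10]})")
    return img > 0


def read_points(path, fixed_shape, moving_shape) -> ControlPointSet:
    """Read paired landmarks from CSV or JSON.

    The image shapes (rows, cols) must be supplied by the caller because the
    point files carry only pixel coordinates.  Fewer than six rows, a bad
    header or a malformed row raise with the offending line number.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            records = json.load(fh)
        if isinstance(records, dict):
            records = records.get("pairs", records)
        rows = []
        for i, rec in enumerate(records):
            try:
                rows.append([float(rec[c]) for c in _POINT_COLUMNS])
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}: malformed point record {i}: {exc}") from exc
    else:
        with open(path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
        if not lines:
            raise ValueError(f"{path}: empty control point file")
        header = [h.strip().lower() for h in lines[0].split(",")]
        if header != list(_POINT_COLUMNS):
            raise ValueError(
                f"{path}: line 1: expected header {','.join(_POINT_COLUMNS)!r}, "
                f"got {lines[0]!r}"
            )
        rows = []
        for lineno, line in enumerate(lines[1:], start=2):
            parts = line.split(",")
            if len(parts) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 fields, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    if len(rows) < MIN_PAIRS:
        raise ValueError(
            f"{path}: {len(rows)} point pairs found but at least {MIN_PAIRS} are "
            "required for the second-order polynomial fit"
        )
    arr = np.asarray(rows, dtype=float)
    return ControlPointSet(arr[:, 0:2], arr[:, 2:4], fixed_shape, moving_shape)


def write_points(points: ControlPointSet, path) -> None:
    """Write landmarks as CSV (default) or JSON, full float precision."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = [
            {
                "fixed_x": fx,
                "fixed_y": fy,
                "moving_x": mx,
                "moving_y": my,
            }
            for (fx, fy), (mx, my) in zip(points.fixed.tolist(), points.moving.tolist())
        ]
        with open(path, "w") as fh:
            json.dump({"pairs": records}, fh, indent=2)
        return
    with open(path, "w") as fh:
        fh.write(",".join(_POINT_COLUMNS) + "\n")
        for (fx, fy), (mx, my) in zip(points.fixed.tolist(), points.moving.tolist()):
            fh.write(f"{fx!r},{fy!r},{mx!r},{my!r}\n")
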