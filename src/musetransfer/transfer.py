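"""Annotation refinement and transfer back to raw fluorescence space.

The extracted annotation mask lives on the H&E canvas and may cover
background.  Refinement intersects it with an eroded tissue mask (erosion
trims boundary artifacts of the tissue segmentation); the refined mask is
then warped into raw MUSE pixel space with the role-swapped polynomial fit
and rendered as an outline overlay on the raw image.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import dilation, disk

from . import extraction, tissue
from .geometry import (
    FIXED_TO_MOVING,
    MOVING_TO_FIXED,
    ControlPointSet,
    PolynomialTransform2D,
    fit_inverse_transform,
    fit_transform,
    registration_quality,
    warp_image,
)
from .imageutils import as_float_image, require_binary, to_grayscale

logger = logging.getLogger(__name__)

__all__ = [
    "refine_annotation",
    "boundary_of",
    "inverse_transfer",
    "overlay",
    "run_pipeline",
    "TransferResult",
    "DEFAULT_EROSION_SIZE",
]

DEFAULT_EROSION_SIZE = 15  # disk element width (px) for the tissue erosion

# 8-connected foreground / 4-connected background avoids the topological
# paradox where a curve is both closed and non-separating
_FG_STRUCTURE = np.ones((3, 3), dtype=bool)


def refine_annotation(
    annotation_mask: np.ndarray,
    tissue_mask: np.ndarray,
    erosion_size: int = DEFAULT_EROSION_SIZE,
) -> np.ndarray:
    """Intersect the annotation with the eroded tissue mask.

    The erosion (disk element of width ``erosion_size``) pulls the tissue
    boundary inward so that segmentation artifacts at the tissue edge cannot
    leak into the refined annotation.  The result is a subset of both inputs.
    """
    ann = require_binary(annotation_mask)
    tis = require_binary(tissue_mask)
    if ann.shape != tis.shape:
        raise ValueError(f"mask shapes differ: {ann.shape} vs {tis.shape}")
    if erosion_size <= 0:
        raise ValueError(f"erosion_size must be positive, got {erosion_size}")
    # outside the frame counts as background, so tissue touching the image
    # border is eroded too (scikit-image's grayscale erosion would keep it)
    eroded = ndimage.binary_erosion(
        tis, structure=disk(erosion_size // 2), border_value=0
    )
    refined = ann & eroded
    if ann.any() and not refined.any():
        logger.warning(
            "refined annotation is empty: the drawn outline lies entirely "
            "outside the (eroded) tissue region"
        )
    return refined


def boundary_of(mask: np.ndarray) -> np.ndarray:
    """(x, y) pixel coordinates of the mask boundary.

    A boundary pixel is a foreground pixel with at least one background
    neighbor (8-connectivity), i.e. the mask minus its 1-px erosion.  Pixels
    on the image frame count as boundary.
    """
    m = require_binary(mask)
    inner = ndimage.binary_erosion(m, structure=_FG_STRUCTURE, border_value=0)
    rr, cc = np.nonzero(m & ~inner)
    return np.column_stack([cc, rr]).astype(float)


def inverse_transfer(
    refined_mask: np.ndarray,
    points: ControlPointSet,
    raw_shape: tuple[int, int],
    *,
    normalization: str = "per_axis",
    condition_cap: float = 1e8,
) -> np.ndarray:
    """Warp a fixed-space mask into raw MUSE pixel space.

    Warping the raw canvas requires the moving-to-fixed mapping as its
    output-to-input lookup, i.e. the forward fit evaluated at raw-space
    coordinates.  Nearest-neighbor sampling keeps the mask binary.
    """
    mask = require_binary(refined_mask)
    t = fit_transform(
        points, MOVING_TO_FIXED, normalization=normalization, condition_cap=condition_cap
    )
    out = warp_image(
        mask.astype(np.uint8),
        t,
        raw_shape,
        interpolation="nearest",
        fill=0,
        expected_direction=MOVING_TO_FIXED,
    )
    return out.astype(bool)


def overlay(
    raw_muse: np.ndarray,
    outline: np.ndarray,
    color=(0, 255, 0),
    thickness: int = 3,
) -> np.ndarray:
    """Draw an outline (point set) onto a copy of the raw image.

    Outline points falling outside the frame are clipped with a warning.
    Only outline pixels (dilated to ``thickness``) are modified.
    """
    img = as_float_image(raw_muse)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    out = img.copy()
    pts = np.atleast_2d(np.asarray(outline, dtype=float))
    if pts.size == 0:
        return out
    if thickness <= 0:
        raise ValueError(f"thickness must be positive, got {thickness}")
    cols = np.round(pts[:, 0]).astype(int)
    rows = np.round(pts[:, 1]).astype(int)
    inside = (rows >= 0) & (rows < out.shape[0]) & (cols >= 0) & (cols < out.shape[1])
    if not inside.all():
        logger.warning("%d outline points outside the image were clipped", (~inside).sum())
    stroke = np.zeros(out.shape[:2], dtype=bool)
    stroke[rows[inside], cols[inside]] = True
    if thickness > 1:
        stroke = dilation(stroke, disk(thickness // 2))
    rgb = np.asarray(color, dtype=float)
    if rgb.max() > 1:
        rgb = rgb / 255.0
    out[stroke] = rgb
    return out


@dataclass
class TransferResult:
    """Everything one annotation-transfer run produces."""

    transform: PolynomialTransform2D
    inverse_transform: PolynomialTransform2D
    registered_muse: np.ndarray
    annotation_mask: np.ndarray
    tissue_mask: np.ndarray
    refined_mask: np.ndarray
    transferred_mask: np.ndarray
    outline: np.ndarray
    overlay_image: np.ndarray
    registration_dsc: float
    provenance: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PipelineParams:
    """Tunable parameters of the end-to-end transfer."""

    diff_threshold: float = extraction.DEFAULT_DIFF_THRESHOLD
    closing_radius: int = extraction.DEFAULT_CLOSING_RADIUS
    tissue: tissue.TissueMaskParams = field(default_factory=tissue.TissueMaskParams)
    erosion_size: int = DEFAULT_EROSION_SIZE
    overlay_color: tuple[int, int, int] = (0, 255, 0)
    overlay_thickness: int = 3
    normalization: str = "per_axis"
    condition_cap: float = 1e8


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _he_tissue_mask(clean_he: np.ndarray) -> np.ndarray:
    """Coarse tissue mask of an H&E export: pixels darker than the pale
    background, holes filled.  Used only for the registration-quality score."""
    gray = to_grayscale(clean_he)
    bg = float(np.median([gray[0, :].mean(), gray[-1, :].mean()]))
    mask = gray < bg - 0.08
    return ndimage.binary_fill_holes(mask)


def run_pipeline(
    annotated_he: np.ndarray,
    clean_he: np.ndarray,
    raw_muse: np.ndarray,
    points: ControlPointSet,
    params: PipelineParams | None = None,
) -> TransferResult:
    """Full semi-automated annotation transfer.

    Stages: fit the forward and inverse polynomial transforms from the
    landmarks; warp the raw MUSE image onto the H&E canvas; extract the drawn
    annotation from the H&E export pair; segment tissue in the registered
    MUSE image; refine the annotation against the eroded tissue mask; warp
    the refined mask back to raw MUSE space; render the outline overlay.
    Deterministic: identical inputs and parameters give bit-identical masks.
    """
    params = params or PipelineParams()
    stage = "inputs"
    try:
        annotated = as_float_image(annotated_he)
        clean = as_float_image(clean_he)
        muse = as_float_image(raw_muse)
        fixed_shape = tuple(annotated.shape[:2])
        raw_shape = tuple(muse.shape[:2])
        if clean.shape != annotated.shape:
            raise ValueError("annotated and clean H&E exports must have identical shape")

        stage = "registration"
        forward = fit_transform(
            points,
            MOVING_TO_FIXED,
            normalization=params.normalization,
            condition_cap=params.condition_cap,
        )
        inverse = fit_inverse_transform(
            points,
            normalization=params.normalization,
            condition_cap=params.condition_cap,
        )
        registered = warp_image(
            muse, inverse, fixed_shape, interpolation="bilinear", fill=0.0,
            expected_direction=FIXED_TO_MOVING,
        )

        stage = "annotation extraction"
        annotation_mask = extraction.extract_annotation_mask(
            annotated,
            clean,
            diff_threshold=params.diff_threshold,
            closing_radius=params.closing_radius,
        )

        stage = "tissue masking"
        tissue_mask = tissue.compute_tissue_mask(registered, params.tissue)

        stage = "refinement"
        refined = refine_annotation(annotation_mask, tissue_mask, params.erosion_size)

        stage = "inverse transfer"
        transferred = warp_image(
            refined.astype(np.uint8),
            forward,
            raw_shape,
            interpolation="nearest",
            fill=0,
            expected_direction=MOVING_TO_FIXED,
        ).astype(bool)
        outline = boundary_of(transferred)

        stage = "overlay"
        overlay_img = overlay(
            muse, outline, color=params.overlay_color, thickness=params.overlay_thickness
        )

        stage = "quality report"
        reg_dsc = registration_quality(tissue_mask, _he_tissue_mask(clean))
    except Exception as exc:
        raise RuntimeError(f"annotation transfer failed at stage '{stage}': {exc}") from exc

    provenance = {
        "params": {
            "diff_threshold": params.diff_threshold,
            "closing_radius": params.closing_radius,
            "tissue": vars(params.tissue).copy(),
            "erosion_size": params.erosion_size,
            "normalization": params.normalization,
        },
        "n_control_points": len(points),
        "fit_rms_px": forward.fit_report.rms_px if forward.fit_report else None,
        "checksums": {
            "annotated_he": _checksum(annotated),
            "clean_he": _checksum(clean),
            "raw_muse": _checksum(muse),
            "transferred_mask": _checksum(transferred),
        },
    }
    return TransferResult(
        transform=forward,
        inverse_transform=inverse,
        registered_muse=registered,
        annotation_mask=annotation_mask,
        tissue_mask=tissue_mask,
        refined_mask=refined,
        transferred_mask=transferred,
        outline=outline,
        overlay_image=overlay_img,
        registration_dsc=reg_dsc,
        provenance=provenance,
    )
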