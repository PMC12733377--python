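"""Recover the pathologist's drawn tumor outline as a filled binary mask.

Slide viewers export the annotated H&E image twice — once with the drawn
overlay and once without.  Subtracting the clean export from the annotated
one isolates the stroke pixels; morphological closing bridges gaps where the
stroke is broken, and hole filling turns the closed outline into a region
mask.  The subtraction is color-agnostic: any overlay color that differs
from the underlying pixels by more than the threshold is picked up.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage.morphology import closing, disk

from .imageutils import as_float_image, require_binary

logger = logging.getLogger(__name__)

__all__ = [
    "subtract_annotation_layer",
    "close_outline",
    "fill_outline",
    "extract_annotation_mask",
    "DEFAULT_DIFF_THRESHOLD",
    "DEFAULT_CLOSING_RADIUS",
]

# JPEG re-compression of the two exports leaves small nonzero differences
# everywhere; 10/255 clears that floor while keeping any real overlay stroke.
DEFAULT_DIFF_THRESHOLD = 10.0 / 255.0
DEFAULT_CLOSING_RADIUS = 5


def subtract_annotation_layer(
    annotated: np.ndarray,
    clean: np.ndarray,
    diff_threshold: float = DEFAULT_DIFF_THRESHOLD,
) -> np.ndarray:
    """Binary mask of pixels where the two exports differ.

    A pixel is marked when the maximum per-channel absolute difference
    exceeds ``diff_threshold`` (on the [0, 1] intensity scale).
    """
    ann = as_float_image(annotated)
    cln = as_float_image(clean)
    if ann.shape != cln.shape:
        raise ValueError(
            f"annotated and clean exports must match in shape and channels; "
            f"got {ann.shape} vs {cln.shape}"
        )
    if not 0.0 <= diff_threshold <= 1.0:
        raise ValueError(f"diff_threshold must lie in [0, 1], got {diff_threshold}")
    diff = np.abs(ann - cln)
    if diff.ndim == 3:
        diff = diff.max(axis=2)
    return diff > diff_threshold


def close_outline(outline: np.ndarray, radius: int = DEFAULT_CLOSING_RADIUS) -> np.ndarray:
    """Morphologically close the stroke mask with a disk element.

    Drawn annotation strokes are several pixels wide; where compression or
    thresholding ate a short stretch of stroke, closing re-seals it.  The
    bridgeable gap scales with the stroke width (closing cannot reconnect
    the endpoints of an idealized 1-px curve: the erosion removes any thin
    bridge the dilation builds); raise ``radius`` for wider dropouts.  The
    result is always a superset of the input (the union guards against
    border clipping).
    """
    if radius <= 0:
        raise ValueError(f"closing radius must be positive, got {radius}")
    mask = require_binary(outline)
    closed = closing(mask, disk(radius))
    return closed | mask


def fill_outline(closed_outline: np.ndarray) -> np.ndarray:
    """Fill every region enclosed by the outline.

    Background connectivity is 4-connected (the dual of the 8-connected
    stroke), so a diagonal chain of stroke pixels still seals its interior.
    Pixels reachable from the image border stay background; disjoint closed
    outlines are each filled.
    """
    mask = require_binary(closed_outline)
    return ndimage.binary_fill_holes(mask)


def extract_annotation_mask(
    annotated: np.ndarray,
    clean: np.ndarray,
    *,
    diff_threshold: float = DEFAULT_DIFF_THRESHOLD,
    closing_radius: int = DEFAULT_CLOSING_RADIUS,
) -> np.ndarray:
    """Subtract, close and fill: the full annotation-mask chain.

    The result may include background the pathologist deliberately enclosed
    (deeper tissue layers can harbor tumor); the downstream refinement step
    intersects it with the fluorescence tissue mask.
    """
    stroke = subtract_annotation_layer(annotated, clean, diff_threshold)
    if not stroke.any():
        logger.warning(
            "annotated and clean exports are identical at threshold %.4f; "
            "annotation mask is empty",
            diff_threshold,
        )
        return stroke
    return fill_outline(close_outline(stroke, closing_radius))
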