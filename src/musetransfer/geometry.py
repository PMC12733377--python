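"""Second-order polynomial landmark registration.

Aligns a moving fluorescence (MUSE) image to a fixed, pathologist-annotated
H&E image from manually paired landmarks.  The mapping is a full degree-2
polynomial per output axis,

    X = a0 + a1*x + a2*y + a3*x^2 + a4*x*y + a5*y^2
    Y = b0 + b1*x + b2*y + b3*x^2 + b4*x*y + b5*y^2

fitted by linear least squares in normalized coordinates.  A quadratic
polynomial has no closed-form inverse, so the inverse mapping is obtained by
refitting with the fixed/moving roles swapped rather than by numerical
inversion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ControlPointSet",
    "FitReport",
    "PolynomialTransform2D",
    "DegenerateLandmarksError",
    "normalize_points",
    "denormalize_points",
    "polynomial_design_matrix",
    "fit_transform",
    "fit_inverse_transform",
    "warp_image",
    "registration_quality",
    "MOVING_TO_FIXED",
    "FIXED_TO_MOVING",
]

MOVING_TO_FIXED = "moving_to_fixed"
FIXED_TO_MOVING = "fixed_to_moving"

MIN_PAIRS = 6  # a degree-2 polynomial per axis has 6 coefficients


class DegenerateLandmarksError(ValueError):
    """Raised when the landmark configuration cannot support a stable fit."""


def _as_points(arr) -> np.ndarray:
    pts = np.asarray(arr, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(1, 2)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an (N, 2) array of (x, y) points, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("point coordinates must be finite")
    return pts


def _axis_divisors(shape, normalization: str) -> tuple[float, float]:
    rows, cols = int(shape[0]), int(shape[1])
    if rows <= 0 or cols <= 0:
        raise ValueError(f"image shape must be positive, got {(rows, cols)}")
    if normalization == "per_axis":
        return float(cols), float(rows)
    if normalization == "max_dim":
        m = float(max(rows, cols))
        return m, m
    raise ValueError(f"unknown normalization convention {normalization!r}")


def normalize_points(points, shape, normalization: str = "per_axis") -> np.ndarray:
    """Map pixel (x, y) coordinates to dimensionless coordinates.

    ``per_axis`` divides x by the image width and y by the image height;
    ``max_dim`` divides both by the larger dimension.  Unit-scale coordinates
    keep the quadratic design matrix well conditioned at typical whole-sample
    image sizes (10^3-10^4 px).
    """
    pts = _as_points(points)
    dx, dy = _axis_divisors(shape, normalization)
    return pts / np.array([dx, dy])


def denormalize_points(points, shape, normalization: str = "per_axis") -> np.ndarray:
    """Inverse of :func:`normalize_points`."""
    pts = _as_points(points)
    dx, dy = _axis_divisors(shape, normalization)
    return pts * np.array([dx, dy])


@dataclass(frozen=True)
class ControlPointSet:
    """Paired landmarks in fixed (H&E) and moving (MUSE) pixel coordinates.

    At least six non-duplicate pairs are required; the degree-2 fit is exactly
    determined at six and overdetermined (least squares) beyond.
    """

    fixed: np.ndarray
    moving: np.ndarray
    fixed_shape: tuple[int, int]
    moving_shape: tuple[int, int]

    def __post_init__(self):
        fixed = _as_points(self.fixed)
        moving = _as_points(self.moving)
        if fixed.shape != moving.shape:
            raise ValueError("fixed and moving point arrays must have the same shape")
        object.__setattr__(self, "fixed", fixed)
        object.__setattr__(self, "moving", moving)
        object.__setattr__(self, "fixed_shape", (int(self.fixed_shape[0]), int(self.fixed_shape[1])))
        object.__setattr__(self, "moving_shape", (int(self.moving_shape[0]), int(self.moving_shape[1])))
        if len(self.deduplicated().fixed) < MIN_PAIRS:
            raise ValueError(
                f"at least {MIN_PAIRS} distinct control point pairs are required for a "
                f"second-order polynomial fit; got {len(self.deduplicated().fixed)}"
            )

    def __len__(self) -> int:
        return len(self.fixed)

    def deduplicated(self) -> "ControlPointSet":
        """Drop exact duplicate pairs, preserving first occurrence order."""
        both = np.hstack([self.fixed, self.moving])
        _, idx = np.unique(both, axis=0, return_index=True)
        idx = np.sort(idx)
        if len(idx) == len(self.fixed):
            return self
        return ControlPointSet(
            self.fixed[idx], self.moving[idx], self.fixed_shape, self.moving_shape
        )

    def swapped(self) -> "ControlPointSet":
        """Swap the fixed/moving roles (used to fit the inverse mapping)."""
        return ControlPointSet(self.moving, self.fixed, self.moving_shape, self.fixed_shape)


@dataclass(frozen=True)
class FitReport:
    """Per-landmark residuals of a fitted transform, in output-side pixels."""

    per_point_px: np.ndarray
    rms_px: float
    condition_number: float


@dataclass
class PolynomialTransform2D:
    """Degree-2 polynomial plane mapping in normalized coordinates.

    ``a`` produces the horizontal output coordinate and ``b`` the vertical
    one, each from the monomial basis [1, x, y, x^2, x*y, y^2].  ``direction``
    records which frame the input coordinates live in.
    """

    a: np.ndarray
    b: np.ndarray
    direction: str
    normalization: str = "per_axis"
    input_shape: tuple[int, int] | None = None
    output_shape: tuple[int, int] | None = None
    fit_report: FitReport | None = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float).reshape(-1)
        self.b = np.asarray(self.b, dtype=float).reshape(-1)
        if self.a.size != 6 or self.b.size != 6:
            raise ValueError("each axis requires exactly 6 polynomial coefficients")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))):
            raise ValueError("polynomial coefficients must be finite")
        if self.direction not in (MOVING_TO_FIXED, FIXED_TO_MOVING):
            raise ValueError(f"unknown direction {self.direction!r}")

    @classmethod
    def identity(cls, direction: str = MOVING_TO_FIXED) -> "PolynomialTransform2D":
        return cls(a=[0, 1, 0, 0, 0, 0], b=[0, 0, 1, 0, 0, 0], direction=direction)

    def __call__(self, points) -> np.ndarray:
        """Evaluate the polynomial at normalized (x, y) points; returns (N, 2)."""
        pts = _as_points(points)
        design = polynomial_design_matrix(pts)
        return np.column_stack([design @ self.a, design @ self.b])

    def map_pixels(self, points_px) -> np.ndarray:
        """Evaluate at pixel coordinates, normalizing/denormalizing by the
        recorded input and output image shapes."""
        if self.input_shape is None or self.output_shape is None:
            raise ValueError("transform carries no image shapes; use normalized coordinates")
        norm = normalize_points(points_px, self.input_shape, self.normalization)
        out = self(norm)
        return denormalize_points(out, self.output_shape, self.normalization)

    def to_dict(self) -> dict:
        return {
            "a": [float(v) for v in self.a],
            "b": [float(v) for v in self.b],
            "direction": self.direction,
            "normalization": self.normalization,
            "input_shape": list(self.input_shape) if self.input_shape else None,
            "output_shape": list(self.output_shape) if self.output_shape else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolynomialTransform2D":
        return cls(
            a=d["a"],
            b=d["b"],
            direction=d["direction"],
            normalization=d.get("normalization", "per_axis"),
            input_shape=tuple(d["input_shape"]) if d.get("input_shape") else None,
            output_shape=tuple(d["output_shape"]) if d.get("output_shape") else None,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PolynomialTransform2D":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def polynomial_design_matrix(points) -> np.ndarray:
    """Monomial basis [1, x, y, x^2, x*y, y^2] evaluated at each point."""
    pts = _as_points(points)
    x, y = pts[:, 0], pts[:, 1]
    return np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])


def fit_transform(
    points: ControlPointSet,
    direction: str = MOVING_TO_FIXED,
    *,
    normalization: str = "per_axis",
    condition_cap: float = 1e8,
) -> PolynomialTransform2D:
    """Least-squares fit of the degree-2 transform from paired landmarks.

    Each output axis is solved independently with an SVD-based solver
    (rank-revealing; the quadratic terms make normal equations unreliable).
    With exactly six non-degenerate pairs the system is square and the
    residuals vanish to machine precision.

    Raises
    ------
    ValueError
        If fewer than six distinct pairs remain after deduplication.
    DegenerateLandmarksError
        If the design matrix condition number exceeds ``condition_cap``
        (near-collinear landmarks extrapolate wildly).
    """
    points = points.deduplicated()
    if direction == MOVING_TO_FIXED:
        src_px, dst_px = points.moving, points.fixed
        src_shape, dst_shape = points.moving_shape, points.fixed_shape
    elif direction == FIXED_TO_MOVING:
        src_px, dst_px = points.fixed, points.moving
        src_shape, dst_shape = points.fixed_shape, points.moving_shape
    else:
        raise ValueError(f"unknown direction {direction!r}")

    src = normalize_points(src_px, src_shape, normalization)
    dst = normalize_points(dst_px, dst_shape, normalization)

    design = polynomial_design_matrix(src)
    cond = np.linalg.cond(design)
    if not np.isfinite(cond) or cond > condition_cap:
        raise DegenerateLandmarksError(
            f"landmark design matrix is ill-conditioned (cond={cond:.3g} > cap "
            f"{condition_cap:.3g}); spread the control points over the tissue"
        )

    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    t = PolynomialTransform2D(
        a=coef[:, 0],
        b=coef[:, 1],
        direction=direction,
        normalization=normalization,
        input_shape=src_shape,
        output_shape=dst_shape,
    )
    mapped_px = denormalize_points(t(src), dst_shape, normalization)
    resid = np.linalg.norm(mapped_px - dst_px, axis=1)
    t.fit_report = FitReport(
        per_point_px=resid,
        rms_px=float(np.sqrt(np.mean(resid**2))),
        condition_number=float(cond),
    )
    return t


def fit_inverse_transform(
    points: ControlPointSet,
    *,
    normalization: str = "per_axis",
    condition_cap: float = 1e8,
) -> PolynomialTransform2D:
    """Fit the fixed-to-moving mapping by swapping the landmark roles."""
    return fit_transform(
        points,
        direction=FIXED_TO_MOVING,
        normalization=normalization,
        condition_cap=condition_cap,
    )


_INTERP_ORDER = {"bilinear": 1, "nearest": 0}


def warp_image(
    img: np.ndarray,
    transform: PolynomialTransform2D,
    out_shape: tuple[int, int],
    *,
    interpolation: str = "bilinear",
    fill: float = 0.0,
    expected_direction: str | None = None,
) -> np.ndarray:
    """Resample ``img`` onto an ``out_shape`` canvas.

    ``transform`` must follow the inverse-mapping convention: it takes
    normalized *output*-canvas coordinates to normalized *input*-image
    coordinates.  (To register the MUSE image onto the H&E canvas, pass the
    fixed-to-moving fit; to carry a mask back to raw MUSE space, pass the
    moving-to-fixed fit.)  Out-of-frame samples are filled with ``fill``
    (default 0 — background is dark in both modalities).  Use nearest
    interpolation for masks; it preserves binarity.
    """
    if expected_direction is not None and transform.direction != expected_direction:
        raise ValueError(
            f"transform direction {transform.direction!r} does not match the "
            f"required output-to-input mapping {expected_direction!r}"
        )
    if interpolation not in _INTERP_ORDER:
        raise ValueError(f"interpolation must be one of {sorted(_INTERP_ORDER)}")
    img = np.asarray(img)
    out_rows, out_cols = int(out_shape[0]), int(out_shape[1])

    yy, xx = np.mgrid[0:out_rows, 0:out_cols]
    out_pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    norm_out = normalize_points(out_pts, (out_rows, out_cols), transform.normalization)
    norm_in = transform(norm_out)
    in_pts = denormalize_points(norm_in, img.shape[:2], transform.normalization)
    # map_coordinates expects (row, col) sample locations
    coords = np.stack([in_pts[:, 1], in_pts[:, 0]])

    order = _INTERP_ORDER[interpolation]

    def _sample(channel):
        return ndimage.map_coordinates(
            channel.astype(float), coords, order=order, mode="constant", cval=fill
        ).reshape(out_rows, out_cols)

    if img.ndim == 2:
        out = _sample(img)
        if order == 0:
            out = out.astype(img.dtype)
        return out
    out = np.stack([_sample(img[..., c]) for c in range(img.shape[2])], axis=-1)
    if order == 0:
        out = out.astype(img.dtype)
    return out


def registration_quality(warped_tissue_mask, fixed_tissue_mask) -> float:
    """Dice overlap between the warped-MUSE and H&E tissue masks.

    This is the score a user maximizes while iteratively refining the manual
    control points; the refinement loop itself is human-driven.
    """
    from .metrics import dice

    return dice(warped_tissue_mask, fixed_tissue_mask)
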