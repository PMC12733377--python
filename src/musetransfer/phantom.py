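"""Synthetic H&E / fluorescence phantom pairs with known ground truth.

Real validation data for cross-modality annotation transfer are whole-sample
image pairs with pathologist annotations, which cannot ship with a library.
The phantom generator emulates their geometry instead: a smooth random
tissue blob on background rendered in an H&E-like palette (pale background,
pink stroma, purple nuclei) and, through a known degree-2 warp, in a
fluorescence-like palette (dark background, red nuclear and green
cytoplasmic signal); a tumor subregion whose outline is drawn on the
annotated H&E copy; exact landmark pairs on the tissue boundary (where
manual pickers find the strongest cross-modality features); optional
tissue-loss patches mimicking FFPE damage.  Every stage of the pipeline and
the end-to-end transfer can thus be scored against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.draw import polygon
from skimage.morphology import dilation, disk

from .geometry import (
    MOVING_TO_FIXED,
    ControlPointSet,
    PolynomialTransform2D,
    denormalize_points,
    normalize_points,
    warp_image,
)
from .transfer import boundary_of

__all__ = ["PhantomParams", "SyntheticSample", "generate_phantom", "perturb_control_points"]


@dataclass(frozen=True)
class PhantomParams:
    """Study conditions for one synthetic sample.

    The default 1024-px canvas is the smallest scale at which the pipeline's
    fixed-size morphology parameters (disk 55, Gaussian 63/53) operate in
    the regime they assume on real whole-sample exports; pass a smaller
    ``shape`` for cheap many-replicate simulations.  The tissue blob fills a
    little under half the frame and the tumor about 40% of the tissue
    radius, leaving the margins that real annotations keep from the tissue
    edge.  ``warp_magnitude`` bounds the quadratic coefficients of the
    hidden moving-to-fixed polynomial in normalized units (0.05 is a mild,
    FFPE-plausible distortion; tens of pixels at these scales).
    """

    shape: tuple[int, int] = (1024, 1024)
    moving_shape: tuple[int, int] | None = None  # defaults to `shape`
    tissue_radius_frac: float = 0.40  # of min(shape)
    boundary_wobble: float = 0.08  # radial Fourier perturbation amplitude
    tumor_radius_frac: float = 0.40  # of the tissue radius
    tumor_offset_frac: float = 0.25  # tumor center offset, of the tissue radius
    nuclei_density: float = 0.02  # fraction of tissue pixels seeding a nucleus
    outline_thickness: int = 3
    warp_magnitude: float = 0.05
    warp_coefficients: tuple | None = None  # explicit (a, b) override
    n_control_points: int = 12
    landmark_inward_scatter: float = 0.2  # radial spread of landmarks off the boundary
    jitter_sigma: float = 0.0  # px, on moving points
    tissue_loss_fraction: float = 0.0  # of tissue area, removed from raw MUSE
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self):
        for name in (
            "tissue_radius_frac",
            "tumor_radius_frac",
            "tumor_offset_frac",
            "nuclei_density",
            "tissue_loss_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_control_points < 6:
            raise ValueError("at least 6 control points are required")
        if self.jitter_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("sigma values must be non-negative")


@dataclass
class SyntheticSample:
    """One phantom: rendered images, ground-truth masks, warp and landmarks."""

    clean_he: np.ndarray
    annotated_he: np.ndarray
    raw_muse: np.ndarray
    true_tissue_mask: np.ndarray  # fixed (H&E) space
    true_tissue_mask_raw: np.ndarray  # raw MUSE space
    true_tumor_mask_fixed: np.ndarray
    true_tumor_mask_raw: np.ndarray
    true_transform: PolynomialTransform2D
    control_points: ControlPointSet
    params: PhantomParams = field(repr=False, default=None)


def _blob_mask(shape, center, radius, wobble, rng, n_harmonics=4, n_vertices=720):
    """Rasterize a smooth star-convex blob: a circle with low-order radial
    Fourier perturbation."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    amps = rng.uniform(0.2, 1.0, n_harmonics) / np.arange(1, n_harmonics + 1)
    amps *= rng.uniform(0.5, 1.0) * wobble / amps.sum()  # total deviation <= wobble
    phases = rng.uniform(0.0, 2.0 * np.pi, n_harmonics)
    r = np.full_like(theta, 1.0)
    for k in range(1, n_harmonics + 1):
        r += amps[k - 1] * np.cos(k * theta + phases[k - 1])
    rr = center[0] + radius * r * np.sin(theta)
    cc = center[1] + radius * r * np.cos(theta)
    rows, cols = polygon(rr, cc, shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rows, cols] = True
    return mask


def _centered_axis_coeffs(identity_axis: int, d, q) -> np.ndarray:
    """Expand  out = in_axis + d0 + d1*u + d2*v + q3*u^2 + q4*u*v + q5*v^2,
    with (u, v) = (x - 1/2, y - 1/2), into the [1, x, y, x^2, xy, y^2] basis.

    Perturbing around the frame center keeps the displacement small over the
    tissue even when the quadratic terms are at their magnitude bound.
    """
    d0, d1, d2 = d
    q3, q4, q5 = q
    c = np.array(
        [
            d0 - 0.5 * d1 - 0.5 * d2 + 0.25 * (q3 + q4 + q5),
            d1 - q3 - 0.5 * q4,
            d2 - 0.5 * q4 - q5,
            q3,
            q4,
            q5,
        ]
    )
    c[1 + identity_axis] += 1.0
    return c


def _draw_transform(params: PhantomParams, rng) -> PolynomialTransform2D:
    """Hidden moving-to-fixed warp: identity plus bounded perturbations.

    Quadratic coefficients are drawn up to ``warp_magnitude``; translation
    and linear terms up to a quarter of it, so the total displacement over a
    centered tissue blob stays within about 5% of the frame at the default
    magnitude.
    """
    if params.warp_coefficients is not None:
        a, b = params.warp_coefficients
        return PolynomialTransform2D(a=a, b=b, direction=MOVING_TO_FIXED)
    m = params.warp_magnitude
    a = _centered_axis_coeffs(0, rng.uniform(-m / 4, m / 4, 3), rng.uniform(-m, m, 3))
    b = _centered_axis_coeffs(1, rng.uniform(-m / 4, m / 4, 3), rng.uniform(-m, m, 3))
    return PolynomialTransform2D(a=a, b=b, direction=MOVING_TO_FIXED)


def _speckle(shape, inside, density, rng, dot_radius=1):
    seeds = (rng.random(shape) < density) & inside
    if dot_radius > 0:
        seeds = dilation(seeds, disk(dot_radius)) & inside
    return seeds


def _render_he(tissue, nuclei, rng, shape):
    img = np.empty(shape + (3,), dtype=float)
    img[...] = (0.93, 0.91, 0.95)  # pale slide background
    shade = ndimage.gaussian_filter(rng.standard_normal(shape), 20) * 0.03
    for c, base in enumerate((0.88, 0.62, 0.76)):  # eosin pink stroma
        chan = img[..., c]
        chan[tissue] = np.clip(base + shade[tissue], 0.0, 1.0)
    for c, base in enumerate((0.42, 0.24, 0.56)):  # hematoxylin nuclei
        img[..., c][nuclei] = base
    return img


def _render_muse(tissue, nuclei, rng, shape, noise_sigma):
    img = np.empty(shape + (3,), dtype=float)
    img[...] = 0.02  # dark field
    shade = ndimage.gaussian_filter(rng.standard_normal(shape), 20) * 0.05
    img[..., 0][tissue] = 0.28 + shade[tissue]  # propidium-iodide red
    img[..., 1][tissue] = 0.48 + shade[tissue]  # eosin-Y green
    img[..., 2][tissue] = 0.06
    img[..., 0][nuclei] = 0.80
    img[..., 1][nuclei] = 0.30
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0)


def _boundary_landmarks(mask, n_points, inward_scatter, rng):
    """Pick n landmark pixels spread around the tissue edge.

    Points sit at roughly equally spaced angles around the region centroid,
    on boundary features pulled inward by a uniform fraction up to
    ``inward_scatter``.  The radial spread matters: landmarks exactly on a
    smooth closed boundary lie near a conic, which is a degenerate
    configuration for a quadratic fit — small point errors then produce
    large interior mapping errors, far beyond what manual picking shows.
    """
    pts = boundary_of(mask)
    centroid = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 1] - centroid[1], pts[:, 0] - centroid[0])
    targets = np.linspace(-np.pi, np.pi, n_points, endpoint=False)
    targets = targets + rng.uniform(-0.25, 0.25, n_points) * (2 * np.pi / n_points)
    chosen = []
    for t in targets:
        diff = np.angle(np.exp(1j * (ang - t)))
        chosen.append(pts[np.argmin(np.abs(diff))])
    chosen = np.array(chosen, dtype=float)
    if inward_scatter > 0:
        pull = rng.uniform(0.0, inward_scatter, (n_points, 1))
        chosen = chosen + (centroid - chosen) * pull
    return chosen


def generate_phantom(params: PhantomParams | None = None, **overrides) -> SyntheticSample:
    """Generate one deterministic synthetic sample.

    Fixed-space geometry (tissue blob, tumor subregion) is rendered in the
    H&E palette; the raw fluorescence image is produced by sampling the
    fixed-space geometry through the hidden moving-to-fixed polynomial and
    rendering it in the fluorescence palette.  Control points are exact
    landmark pairs on the tissue boundary (optionally jittered on the moving
    side).  Raises if the warp pushes tissue out of the moving frame.
    """
    if params is None:
        params = PhantomParams(**overrides)
    elif overrides:
        params = replace(params, **overrides)
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.shape)
    moving_shape = tuple(params.moving_shape or shape)

    # --- fixed-space geometry ---
    r_tissue = params.tissue_radius_frac * min(shape)
    center = (shape[0] / 2.0, shape[1] / 2.0)
    tissue = _blob_mask(shape, center, r_tissue, params.boundary_wobble, rng)

    r_tumor = params.tumor_radius_frac * r_tissue
    off = params.tumor_offset_frac * r_tissue
    ang = rng.uniform(0.0, 2.0 * np.pi)
    t_center = (center[0] + off * np.sin(ang), center[1] + off * np.cos(ang))
    tumor = _blob_mask(shape, t_center, r_tumor, params.boundary_wobble, rng) & tissue

    nuclei = _speckle(shape, tissue, params.nuclei_density, rng)

    # --- hidden warp and raw-space geometry ---
    true_t = _draw_transform(params, rng)
    true_t.input_shape = moving_shape
    true_t.output_shape = shape

    def to_raw_poly(mask):
        return warp_image(
            mask.astype(np.uint8), true_t, moving_shape, interpolation="nearest", fill=0
        ).astype(bool)

    tissue_raw = to_raw_poly(tissue)
    border = np.zeros(moving_shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    if not tissue_raw.any() or (tissue_raw & border).any():
        raise ValueError(
            "warp pushes the tissue out of the moving frame; reduce warp_magnitude"
        )

    loss = None
    if params.tissue_loss_fraction > 0:
        loss = _draw_tissue_loss(tissue_raw, params.tissue_loss_fraction, rng)

    def moving_to_fixed_px(pts):
        """The phantom's exact moving->fixed mapping: the polynomial, locally
        deformed around loss sites (tissue collapse makes real FFPE
        deformation non-polynomial — the registration's documented failure
        mode)."""
        pts = np.asarray(pts, dtype=float)
        if loss is not None:
            pts = pts + loss.displacement(pts)
        return denormalize_points(true_t(normalize_points(pts, moving_shape)), shape)

    if loss is not None:

        def to_raw(mask):
            yy, xx = np.mgrid[0: moving_shape[0], 0: moving_shape[1]]
            src = moving_to_fixed_px(np.column_stack([xx.ravel(), yy.ravel()]))
            return (
                ndimage.map_coordinates(
                    mask.astype(np.uint8), np.stack([src[:, 1], src[:, 0]]),
                    order=0, mode="constant", cval=0,
                )
                .reshape(moving_shape)
                .astype(bool)
            )

        tissue_raw = to_raw(tissue)
    else:
        to_raw = to_raw_poly
    tumor_raw = to_raw(tumor)
    nuclei_raw = _speckle(moving_shape, tissue_raw, params.nuclei_density, rng)

    # --- rendering ---
    clean_he = _render_he(tissue, nuclei, rng, shape)
    annotated_he = clean_he.copy()
    stroke_pts = boundary_of(tumor)
    stroke = np.zeros(shape, dtype=bool)
    stroke[stroke_pts[:, 1].astype(int), stroke_pts[:, 0].astype(int)] = True
    if params.outline_thickness > 1:
        stroke = dilation(stroke, disk(params.outline_thickness // 2))
    annotated_he[stroke] = (0.05, 0.75, 0.20)  # drawn outline, distinct green

    raw_muse = _render_muse(tissue_raw, nuclei_raw, rng, moving_shape, params.noise_sigma)
    if loss is not None:
        raw_muse = loss.darken(raw_muse, tissue_raw)

    # --- exact landmark pairs (moving -> fixed via the hidden mapping) ---
    moving_pts = _boundary_landmarks(
        tissue_raw, params.n_control_points, params.landmark_inward_scatter, rng
    )
    fixed_pts = moving_to_fixed_px(moving_pts)
    cps = ControlPointSet(fixed_pts, moving_pts, shape, moving_shape)
    if params.jitter_sigma > 0:
        cps = perturb_control_points(cps, params.jitter_sigma, seed=rng.integers(2**31))

    return SyntheticSample(
        clean_he=clean_he,
        annotated_he=annotated_he,
        raw_muse=raw_muse,
        true_tissue_mask=tissue,
        true_tissue_mask_raw=tissue_raw,
        true_tumor_mask_fixed=tumor,
        true_tumor_mask_raw=tumor_raw,
        true_transform=true_t,
        control_points=cps,
        params=params,
    )


class _TissueLoss:
    """FFPE-style tissue loss: dark bites at the tissue edge plus a smooth
    local collapse of the surrounding tissue toward each bite.

    The collapse is what hurts the pipeline: it makes the sample's true
    deformation locally non-polynomial, so even exactly picked landmark
    pairs no longer follow a single degree-2 transform and the registration
    degrades near the lost region.
    """

    def __init__(self, centers: np.ndarray, r_patch: float, strength: float = 0.5):
        self.centers = np.atleast_2d(centers)
        self.r_patch = float(r_patch)
        self.strength = float(strength)

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        d = np.zeros_like(pts, dtype=float)
        for c in self.centers:
            delta = c - pts
            dist2 = np.sum(delta**2, axis=1, keepdims=True)
            d += self.strength * delta * np.exp(-dist2 / (2.0 * self.r_patch**2))
        return d

    def darken(self, raw_muse: np.ndarray, tissue_raw: np.ndarray) -> np.ndarray:
        out = raw_muse.copy()
        rr, cc = np.ogrid[: tissue_raw.shape[0], : tissue_raw.shape[1]]
        removed = np.zeros(tissue_raw.shape, dtype=bool)
        for cx, cy in self.centers:
            removed |= (rr - cy) ** 2 + (cc - cx) ** 2 <= self.r_patch**2
        out[removed & tissue_raw] = 0.02
        return out


def _draw_tissue_loss(tissue_raw, fraction, rng) -> _TissueLoss:
    """Place boundary-centered loss bites covering ~``fraction`` of the
    tissue area."""
    edge = boundary_of(tissue_raw)
    r_patch = max(6.0, 0.25 * np.sqrt(tissue_raw.sum()))
    target = fraction * tissue_raw.sum()
    rr, cc = np.ogrid[: tissue_raw.shape[0], : tissue_raw.shape[1]]
    removed = np.zeros(tissue_raw.shape, dtype=bool)
    centers = []
    guard = 0
    while removed.sum() < target and guard < 100:
        guard += 1
        cx, cy = edge[rng.integers(len(edge))]
        centers.append((cx, cy))
        removed |= ((rr - cy) ** 2 + (cc - cx) ** 2 <= r_patch**2) & tissue_raw
    return _TissueLoss(np.array(centers, dtype=float), r_patch)


def perturb_control_points(
    points: ControlPointSet, sigma: float, seed: int
) -> ControlPointSet:
    """Add i.i.d. zero-mean Gaussian displacement (px) to the moving points.

    Models the error of manual point picking; fixed points are untouched.
    ``sigma=0`` returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    if sigma == 0:
        return points
    rng = np.random.default_rng(seed)
    moving = points.moving + rng.normal(0.0, sigma, points.moving.shape)
    return ControlPointSet(points.fixed, moving, points.fixed_shape, points.moving_shape)
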