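"""Agreement metrics between semi-automated and manual annotations.

Three complementary measures: Dice overlap of the filled region masks
(global area agreement), symmetric Hausdorff distance between the annotation
boundaries normalized by the maximum image dimension (worst-case boundary
deviation), and cosine similarity of feature vectors from a pluggable image
descriptor (structural consistency).  Batch summaries report the
order statistics used in boxplots (min/max, quartiles, median, 1.5*IQR
outliers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Protocol, runtime_checkable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .imageutils import as_float_image, require_binary, to_grayscale

__all__ = [
    "dice",
    "hausdorff_normalized",
    "boundary_points",
    "feature_similarity",
    "FeatureExtractor",
    "HistogramDescriptor",
    "SimilarityReport",
    "evaluate_transfer",
    "summarize_batch",
]


def dice(i1: np.ndarray, i2: np.ndarray) -> float:
    """Dice score coefficient 2|I1 n I2| / (|I1| + |I2|).

    1 is perfect overlap, 0 none.  Two empty masks compare as 1.0 (nothing
    was annotated in either, which is agreement); one empty mask gives 0.0.
    """
    m1 = require_binary(i1)
    m2 = require_binary(i2)
    if m1.shape != m2.shape:
        raise ValueError(f"mask shapes differ: {m1.shape} vs {m2.shape}")
    total = int(m1.sum()) + int(m2.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((m1 & m2).sum()) / total


def hausdorff_normalized(
    o1: np.ndarray,
    o2: np.ndarray,
    shape: tuple[int, int],
    *,
    directed: bool = False,
) -> float:
    """Hausdorff distance between two boundary point sets, over image size.

    Points are (x, y) pixel coordinates.  The symmetric (undirected) form
    max{sup_a inf_b d(a,b), sup_b inf_a d(a,b)} is the default; pass
    ``directed=True`` for the one-sided sup-inf from ``o1`` to ``o2``.  The
    pixel-unit distance is divided by max(height, width) so samples of
    different sizes are comparable.
    """
    p1 = np.atleast_2d(np.asarray(o1, dtype=float))
    p2 = np.atleast_2d(np.asarray(o2, dtype=float))
    if p1.size == 0 or p2.size == 0:
        raise ValueError("Hausdorff distance is undefined for an empty outline")
    d12 = cKDTree(p2).query(p1)[0].max()
    if directed:
        h = d12
    else:
        d21 = cKDTree(p1).query(p2)[0].max()
        h = max(d12, d21)
    return float(h) / float(max(shape[0], shape[1]))


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """(x, y) coordinates of a mask's boundary pixels.

    Thin wrapper over :func:`musetransfer.transfer.boundary_of` placed here
    so metric callers need not import the transfer stage.
    """
    from .transfer import boundary_of

    return boundary_of(mask)


@runtime_checkable
class FeatureExtractor(Protocol):
    """Image -> fixed-length real feature vector, deterministic per image.

    Any callable satisfying this contract can drive the feature-similarity
    metric — including an adapter around a pretrained convolutional network,
    which is what is needed to approximate deep-feature similarity scores.
    """

    def __call__(self, img: np.ndarray) -> np.ndarray: ...


class HistogramDescriptor:
    """Built-in deterministic descriptor: coarse multiscale intensity
    histograms concatenated with gradient-orientation histograms.

    A dependency-free stand-in for a learned feature extractor: it captures
    coarse layout and texture, runs offline and is bit-reproducible.  It does
    not reproduce deep-network feature values; plug in a CNN adapter through
    the :class:`FeatureExtractor` contract for that.
    """

    def __init__(self, grid_sizes: tuple[int, ...] = (2, 4), n_bins: int = 8):
        self.grid_sizes = grid_sizes
        self.n_bins = n_bins

    def __call__(self, img: np.ndarray) -> np.ndarray:
        gray = to_grayscale(as_float_image(img))
        gy, gx = np.gradient(gray)
        mag = np.hypot(gx, gy)
        ori = np.arctan2(gy, gx)  # [-pi, pi]
        feats: list[np.ndarray] = []
        for g in self.grid_sizes:
            rows = np.array_split(np.arange(gray.shape[0]), g)
            cols = np.array_split(np.arange(gray.shape[1]), g)
            for r in rows:
                for c in cols:
                    cell = gray[np.ix_(r, c)]
                    hist, _ = np.histogram(cell, bins=self.n_bins, range=(0.0, 1.0))
                    feats.append(hist / max(cell.size, 1))
                    cell_ori = ori[np.ix_(r, c)].ravel()
                    cell_mag = mag[np.ix_(r, c)].ravel()
                    ohist, _ = np.histogram(
                        cell_ori, bins=self.n_bins, range=(-np.pi, np.pi), weights=cell_mag
                    )
                    feats.append(ohist / max(cell_mag.sum(), 1e-12))
        return np.concatenate(feats)


def feature_similarity(
    img1: np.ndarray,
    img2: np.ndarray,
    extractor: FeatureExtractor | None = None,
) -> float:
    """Cosine similarity between the two images' feature vectors."""
    extractor = extractor or HistogramDescriptor()
    v1 = np.asarray(extractor(img1), dtype=float).ravel()
    v2 = np.asarray(extractor(img2), dtype=float).ravel()
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError(
            f"feature extractor {type(extractor).__name__} returned a zero-norm vector"
        )
    return float(np.dot(v1, v2) / (n1 * n2))


@dataclass(frozen=True)
class SimilarityReport:
    """Three-metric evaluation of one semi-automated vs. manual pair."""

    dsc: float
    feature_similarity: float
    hausdorff_normalized: float
    extractor_id: str = "histogram-descriptor"
    sample_id: str = ""
    flags: tuple[str, ...] = field(default=())

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "dsc": self.dsc,
            "feature_similarity": self.feature_similarity,
            "hausdorff_normalized": self.hausdorff_normalized,
            "extractor_id": self.extractor_id,
            "flags": list(self.flags),
        }


def evaluate_transfer(
    semi_mask: np.ndarray,
    manual_mask: np.ndarray,
    semi_img: np.ndarray | None = None,
    manual_img: np.ndarray | None = None,
    extractor: FeatureExtractor | None = None,
    *,
    sample_id: str = "",
) -> SimilarityReport:
    """Score a semi-automated annotation against the manual gold standard.

    Dice is computed on the filled masks, Hausdorff on their boundaries.
    If no images are supplied the feature similarity is computed on the
    masks themselves.
    """
    m_semi = require_binary(semi_mask)
    m_manual = require_binary(manual_mask)
    if m_semi.shape != m_manual.shape:
        raise ValueError(f"mask shapes differ: {m_semi.shape} vs {m_manual.shape}")
    flags = []
    if not m_semi.any() or not m_manual.any():
        flags.append("empty_mask")

    dsc = dice(m_semi, m_manual)
    hd = hausdorff_normalized(
        boundary_points(m_semi), boundary_points(m_manual), m_semi.shape
    )
    extractor = extractor or HistogramDescriptor()
    if semi_img is None or manual_img is None:
        semi_img = m_semi.astype(float)
        manual_img = m_manual.astype(float)
    fs = feature_similarity(semi_img, manual_img, extractor)
    return SimilarityReport(
        dsc=dsc,
        feature_similarity=fs,
        hausdorff_normalized=hd,
        extractor_id=type(extractor).__name__,
        sample_id=sample_id,
        flags=tuple(flags),
    )


_METRIC_COLUMNS = ("dsc", "feature_similarity", "hausdorff_normalized")


def summarize_batch(reports: Iterable[SimilarityReport]) -> pd.DataFrame:
    """Boxplot-style order statistics per metric over a batch of reports.

    Columns: minimum, maximum, 25th/75th percentile (linear interpolation
    between order statistics), median, and the values falling outside
    median +/- 1.5*IQR whiskers (the usual boxplot outlier rule).
    """
    reports = list(reports)
    if not reports:
        raise ValueError("cannot summarize an empty batch")
    df = pd.DataFrame([r.to_dict() for r in reports])
    rows = {}
    for col in _METRIC_COLUMNS:
        vals = df[col].to_numpy(dtype=float)
        q25, q75 = np.percentile(vals, [25, 75])  # linear interpolation
        iqr = q75 - q25
        lo, hi = q25 - 1.5 * iqr, q75 + 1.5 * iqr
        outliers = sorted(float(v) for v in vals[(vals < lo) | (vals > hi)])
        rows[col] = {
            "minimum": float(vals.min()),
            "maximum": float(vals.max()),
            "p25": float(q25),
            "p75": float(q75),
            "median": float(np.median(vals)),
            "outliers": outliers,
        }
    return pd.DataFrame(rows).T[["minimum", "maximum", "p25", "p75", "median", "outliers"]]
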