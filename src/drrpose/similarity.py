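"""Contour-point similarity between edge maps of two images.

Edges are extracted with the Canny detector.  Every contour point of the
reference image is scored by the Euclidean distance ``d`` to its nearest
contour point in the floating image using a banded step function: 1 for an
exact hit, ``w1`` within the inner band ``0 < d <= a_band``, ``w2`` within
the outer band ``a_band < d <= b_band`` and 0 beyond.  The similarity is the
mean score over all reference contour points, so it lies in [0, 1] and
equals 1 only for a perfect contour overlap.  The measure is deliberately
asymmetric: the reference set defines which points are scored.

For the dual-view objective the frontal and lateral similarities are
combined linearly with weights ``wf > wl`` (the frontal view carries more
information and is weighted more heavily).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.feature import canny

from .drr import Image2D

__all__ = [
    "ContourPointSet",
    "SimilarityBands",
    "CompositeWeights",
    "SimilarityUndefinedError",
    "extract_contour_points",
    "match_score",
    "contour_similarity",
    "composite_similarity",
]


class SimilarityUndefinedError(ValueError):
    """Raised when the reference contour set is empty and no score exists."""


@dataclass(frozen=True)
class ContourPointSet:
    """Ordered (row, col) integer pixel coordinates of one image's contours."""

    points: np.ndarray
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=np.int64).reshape(-1, 2)
        shape = (int(self.image_shape[0]), int(self.image_shape[1]))
        if p.size:
            if p.min() < 0 or np.any(p >= np.array(shape)):
                raise ValueError("contour coordinates must lie within the image bounds")
            if len(np.unique(p, axis=0)) != len(p):
                raise ValueError("contour point set must not contain duplicates")
        p.setflags(write=False)
        object.__setattr__(self, "points", p)
        object.__setattr__(self, "image_shape", shape)

    @property
    def n(self) -> int:
        return len(self.points)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.points, fmt="%d", delimiter=",", header="row,col", comments="")


@dataclass(frozen=True)
class SimilarityBands:
    """Banded match-score parameters: radii in pixels, weights dimensionless."""

    a_band: float = 1.0
    b_band: float = 3.0
    w1: float = 0.8
    w2: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.a_band < self.b_band:
            raise ValueError(f"bands must satisfy 0 < a_band < b_band, got {self.a_band}, {self.b_band}")
        if not 1 >= self.w1 > self.w2 > 0:
            raise ValueError(f"weights must satisfy 1 >= w1 > w2 > 0, got {self.w1}, {self.w2}")


@dataclass(frozen=True)
class CompositeWeights:
    """Frontal/lateral mixing weights with wf > wl, each in (0, 1)."""

    wf: float = 0.6
    wl: float = 0.4

    def __post_init__(self) -> None:
        if not (0 < self.wl < self.wf < 1):
            raise ValueError(f"weights must satisfy 0 < wl < wf < 1, got wf={self.wf}, wl={self.wl}")
        if self.wf + self.wl > 1 + 1e-12:
            raise ValueError(f"wf + wl must not exceed 1, got {self.wf + self.wl}")


def extract_contour_points(
    image,
    sigma: float = 1.0,
    thresholds="auto",
) -> ContourPointSet:
    """Canny contour points of an image, in row-major scan order.

    ``thresholds`` is either ``"auto"`` (hysteresis thresholds at the 70th
    and 90th percentiles of the gradient magnitude) or an explicit
    ``(low, high)`` pair of absolute gradient thresholds.  A constant image
    yields an empty set.
    """
    pixels = image.pixels if isinstance(image, Image2D) else np.asarray(image, dtype=float)
    if pixels.ndim != 2 or min(pixels.shape) < 3:
        raise ValueError(f"image must be at least 3x3, got shape {pixels.shape}")
    if not np.all(np.isfinite(pixels)):
        raise ValueError("image must be finite")
    if pixels.max() == pixels.min():
        return ContourPointSet(points=np.empty((0, 2), dtype=np.int64), image_shape=pixels.shape)
    if thresholds == "auto":
        edges = canny(pixels, sigma=sigma, low_threshold=0.70, high_threshold=0.90, use_quantiles=True)
    else:
        low, high = thresholds
        edges = canny(pixels, sigma=sigma, low_threshold=low, high_threshold=high)
    return ContourPointSet(points=np.argwhere(edges), image_shape=pixels.shape)


def match_score(d, bands: SimilarityBands):
    """Banded score of a contour-point distance (pixels); vectorised over d."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    score = np.where(
        d == 0.0, 1.0, np.where(d <= bands.a_band, bands.w1, np.where(d <= bands.b_band, bands.w2, 0.0))
    )
    return float(score) if score.ndim == 0 else score


def contour_similarity(
    reference: ContourPointSet,
    floating: ContourPointSet,
    bands: SimilarityBands = SimilarityBands(),
) -> float:
    """Mean banded match score of reference contour points against floating ones.

    For each reference point the nearest floating point (Euclidean distance,
    ties resolved to the earlier point in row-major order) is scored; any
    floating point farther than ``b_band`` in every direction contributes 0,
    so searching beyond the b_band window is unnecessary.
    """
    if reference.image_shape != floating.image_shape:
        raise ValueError(
            f"contour sets come from different image shapes: {reference.image_shape} vs {floating.image_shape}"
        )
    if reference.n == 0:
        raise SimilarityUndefinedError("reference contour set is empty; similarity is undefined")
    if floating.n == 0:
        return 0.0
    tree = cKDTree(floating.points.astype(float))
    d, _ = tree.query(reference.points.astype(float), k=1)
    return float(np.mean(match_score(d, bands)))


def composite_similarity(sim_f: float, sim_l: float, weights: CompositeWeights = CompositeWeights()) -> float:
    """Weighted dual-view similarity ``wf * sim_f + wl * sim_l``."""
    for name, s in (("sim_f", sim_f), ("sim_l", sim_l)):
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {s}")
    return weights.wf * float(sim_f) + weights.wl * float(sim_l)
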