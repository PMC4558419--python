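"""Euclidean shape descriptors per dot and per image.

Roundness follows the diameters-ratio convention: the ratio of the major
to the minor axis of the second-moment-equivalent ellipse (1 for a circle,
larger for elongated shapes).  An alternative circularity formula
(perimeter^2 / 4*pi*area) is available behind the ``method`` switch.
Degenerate values (too-small objects, zero areas, flagged fractal
dimensions of exactly 1) are removed by :func:`filter_degenerate` before
any averaging — small unequivocally-stained silver grains never enter the
statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage import measure

from .groups import GroupLabel
from .segmentation import AgnorObject, BinaryMask
from .synthetic import RgbImage

__all__ = [
    "ImageMeasurement",
    "roundness",
    "object_area",
    "image_summary",
    "filter_degenerate",
]

_FD_DEGENERATE_TOL = 1e-6


@dataclass
class ImageMeasurement:
    """Per-image aggregate measurements.

    ``density`` is dots per mm^2 of calibrated image area;
    ``total_normalized_area`` is AgNOR-positive pixels over total pixels,
    scaled by 1e6 (a dimensionless parts-per-million fraction).  Means are
    over non-degenerate objects only and NaN when no object survives.
    """

    image_id: str
    group: GroupLabel | None
    dot_count: int
    mean_dots_per_nucleus: float
    density: float
    total_normalized_area: float
    mean_roundness: float
    mean_object_fd: float
    skeleton_fd: float
    image_kind: str = "single"
    raw_dot_count: int = 0  # components before the value filter


def roundness(obj_mask: np.ndarray, method: str = "axis_ratio") -> float:
    """Roundness of a single object mask; NaN when degenerate (< 5 px).

    ``axis_ratio`` (default): sqrt of the ratio of the eigenvalues of the
    pixel-coordinate covariance (major/minor axis of the equivalent
    ellipse, >= 1).  A per-pixel variance of 1/12 is added on the diagonal
    so 1-pixel-wide shapes stay finite.  ``circularity``:
    perimeter^2 / (4*pi*area), also >= 1, 1 for a disk.
    """
    m = np.asarray(obj_mask, dtype=bool)
    n = int(m.sum())
    if n < 5:
        return float("nan")
    if method == "axis_ratio":
        rows, cols = np.nonzero(m)
        r = rows - rows.mean()
        c = cols - cols.mean()
        cov = np.array(
            [
                [np.mean(r * r) + 1 / 12, np.mean(r * c)],
                [np.mean(r * c), np.mean(c * c) + 1 / 12],
            ]
        )
        lam2, lam1 = np.linalg.eigvalsh(cov)
        if lam2 <= 0:
            return float("nan")
        return float(math.sqrt(lam1 / lam2))
    if method == "circularity":
        perim = measure.perimeter_crofton(m, directions=4)
        if perim <= 0:
            return float("nan")
        return float(perim**2 / (4 * math.pi * n))
    raise ValueError(f"unknown roundness method {method!r}")


def object_area(pixel_area: int, pixel_size: float) -> tuple[int, float]:
    """(pixel area, calibrated area in um^2) for a pixel size in um/px."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    return int(pixel_area), float(pixel_area * pixel_size**2)


def filter_degenerate(objects: Sequence[AgnorObject]) -> list[AgnorObject]:
    """Drop objects with zero area, degenerate roundness, or FD flagged 1.

    Order is preserved; the filter is idempotent.  NaN fractal dimensions
    (not yet computed) are kept — only the explicit degenerate flag
    (exactly 1, within 1e-6) is excluded.
    """
    out = []
    for obj in objects:
        if obj.pixel_area <= 0:
            continue
        if not np.isfinite(obj.roundness) or obj.roundness == 0:
            continue
        if np.isfinite(obj.boundary_fd) and abs(obj.boundary_fd - 1.0) < _FD_DEGENERATE_TOL:
            continue
        out.append(obj)
    return out


def _nanmean(values: list[float]) -> float:
    finite = [v for v in values if np.isfinite(v)]
    return float(np.mean(finite)) if finite else float("nan")


def image_summary(
    objects: Sequence[AgnorObject],
    mask: BinaryMask,
    image: RgbImage,
    *,
    mean_dots_per_nucleus: float = float("nan"),
    skeleton_fd: float = float("nan"),
    group: GroupLabel | None = None,
    raw_dot_count: int | None = None,
) -> ImageMeasurement:
    """Aggregate surviving objects into one per-image record."""
    h, w = mask.pixels.shape
    fg = int(mask.pixels.sum())
    count = len(objects)
    return ImageMeasurement(
        image_id=image.image_id,
        group=group,
        dot_count=count,
        mean_dots_per_nucleus=float(mean_dots_per_nucleus),
        density=count / image.area_mm2,
        total_normalized_area=fg / (h * w) * 1e6,
        mean_roundness=_nanmean([o.roundness for o in objects]),
        mean_object_fd=_nanmean([o.boundary_fd for o in objects]),
        skeleton_fd=float(skeleton_fd),
        image_kind=image.kind,
        raw_dot_count=count if raw_dot_count is None else int(raw_dot_count),
    )
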