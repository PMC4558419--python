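"""Box-counting fractal dimension and skeleton filtering of binary masks.

The box-counting estimator overlays grids of decreasing box size on a
binary set, counts occupied boxes, and fits the slope of
``log(count)`` against ``log(1/size)`` by least squares.  For each size
the count is minimized over several grid offsets, which removes most of
the placement sensitivity of naive box counting.  Planar sets yield
dimensions between 0 (isolated points) and 2 (area-filling regions);
smooth curves sit near 1 and rugged silhouettes above it, which is what
makes the estimator a useful descriptor of nucleolar boundary complexity.

The skeleton filter reduces a dot map to its topology-preserving 1-px
medial lines and iteratively prunes spur branches, so the box-counting
dimension of the result reflects the spatial repartition of the dots
(glandular vs disorganized) rather than their individual areas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import morphology

from .segmentation import BinaryMask

__all__ = [
    "BoxCountResult",
    "SkeletonMap",
    "default_box_sizes",
    "box_count_fd",
    "object_boundary_fd",
    "skeletonize_prune",
    "skeleton_fd",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)

#: objects smaller than this cannot support a boundary-FD estimate
MIN_OBJECT_PX_FOR_FD = 8

#: degenerate flag: removed downstream by the value filter
FD_DEGENERATE = 1.0


@dataclass
class BoxCountResult:
    """Box sizes (decreasing), occupied counts, fitted slope and quality."""

    box_sizes: np.ndarray
    counts: np.ndarray
    fd: float
    r_squared: float

    @property
    def n_scales(self) -> int:
        return len(self.box_sizes)


@dataclass
class SkeletonMap:
    """Pruned 1-px skeleton of a dot map."""

    mask: np.ndarray
    prune_length_px: int
    component_count: int


def default_box_sizes(shape: tuple[int, int], min_size: int = 2) -> list[int]:
    """Powers of two from ``min_size`` up to ``min(shape) // 4``."""
    top = min(shape) // 4
    sizes = []
    s = int(min_size)
    while s <= top:
        sizes.append(s)
        s *= 2
    return sizes[::-1]  # decreasing


def box_count_fd(
    mask: BinaryMask | np.ndarray,
    sizes: Sequence[int] | None = None,
    offsets_per_size: int = 9,
) -> BoxCountResult:
    """Box-counting dimension of a non-empty binary mask.

    For each box size the occupied-box count is the minimum over up to
    ``offsets_per_size`` grid offsets drawn from a 3 x 3 third-of-box
    lattice; the dimension is the least-squares slope of log(count) vs
    log(1/size).  Raises on an empty mask or fewer than 3 usable sizes.
    """
    pixels = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    coords = np.nonzero(pixels)
    if coords[0].size == 0:
        raise ValueError("box_count_fd: empty mask has no fractal dimension")
    rows, cols = (c.astype(np.int64) for c in coords)
    if sizes is None:
        sizes = default_box_sizes(pixels.shape)
    sizes = sorted({int(s) for s in sizes if s >= 1}, reverse=True)
    if len(sizes) < 3:
        raise ValueError(f"box_count_fd needs >= 3 box sizes, got {sizes}")

    counts = []
    width = pixels.shape[1]
    for s in sizes:
        offs = [(i * s // 3, j * s // 3) for i in range(3) for j in range(3)][: max(offsets_per_size, 1)]
        best = None
        stride = width // s + 2
        for dr, dc in offs:
            keys = ((rows + dr) // s) * stride + (cols + dc) // s
            n = np.unique(keys).size
            best = n if best is None else min(best, n)
        counts.append(best)

    sizes_arr = np.array(sizes, dtype=float)
    counts_arr = np.array(counts, dtype=float)
    x = np.log(1.0 / sizes_arr)
    y = np.log(counts_arr)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return BoxCountResult(
        box_sizes=sizes_arr.astype(int), counts=counts_arr.astype(int), fd=float(slope), r_squared=r2
    )


def _geometric_sizes(max_size: int, ratio: float = 1.5) -> list[int]:
    """Roughly geometric integer box sizes from 2 up to ``max_size``."""
    sizes = []
    s = 2.0
    while int(round(s)) <= max_size:
        if not sizes or int(round(s)) != sizes[-1]:
            sizes.append(int(round(s)))
        s *= ratio
    return sizes


def object_boundary_fd(obj_mask: np.ndarray) -> float:
    """Silhouette (boundary) fractal dimension of a single object.

    The boundary is the object minus its 1-px erosion.  Objects too small
    to support at least 3 box scales return the degenerate flag 1.0, which
    the value filter removes downstream.  Small smooth dots measure close
    to 1; rugged boundaries measure higher.
    """
    m = np.asarray(obj_mask, dtype=bool)
    if int(m.sum()) < MIN_OBJECT_PX_FOR_FD:
        return FD_DEGENERATE
    m = np.pad(m, 1)
    boundary = m & ~ndimage.binary_erosion(m)
    sizes = _geometric_sizes(max(m.shape) // 2)
    if len(sizes) < 3:
        return FD_DEGENERATE
    res = box_count_fd(boundary, sizes=sizes)
    return res.fd


def skeletonize_prune(mask: BinaryMask | np.ndarray, prune_length_px: int = 5) -> SkeletonMap:
    """Topology-preserving thinning followed by iterative spur pruning.

    Each pruning iteration removes end-point pixels (exactly one
    8-neighbor); a component about to vanish keeps one pixel, so the
    connected-component count of the source mask is preserved.
    """
    if isinstance(mask, BinaryMask):
        if mask.provenance not in ("agnor", "reference"):
            raise ValueError(f"skeletonize_prune expects an agnor/reference mask, got {mask.provenance!r}")
        pixels = mask.pixels
    else:
        pixels = np.asarray(mask, dtype=bool)
    skel = morphology.skeletonize(pixels)
    kernel = np.ones((3, 3), dtype=np.uint8)
    for _ in range(max(prune_length_px, 0)):
        nb = ndimage.convolve(skel.astype(np.uint8), kernel, mode="constant") - skel
        endpoints = skel & (nb == 1)
        if not endpoints.any():
            break
        labelled, n = ndimage.label(skel, structure=_STRUCT8)
        sizes = np.bincount(labelled.ravel(), minlength=n + 1)
        removed = np.bincount(labelled[endpoints].ravel(), minlength=n + 1)
        # protect components that would be erased outright
        dying = np.flatnonzero((removed >= sizes[: len(removed)]) & (np.arange(len(removed)) > 0))
        keep = np.zeros_like(skel)
        for lab in dying:
            rr, cc = np.nonzero(labelled == lab)
            keep[rr[0], cc[0]] = True
        skel = skel & ~(endpoints & ~keep)
    _, n_comp = ndimage.label(skel, structure=_STRUCT8)
    return SkeletonMap(mask=skel, prune_length_px=prune_length_px, component_count=int(n_comp))


def skeleton_fd(
    dot_mask: BinaryMask | np.ndarray,
    prune_length_px: int = 5,
    sizes: Sequence[int] | None = None,
) -> float:
    """Box-counting dimension of the skeleton-filtered whole-image dot map.

    Raises on an empty mask; returns the degenerate flag 1.0 when the
    skeleton is too sparse (< 8 px) to support an estimate.
    """
    pixels = dot_mask.pixels if isinstance(dot_mask, BinaryMask) else np.asarray(dot_mask, dtype=bool)
    if not pixels.any():
        raise ValueError("skeleton_fd: empty dot mask")
    skel = skeletonize_prune(pixels, prune_length_px=prune_length_px)
    if int(skel.mask.sum()) < 8:
        return FD_DEGENERATE
    return box_count_fd(skel.mask, sizes=sizes).fd
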