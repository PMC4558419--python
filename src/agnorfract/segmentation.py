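"""Color/intensity segmentation of AgNOR dots from RGB brightfield images.

Silver-precipitated nucleolar organizer regions are the darkest structures
on the slide, so the core rule is a darkness threshold on mean RGB
intensity.  The green basal-cell chromogen can also be dark, hence an
explicit green-dominance exclusion; morphological opening and a minimum
object size remove sub-resolution silver grains.  All operators are
explicit and deterministic — a reproducible replacement for opaque
point-and-click segmentation commands in commercial packages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import morphology

from .synthetic import RgbImage

__all__ = [
    "SegmentationConfig",
    "BinaryMask",
    "AgnorObject",
    "segment_agnor",
    "label_objects",
    "count_per_nucleus",
    "assign_compartment",
]

#: 8-connected foreground structuring element
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationConfig:
    """Explicit segmentation rule set.

    ``darkness_threshold`` — maximum mean-RGB intensity of a dot pixel;
    ``green_margin`` — a pixel is excluded as basal chromogen when its
    green channel exceeds both red and blue by at least this margin;
    ``min_object_px`` — components below this size are dropped (silver
    grain filter); ``opening_radius_px`` — radius of an optional binary
    opening; foreground connectivity is fixed at 8 (background 4).
    """

    darkness_threshold: float = 80.0
    green_margin: float = 25.0
    min_object_px: int = 12
    opening_radius_px: int = 0

    def validate(self) -> list[str]:
        bad = []
        if not 0 <= self.darkness_threshold <= 255:
            bad.append("darkness_threshold must lie in [0, 255]")
        if not 0 <= self.green_margin <= 255:
            bad.append("green_margin must lie in [0, 255]")
        if self.min_object_px < 1:
            bad.append("min_object_px must be >= 1")
        if self.opening_radius_px < 0:
            bad.append("opening_radius_px must be >= 0")
        return bad


@dataclass
class BinaryMask:
    """Boolean mask with provenance (``agnor``, ``skeleton`` or ``reference``)."""

    pixels: np.ndarray
    provenance: str = "agnor"
    source_image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D mask, got shape {self.pixels.shape}")


@dataclass
class AgnorObject:
    """One segmented dot and its measurements.

    Geometry fields are filled by :func:`label_objects`; morphometric and
    fractal fields (``area_um2``, ``roundness``, ``boundary_fd``) by the
    morphometry/fractal layers.  ``roundness`` is NaN when degenerate;
    ``boundary_fd`` is flagged exactly 1.0 when degenerate, so the
    downstream value filter can drop both explicitly.
    """

    label: int
    pixel_area: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # (rmin, cmin, rmax, cmax), exclusive max
    mask: np.ndarray | None = field(default=None, repr=False)
    area_um2: float = float("nan")
    roundness: float = float("nan")
    boundary_fd: float = float("nan")
    compartment: str = "unknown"
    nucleus_id: int = 0


def segment_agnor(image: RgbImage, config: SegmentationConfig | None = None) -> BinaryMask:
    """Segment AgNOR dots into a binary mask.

    Foreground = pixels at or below the darkness threshold that are not
    green-dominant, followed by optional opening and small-object removal.
    """
    config = config or SegmentationConfig()
    bad = config.validate()
    if bad:
        raise ValueError("invalid SegmentationConfig: " + "; ".join(bad))
    px = image.pixels
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"expected an RGB image (H x W x 3), got shape {px.shape}")
    px = px.astype(np.float32)
    r, g, b = px[..., 0], px[..., 1], px[..., 2]
    dark = px.mean(axis=2) <= config.darkness_threshold
    greenish = (g >= r + config.green_margin) & (g >= b + config.green_margin)
    fg = dark & ~greenish
    if config.opening_radius_px > 0:
        fg = morphology.binary_opening(fg, morphology.disk(config.opening_radius_px))
    if config.min_object_px > 1:
        labelled, n = ndimage.label(fg, structure=_STRUCT8)
        if n:
            sizes = np.bincount(labelled.ravel())
            small = np.flatnonzero(sizes < config.min_object_px)
            fg = fg & ~np.isin(labelled, small[small > 0])
    return BinaryMask(pixels=fg, provenance="agnor", source_image_id=image.image_id)


def label_objects(mask: BinaryMask, config: SegmentationConfig | None = None) -> list[AgnorObject]:
    """8-connected labelling; labels in row-major order of first pixel."""
    if mask.provenance != "agnor":
        raise ValueError(f"label_objects expects an agnor mask, got {mask.provenance!r}")
    labelled, n = ndimage.label(mask.pixels, structure=_STRUCT8)
    if n == 0:
        return []
    slices = ndimage.find_objects(labelled)
    centroids = ndimage.center_of_mass(mask.pixels, labelled, range(1, n + 1))
    objects = []
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        crop = labelled[sl] == lab
        objects.append(
            AgnorObject(
                label=lab,
                pixel_area=int(crop.sum()),
                centroid=tuple(float(c) for c in centroids[lab - 1]),
                bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
                mask=crop,
            )
        )
    return objects


def count_per_nucleus(
    objects: Sequence[AgnorObject], nucleus_mask: np.ndarray
) -> tuple[dict[int, int], float]:
    """Assign each dot to the nucleus under its centroid and count.

    Returns a ``{nucleus_label: count}`` dict covering every nucleus in the
    mask (zero-dot nuclei included) and the mean count over all nuclei.
    Objects whose centroid lies on background get ``nucleus_id = 0`` and do
    not enter the mean.  Raises on geometry mismatch.
    """
    nucleus_mask = np.asarray(nucleus_mask)
    labels = [int(v) for v in np.unique(nucleus_mask) if v > 0]
    counts = {lab: 0 for lab in labels}
    for obj in objects:
        r, c = (int(round(x)) for x in obj.centroid)
        if not (0 <= r < nucleus_mask.shape[0] and 0 <= c < nucleus_mask.shape[1]):
            raise ValueError(
                f"object centroid {obj.centroid} outside nucleus mask of shape {nucleus_mask.shape}"
            )
        nid = int(nucleus_mask[r, c])
        obj.nucleus_id = nid
        if nid > 0:
            counts[nid] += 1
    mean = float(np.mean(list(counts.values()))) if counts else float("nan")
    return counts, mean


def assign_compartment(
    objects: Sequence[AgnorObject], epithelium_mask: np.ndarray | None
) -> list[AgnorObject]:
    """Tag each object epithelium/stroma from a compartment map.

    The map marks epithelium as True; anything else is stroma.  A missing
    map is an error — compartments are never guessed heuristically.
    """
    if epithelium_mask is None:
        raise ValueError("assign_compartment requires a compartment map (none provided)")
    epithelium_mask = np.asarray(epithelium_mask, dtype=bool)
    out = []
    for obj in objects:
        r, c = (int(round(x)) for x in obj.centroid)
        if not (0 <= r < epithelium_mask.shape[0] and 0 <= c < epithelium_mask.shape[1]):
            raise ValueError(
                f"object centroid {obj.centroid} outside compartment map of shape {epithelium_mask.shape}"
            )
        obj.compartment = "epithelium" if epithelium_mask[r, c] else "stroma"
        out.append(obj)
    return out
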