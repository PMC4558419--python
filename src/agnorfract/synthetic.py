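"""Synthetic silver-stained histology images with exact ground truth.

Real AgNOR slides combine three chromogens: silver-precipitated nucleolar
organizer regions appear as small near-black dots, a Nuclear Red
counterstain renders nuclei in desaturated red, and a green HRP substrate
marks the basal-cell layer that rims benign glands.  This module renders
that appearance model onto an RGB canvas from a parametric scene
description, so every generated image ships with a pixel-exact ground
truth (dot mask, labelled nucleus mask, per-object geometry table).

Dots are drawn as rotated ellipses whose radius is modulated by a radial
sinusoid, ``rho(phi) = 1 + a * sin(h * phi + phase)`` in the ellipse's
normalized frame; the amplitude ``a`` is the single knob controlling
boundary ruggedness (hence silhouette fractal dimension) and the axis
ratio controls roundness.  Nuclei sit either on a ring contour (glandular
architecture, with a green basal band for benign groups) or scattered
(disorganized, carcinoma-like architecture).

Everything is driven by one :class:`numpy.random.Generator` seeded from
``SyntheticSpec.seed``: identical spec + seed reproduces the image
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .groups import ALL_GROUPS, GroupLabel

__all__ = [
    "SyntheticSpec",
    "RgbImage",
    "GroundTruth",
    "PackingError",
    "generate_image",
    "generate_cohort",
    "cohort_labels",
    "make_reference_shape",
    "default_group_specs",
]

_BACKGROUND = np.array([242.0, 236.0, 232.0])

#: dot (silver), counterstain (nuclear red), basal chromogen (HRP green)
DEFAULT_STAIN_COLORS: tuple[tuple[int, int, int], ...] = (
    (32, 28, 26),
    (205, 95, 95),
    (52, 98, 46),
)

COMPOSITE_GRID = (4, 6)  # rows x cols of merged high-magnification fields


class PackingError(RuntimeError):
    """Raised when a scene cannot be packed without overlaps."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parametric description of one synthetic field.

    Parameters
    ----------
    dots_per_nucleus_mean:
        Poisson mean of AgNOR dots per nucleus (realized counts are
        recorded in the ground truth).
    nuclei_per_image:
        Number of epithelial nuclei rendered per single frame.
    dot_radius_px:
        Mean minor semi-axis of a dot, pixels.
    aspect_ratio_mean:
        Mean major/minor axis ratio of dots (>= 1; 1 = circular).
    ruggedness_amplitude:
        Relative radial boundary perturbation in [0, 0.5].
    ruggedness_harmonics:
        Angular frequency of the boundary perturbation (>= 2).
    arrangement:
        ``"glandular"`` places nuclei on ring contours (with a green basal
        band for benign groups); ``"disorganized"`` scatters them.
    stain_colors:
        RGB triples for (dot, counterstain, basal chromogen).
    noise_sd:
        Gaussian pixel noise, grey levels.
    seed:
        RNG seed; same spec + seed gives bit-identical output.
    group:
        Pathology label attached to the ground truth (and deciding
        whether a basal band is drawn around glands).
    """

    dots_per_nucleus_mean: float = 3.0
    nuclei_per_image: int = 10
    dot_radius_px: float = 4.0
    aspect_ratio_mean: float = 1.2
    ruggedness_amplitude: float = 0.15
    ruggedness_harmonics: int = 8
    arrangement: str = "glandular"
    stain_colors: tuple[tuple[int, int, int], ...] = DEFAULT_STAIN_COLORS
    noise_sd: float = 4.0
    seed: int = 0
    group: GroupLabel = GroupLabel.BNH
    image_size: tuple[int, int] = (512, 512)
    nucleus_radius_px: float = 22.0
    stromal_dots_mean: float = 0.5
    pixel_size_um: float = 0.17
    kind: str = "single"
    fixed_dot_count: bool = False

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        bad = []
        if self.dots_per_nucleus_mean < 0:
            bad.append("dots_per_nucleus_mean must be >= 0")
        if self.nuclei_per_image < 1:
            bad.append("nuclei_per_image must be a positive integer")
        if self.dot_radius_px <= 0:
            bad.append("dot_radius_px must be > 0")
        if self.aspect_ratio_mean < 1:
            bad.append("aspect_ratio_mean must be >= 1")
        if not 0 <= self.ruggedness_amplitude <= 0.5:
            bad.append("ruggedness_amplitude must lie in [0, 0.5]")
        if self.ruggedness_harmonics < 2:
            bad.append("ruggedness_harmonics must be an integer >= 2")
        if self.arrangement not in ("glandular", "disorganized"):
            bad.append(f"unknown arrangement {self.arrangement!r}")
        if self.noise_sd < 0:
            bad.append("noise_sd must be >= 0")
        if min(self.image_size) < 64:
            bad.append("image_size must be at least 64x64")
        if self.pixel_size_um <= 0:
            bad.append("pixel_size_um must be > 0")
        if self.kind not in ("single", "composite"):
            bad.append(f"unknown kind {self.kind!r}")
        if len(self.stain_colors) != 3:
            bad.append("stain_colors must hold three RGB triples")
        return bad


@dataclass
class RgbImage:
    """Calibrated H x W x 3 color image."""

    pixels: np.ndarray  # uint8, H x W x 3
    pixel_size: float  # micrometres per pixel
    kind: str = "single"
    image_id: str = ""

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 pixels, got shape {self.pixels.shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def area_mm2(self) -> float:
        h, w = self.shape
        return h * w * self.pixel_size**2 / 1e6


#: columns of the ground-truth object table
OBJECT_TABLE_COLUMNS = (
    "object_id",
    "row",
    "col",
    "pixel_area",
    "true_aspect_ratio",
    "true_ruggedness_amplitude",
    "nucleus_id",
    "compartment",
)


@dataclass
class GroundTruth:
    """Exact scene description for one rendered image.

    ``object_table`` has one row per rendered dot
    (columns :data:`OBJECT_TABLE_COLUMNS`); ``nucleus_mask`` is a labelled
    integer mask (0 = background), ``dot_mask`` a boolean mask whose
    8-connected components correspond one-to-one to table rows.
    ``epithelium_mask`` marks the epithelial compartment (glandular
    epithelium including nuclei); everything else is stroma.
    """

    object_table: pd.DataFrame
    nucleus_mask: np.ndarray
    dot_mask: np.ndarray
    group: GroupLabel
    epithelium_mask: np.ndarray


# ---------------------------------------------------------------------------
# rasterization primitives


def _rugged_ellipse_patch(
    a: float, b: float, amplitude: float, harmonics: int, phase: float, angle: float
) -> np.ndarray:
    """Boolean patch of an ellipse with sinusoidal radial perturbation.

    The boundary in the normalized elliptical frame is
    ``rho = 1 + amplitude * sin(harmonics * phi + phase)``; the patch is
    rotated by ``angle`` and centered.
    """
    rmax = max(a, b) * (1.0 + amplitude) + 1.5
    n = int(np.ceil(rmax))
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1].astype(float)
    c, s = np.cos(angle), np.sin(angle)
    u = c * xx + s * yy
    v = -s * xx + c * yy
    rho = np.hypot(u / a, v / b)
    phi = np.arctan2(v / b, u / a)
    return rho <= 1.0 + amplitude * np.sin(harmonics * phi + phase)


def _disk_patch(radius: float) -> np.ndarray:
    n = int(np.ceil(radius))
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1].astype(float)
    return xx**2 + yy**2 <= radius**2


def _paste(target: np.ndarray, patch: np.ndarray, center: tuple[int, int], value) -> None:
    """Write ``value`` into ``target`` wherever ``patch`` is set, clipped."""
    n = patch.shape[0] // 2
    r0, c0 = center
    h, w = target.shape[:2]
    rlo, rhi = max(r0 - n, 0), min(r0 + n + 1, h)
    clo, chi = max(c0 - n, 0), min(c0 + n + 1, w)
    p = patch[rlo - (r0 - n) : rlo - (r0 - n) + (rhi - rlo), clo - (c0 - n) : clo - (c0 - n) + (chi - clo)]
    target[rlo:rhi, clo:chi][p] = value


# ---------------------------------------------------------------------------
# scene layout


def _place_nuclei(spec: SyntheticSpec, rng: np.random.Generator):
    """Return (centers, radii, gland_centers_and_ring_radii)."""
    h, w = spec.image_size
    rn = spec.nucleus_radius_px
    min_sep = 2.3 * rn
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    glands: list[tuple[float, float, float]] = []

    if spec.arrangement == "glandular":
        band = 6.0
        margin = rn + band + 4.0
        ring_r = min(h, w) / 2.0 - margin
        cy, cx = h / 2.0, w / 2.0
        remaining = spec.nuclei_per_image
        r = ring_r
        while remaining > 0:
            if r < 1.5 * rn:
                raise PackingError(
                    f"cannot place {spec.nuclei_per_image} nuclei of radius {rn:.1f} "
                    f"on ring contours inside a {h}x{w} frame"
                )
            capacity = max(int(2 * np.pi * r / min_sep), 1)
            k = min(capacity, remaining)
            glands.append((cy, cx, r))
            phase = rng.uniform(0, 2 * np.pi)
            for j in range(k):
                ang = phase + 2 * np.pi * j / k + rng.normal(0, 0.25 / k)
                rr = r + rng.normal(0, 0.06 * rn)
                centers.append((cy + rr * np.sin(ang), cx + rr * np.cos(ang)))
                radii.append(rn * rng.uniform(0.9, 1.1))
            remaining -= k
            r -= 2.8 * rn
    else:
        margin = rn + 3.0
        attempts = 0
        limit = 600 * spec.nuclei_per_image
        while len(centers) < spec.nuclei_per_image:
            attempts += 1
            if attempts > limit:
                raise PackingError(
                    f"cannot pack {spec.nuclei_per_image} non-overlapping nuclei of "
                    f"radius {rn:.1f} into a {h}x{w} frame"
                )
            cand = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
            if all((cand[0] - y) ** 2 + (cand[1] - x) ** 2 >= min_sep**2 for y, x in centers):
                centers.append(cand)
                radii.append(rn * rng.uniform(0.9, 1.1))
    return centers, radii, glands


def _place_dots_in_disk(
    rng: np.random.Generator,
    center: tuple[float, float],
    placement_radius: float,
    n_wanted: int,
    reff: float,
    occupied: list[tuple[float, float, float]],
    attempts_per_dot: int = 60,
    restarts: int = 8,
) -> list[tuple[float, float]]:
    """Rejection-sample up to ``n_wanted`` non-touching dot centers.

    The whole placement is restarted when it stalls; the best (longest)
    attempt is committed.  A nucleus that genuinely cannot hold all drawn
    dots keeps its realized count — ground truth records what is rendered.
    """
    if n_wanted <= 0:
        return []
    min_d2 = (2 * reff + 2.0) ** 2
    occ = np.array([(y, x) for y, x, _ in occupied], dtype=float).reshape(-1, 2)
    occ_d2 = np.array([(reff + r + 2.0) ** 2 for _, _, r in occupied], dtype=float)
    best: list[tuple[float, float]] = []
    for _ in range(max(restarts, 1)):
        m = attempts_per_dot * n_wanted
        ang = rng.uniform(0, 2 * np.pi, size=m)
        rad = placement_radius * np.sqrt(rng.uniform(size=m))
        cand = np.column_stack([center[0] + rad * np.sin(ang), center[1] + rad * np.cos(ang)])
        if len(occ):
            d2 = ((cand[:, None, :] - occ[None, :, :]) ** 2).sum(-1)
            cand = cand[(d2 >= occ_d2[None, :]).all(axis=1)]
        out: list[tuple[float, float]] = []
        while len(cand) and len(out) < n_wanted:
            p = cand[0]  # random greedy: batch order is random
            out.append((float(p[0]), float(p[1])))
            d2 = (cand[:, 0] - p[0]) ** 2 + (cand[:, 1] - p[1]) ** 2
            cand = cand[d2 >= min_d2]
        if len(out) > len(best):
            best = out
        if len(best) == n_wanted:
            break
    occupied.extend((y, x, reff) for y, x in best)
    return best


# ---------------------------------------------------------------------------
# generation


def generate_image(spec: SyntheticSpec) -> tuple[RgbImage, GroundTruth]:
    """Render one synthetic field and its exact ground truth.

    Raises
    ------
    ValueError
        If the spec violates its invariants.
    PackingError
        If the requested nuclei cannot be placed without overlap.
    """
    bad = spec.validate()
    if bad:
        raise ValueError("invalid SyntheticSpec: " + "; ".join(bad))
    if spec.kind == "composite":
        return _generate_composite(spec)
    return _generate_single(spec)


def _generate_single(spec: SyntheticSpec) -> tuple[RgbImage, GroundTruth]:
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    dot_rgb, nuc_rgb, band_rgb = (np.array(c, float) for c in spec.stain_colors)

    canvas = np.empty((h, w, 3), dtype=float)
    canvas[:] = _BACKGROUND
    canvas += rng.normal(0, 1.5, size=(h, w, 1))  # faint background texture

    nucleus_mask = np.zeros((h, w), dtype=np.int32)
    dot_mask = np.zeros((h, w), dtype=bool)
    epithelium = np.zeros((h, w), dtype=bool)

    centers, radii, glands = _place_nuclei(spec, rng)

    # basal-cell band: green annulus rimming each gland of benign lesions
    if spec.arrangement == "glandular" and not spec.group.carcinoma:
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        for cy, cx, ring_r in glands:
            d = np.hypot(yy - cy, xx - cx)
            rn = spec.nucleus_radius_px
            band = (d >= ring_r + rn * 1.15) & (d <= ring_r + rn * 1.15 + 5.0)
            canvas[band] = band_rgb + rng.normal(0, 3, size=3)

    for i, ((cy, cx), rad) in enumerate(zip(centers, radii), start=1):
        patch = _disk_patch(rad)
        shade = nuc_rgb + rng.normal(0, 6, size=3)
        _paste(canvas, patch, (int(round(cy)), int(round(cx))), shade)
        _paste(nucleus_mask, patch, (int(round(cy)), int(round(cx))), i)
        _paste(epithelium, _disk_patch(rad + 3.0), (int(round(cy)), int(round(cx))), True)

    # dots: inside nuclei (epithelial) plus optional stromal scatter
    records: list[dict] = []
    occupied: list[tuple[float, float, float]] = []
    next_id = 1

    def _draw_dot(center: tuple[float, float], nucleus_id: int) -> None:
        nonlocal next_id
        ar = max(1.0, rng.normal(spec.aspect_ratio_mean, 0.05 + 0.15 * (spec.aspect_ratio_mean - 1)))
        b = spec.dot_radius_px * rng.uniform(0.85, 1.15)
        a = ar * b
        amp = float(np.clip(rng.normal(spec.ruggedness_amplitude, 0.08 * spec.ruggedness_amplitude), 0.0, 0.5))
        patch = _rugged_ellipse_patch(a, b, amp, spec.ruggedness_harmonics, rng.uniform(0, 2 * np.pi), rng.uniform(0, np.pi))
        rc = (int(round(center[0])), int(round(center[1])))
        _paste(canvas, patch, rc, dot_rgb + rng.normal(0, 2, size=3))
        _paste(dot_mask, patch, rc, True)
        records.append(
            dict(
                object_id=next_id,
                row=center[0],
                col=center[1],
                pixel_area=int(patch.sum()),
                true_aspect_ratio=ar,
                true_ruggedness_amplitude=amp,
                nucleus_id=nucleus_id,
                compartment="epithelium" if nucleus_id > 0 else "stroma",
            )
        )
        next_id += 1

    reff = spec.aspect_ratio_mean * spec.dot_radius_px * 1.15 * (1 + spec.ruggedness_amplitude)
    for i, ((cy, cx), rad) in enumerate(zip(centers, radii), start=1):
        if spec.fixed_dot_count:
            k = int(round(spec.dots_per_nucleus_mean))
        else:
            k = int(rng.poisson(spec.dots_per_nucleus_mean))
        placement = max(rad - reff - 1.0, 1.0)
        for center in _place_dots_in_disk(rng, (cy, cx), placement, k, reff, occupied):
            _draw_dot(center, i)

    if spec.stromal_dots_mean > 0:
        k = int(rng.poisson(spec.stromal_dots_mean))
        margin = reff + 3.0
        for _ in range(k):
            for _ in range(200):
                cand = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
                far_from_nuclei = all(
                    np.hypot(cand[0] - cy, cand[1] - cx) >= rad + reff + 4.0
                    for (cy, cx), rad in zip(centers, radii)
                )
                far_from_dots = all(
                    (cand[0] - y) ** 2 + (cand[1] - x) ** 2 >= (2 * reff + 2.0) ** 2
                    for y, x, r in occupied
                )
                outside_epithelium = not epithelium[int(round(cand[0])), int(round(cand[1]))]
                if far_from_nuclei and far_from_dots and outside_epithelium:
                    occupied.append((cand[0], cand[1], reff))
                    _draw_dot(cand, 0)
                    break

    if spec.noise_sd > 0:
        canvas += rng.normal(0, spec.noise_sd, size=canvas.shape)
    pixels = np.clip(canvas, 0, 255).round().astype(np.uint8)

    table = pd.DataFrame(records, columns=list(OBJECT_TABLE_COLUMNS))
    image_id = f"{spec.group}_s{spec.seed}"
    image = RgbImage(pixels=pixels, pixel_size=spec.pixel_size_um, kind="single", image_id=image_id)
    gt = GroundTruth(
        object_table=table,
        nucleus_mask=nucleus_mask,
        dot_mask=dot_mask,
        group=spec.group,
        epithelium_mask=epithelium,
    )
    return image, gt


def _generate_composite(spec: SyntheticSpec) -> tuple[RgbImage, GroundTruth]:
    """Grid-concatenate tiles into one merged capture (no stitching seams)."""
    rows, cols = COMPOSITE_GRID
    ss = np.random.SeedSequence(spec.seed)
    tile_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(rows * cols)]
    tiles = []
    for ts in tile_seeds:
        tiles.append(_generate_single(dataclasses.replace(spec, kind="single", seed=ts)))

    th, tw = spec.image_size
    h, w = rows * th, cols * tw
    pixels = np.zeros((h, w, 3), dtype=np.uint8)
    nucleus_mask = np.zeros((h, w), dtype=np.int32)
    dot_mask = np.zeros((h, w), dtype=bool)
    epithelium = np.zeros((h, w), dtype=bool)
    tables = []
    obj_off = 0
    nuc_off = 0
    for idx, (img, gt) in enumerate(tiles):
        r, c = divmod(idx, cols)
        sl = (slice(r * th, (r + 1) * th), slice(c * tw, (c + 1) * tw))
        pixels[sl] = img.pixels
        nm = gt.nucleus_mask.copy()
        nm[nm > 0] += nuc_off
        nucleus_mask[sl] = nm
        dot_mask[sl] = gt.dot_mask
        epithelium[sl] = gt.epithelium_mask
        t = gt.object_table.copy()
        t["object_id"] += obj_off
        t["row"] += r * th
        t["col"] += c * tw
        t.loc[t["nucleus_id"] > 0, "nucleus_id"] += nuc_off
        tables.append(t)
        obj_off += len(t)
        nuc_off += int(gt.nucleus_mask.max())

    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(columns=list(OBJECT_TABLE_COLUMNS))
    image_id = f"{spec.group}_s{spec.seed}_composite"
    image = RgbImage(pixels=pixels, pixel_size=spec.pixel_size_um, kind="composite", image_id=image_id)
    gt = GroundTruth(
        object_table=table,
        nucleus_mask=nucleus_mask,
        dot_mask=dot_mask,
        group=spec.group,
        epithelium_mask=epithelium,
    )
    return image, gt


def generate_cohort(
    specs_by_group: Mapping[GroupLabel, SyntheticSpec],
    images_per_group: int,
    seed: int,
) -> list[tuple[RgbImage, GroundTruth]]:
    """Generate ``6 x images_per_group`` images with per-image derived seeds.

    Group order is the canonical one (BNH, AAH, G2..G5); per-image seeds
    are spawned deterministically from ``seed``.
    """
    if images_per_group < 1:
        raise ValueError("images_per_group must be >= 1")
    missing = [g.value for g in ALL_GROUPS if g not in specs_by_group]
    if missing:
        raise ValueError(f"specs_by_group is missing groups: {', '.join(missing)}")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(ALL_GROUPS) * images_per_group)
    cohort = []
    idx = 0
    for group in ALL_GROUPS:
        base = specs_by_group[group]
        for j in range(images_per_group):
            child_seed = int(children[idx].generate_state(1)[0] % (2**31))
            idx += 1
            sp = dataclasses.replace(base, seed=child_seed, group=group)
            img, gt = generate_image(sp)
            img.image_id = f"{group}_{j:03d}"
            cohort.append((img, gt))
    return cohort


def cohort_labels(
    cohort: Sequence[tuple[RgbImage, GroundTruth]], images_per_patient: int = 5
) -> pd.DataFrame:
    """Build an image -> (patient, group) labels table for a cohort.

    Synthetic images are grouped into pseudo-patients of
    ``images_per_patient`` consecutive images within each group, mimicking
    several captures per biopsy.
    """
    rows = []
    counters: dict[str, int] = {}
    for img, gt in cohort:
        g = str(gt.group)
        k = counters.get(g, 0)
        counters[g] = k + 1
        rows.append(
            dict(
                image_id=img.image_id,
                patient_id=f"{g}_p{k // images_per_patient:02d}",
                group=g,
                image_kind=img.kind,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reference shapes (estimator calibration fixtures)


def make_reference_shape(kind: str, **params) -> np.ndarray:
    """Rasterize an analytic binary shape for estimator calibration.

    Supported kinds: ``line``, ``disk``, ``ellipse``, ``filled_square``,
    ``sierpinski``, ``rugged_blob``.
    """
    if kind == "line":
        length = int(params.get("length", 512))
        side = int(params.get("side", length))
        mask = np.zeros((side, side), dtype=bool)
        mask[side // 2, :length] = True
        return mask
    if kind == "disk":
        radius = float(params["radius"])
        side = int(params.get("side", int(2 * radius) + 16))
        yy, xx = np.mgrid[0:side, 0:side].astype(float)
        c = (side - 1) / 2.0
        return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
    if kind == "ellipse":
        a = float(params["semi_major"])
        b = float(params["semi_minor"])
        angle = float(params.get("angle", 0.0))
        side = int(params.get("side", int(2 * a) + 16))
        yy, xx = np.mgrid[0:side, 0:side].astype(float)
        c = (side - 1) / 2.0
        u = np.cos(angle) * (xx - c) + np.sin(angle) * (yy - c)
        v = -np.sin(angle) * (xx - c) + np.cos(angle) * (yy - c)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if kind == "filled_square":
        side = int(params.get("side", 512))
        return np.ones((side, side), dtype=bool)
    if kind == "sierpinski":
        order = int(params.get("order", 7))
        side = int(params.get("side", 512))
        base = 2**order
        if side % base:
            raise ValueError(f"side {side} must be a multiple of 2**order = {base}")
        i, j = np.mgrid[0:base, 0:base]
        cells = (i & j) == 0  # exactly 3**order occupied cells
        factor = side // base
        return np.kron(cells, np.ones((factor, factor), dtype=bool))
    if kind == "rugged_blob":
        radius = float(params["radius"])
        amplitude = float(params.get("amplitude", 0.2))
        harmonics = int(params.get("harmonics", 8))
        phase = float(params.get("phase", 0.0))
        side = int(params.get("side", int(2 * radius * (1 + amplitude)) + 16))
        yy, xx = np.mgrid[0:side, 0:side].astype(float)
        c = (side - 1) / 2.0
        r = np.hypot(yy - c, xx - c)
        theta = np.arctan2(yy - c, xx - c)
        return r <= radius * (1.0 + amplitude * np.sin(harmonics * theta + phase))
    raise ValueError(f"unknown reference shape kind {kind!r}")


# ---------------------------------------------------------------------------
# cohort design defaults


def default_group_specs(**overrides) -> dict[GroupLabel, SyntheticSpec]:
    """Study-condition defaults for the six groups.

    The design encodes the qualitative biology the groups are meant to
    differ in: carcinoma dots are more elongated (higher axis ratio) with
    smoother boundaries (lower ruggedness) and sit in progressively
    disorganized architecture; benign groups keep rounder, more rugged
    dots in glandular rings with a basal band.  ``overrides`` are applied
    to every group's spec (e.g. ``image_size=(160, 160)``).
    """
    design = {
        GroupLabel.BNH: dict(dots_per_nucleus_mean=2.4, aspect_ratio_mean=1.10, ruggedness_amplitude=0.30, arrangement="glandular"),
        GroupLabel.AAH: dict(dots_per_nucleus_mean=2.2, aspect_ratio_mean=1.15, ruggedness_amplitude=0.26, arrangement="glandular"),
        GroupLabel.G2: dict(dots_per_nucleus_mean=2.8, aspect_ratio_mean=1.45, ruggedness_amplitude=0.12, arrangement="glandular"),
        GroupLabel.G3: dict(dots_per_nucleus_mean=3.0, aspect_ratio_mean=1.50, ruggedness_amplitude=0.10, arrangement="disorganized"),
        GroupLabel.G4: dict(dots_per_nucleus_mean=3.4, aspect_ratio_mean=1.55, ruggedness_amplitude=0.08, arrangement="disorganized"),
        GroupLabel.G5: dict(dots_per_nucleus_mean=3.6, aspect_ratio_mean=1.60, ruggedness_amplitude=0.06, arrangement="disorganized"),
    }
    return {
        g: SyntheticSpec(group=g, **kw, **overrides) for g, kw in design.items()
    }


# ---------------------------------------------------------------------------
# on-disk representation


def save_ground_truth(gt: GroundTruth, image: RgbImage, spec: SyntheticSpec, out_dir: str | Path) -> None:
    """Write object table (CSV), masks (16-bit PNG), and a JSON sidecar."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = image.image_id
    gt.object_table.to_csv(out / f"{stem}_objects.csv", index=False)
    iio.imwrite(out / f"{stem}_nuclei.png", gt.nucleus_mask.astype(np.uint16))
    iio.imwrite(out / f"{stem}_dots.png", (gt.dot_mask.astype(np.uint8) * 255))
    iio.imwrite(out / f"{stem}_epithelium.png", (gt.epithelium_mask.astype(np.uint8) * 255))
    sidecar = dataclasses.asdict(spec)
    sidecar["group"] = str(spec.group)
    (out / f"{stem}_spec.json").write_text(json.dumps(sidecar, indent=2))
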