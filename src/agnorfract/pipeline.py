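"""End-to-end measurement: image -> mask -> objects -> per-image record -> stats.

`measure_image` composes the segmentation, morphometry, and fractal layers
for one image; `measure_cohort` maps it over a synthetic cohort and
returns tidy object- and image-level DataFrames; `run_statistics` runs the
group comparisons the image-level table supports.  The heavier stages
(per-object boundary FD, whole-image skeleton FD) can be switched off for
experiments that do not need them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import fractal, morphometry, stats
from .groups import GroupLabel
from .morphometry import ImageMeasurement
from .segmentation import (
    AgnorObject,
    SegmentationConfig,
    assign_compartment,
    count_per_nucleus,
    label_objects,
    segment_agnor,
)
from .synthetic import GroundTruth, RgbImage

__all__ = [
    "MeasureOptions",
    "measure_image",
    "measure_cohort",
    "run_statistics",
    "IMAGE_METRICS",
]

#: image-level metrics carried into the statistics layer
IMAGE_METRICS = (
    "dot_count",
    "mean_dots_per_nucleus",
    "density",
    "total_normalized_area",
    "mean_roundness",
    "mean_object_fd",
    "skeleton_fd",
)


@dataclass(frozen=True)
class MeasureOptions:
    """Per-image measurement switches."""

    compute_object_fd: bool = True
    compute_skeleton_fd: bool = True
    roundness_method: str = "axis_ratio"
    prune_length_px: int = 5


def measure_image(
    image: RgbImage,
    *,
    nucleus_mask: np.ndarray | None = None,
    epithelium_mask: np.ndarray | None = None,
    seg_config: SegmentationConfig | None = None,
    options: MeasureOptions | None = None,
    group: GroupLabel | None = None,
) -> tuple[ImageMeasurement, list[AgnorObject]]:
    """Segment and measure one RGB image.

    Returns the per-image aggregate and the surviving (value-filtered)
    object list.  Per-nucleus counts and compartment tags are computed
    only when the corresponding masks are supplied.
    """
    options = options or MeasureOptions()
    mask = segment_agnor(image, seg_config)
    objects = label_objects(mask)
    for obj in objects:
        obj.roundness = morphometry.roundness(obj.mask, method=options.roundness_method)
        _, obj.area_um2 = morphometry.object_area(obj.pixel_area, image.pixel_size)
        if options.compute_object_fd:
            obj.boundary_fd = fractal.object_boundary_fd(obj.mask)

    mean_dpn = float("nan")
    if nucleus_mask is not None:
        _, mean_dpn = count_per_nucleus(objects, nucleus_mask)
    if epithelium_mask is not None:
        objects = assign_compartment(objects, epithelium_mask)

    surviving = morphometry.filter_degenerate(objects)

    skel_fd = float("nan")
    if options.compute_skeleton_fd and mask.pixels.any():
        skel_fd = fractal.skeleton_fd(mask, prune_length_px=options.prune_length_px)

    meas = morphometry.image_summary(
        surviving,
        mask,
        image,
        mean_dots_per_nucleus=mean_dpn,
        skeleton_fd=skel_fd,
        group=group,
        raw_dot_count=len(objects),
    )
    return meas, surviving


def measure_cohort(
    cohort: Sequence[tuple[RgbImage, GroundTruth]],
    *,
    seg_config: SegmentationConfig | None = None,
    options: MeasureOptions | None = None,
    labels: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Measure every image of a cohort.

    Returns ``(image_df, object_df)``: one row per image with the
    :data:`IMAGE_METRICS` columns, and one row per surviving object.
    ``labels`` (image_id -> patient_id) attaches patient identifiers when
    given; otherwise each image is its own pseudo-patient.
    """
    image_rows, object_rows = [], []
    patient_of = {}
    if labels is not None:
        patient_of = dict(zip(labels["image_id"], labels["patient_id"]))
    for img, gt in cohort:
        meas, objects = measure_image(
            img,
            nucleus_mask=gt.nucleus_mask,
            epithelium_mask=gt.epithelium_mask,
            seg_config=seg_config,
            options=options,
            group=gt.group,
        )
        pid = patient_of.get(img.image_id, img.image_id)
        row = dict(
            image_id=meas.image_id,
            patient_id=pid,
            group=str(gt.group),
            image_kind=img.kind,
            raw_dot_count=meas.raw_dot_count,
        )
        for m in IMAGE_METRICS:
            row[m] = getattr(meas, m)
        image_rows.append(row)
        for obj in objects:
            object_rows.append(
                dict(
                    image_id=img.image_id,
                    patient_id=pid,
                    group=str(gt.group),
                    label=obj.label,
                    pixel_area=obj.pixel_area,
                    area_um2=obj.area_um2,
                    roundness=obj.roundness,
                    boundary_fd=obj.boundary_fd,
                    centroid_row=obj.centroid[0],
                    centroid_col=obj.centroid[1],
                    compartment=obj.compartment,
                    nucleus_id=obj.nucleus_id,
                )
            )
    image_df = pd.DataFrame(image_rows)
    object_df = pd.DataFrame(
        object_rows,
        columns=[
            "image_id",
            "patient_id",
            "group",
            "label",
            "pixel_area",
            "area_um2",
            "roundness",
            "boundary_fd",
            "centroid_row",
            "centroid_col",
            "compartment",
            "nucleus_id",
        ],
    )
    return image_df, object_df


def image_df_to_long(image_df: pd.DataFrame, metrics: Sequence[str] = IMAGE_METRICS) -> pd.DataFrame:
    """Melt the wide image table into the long cohort-table format."""
    id_cols = [c for c in ("patient_id", "image_id", "image_kind", "group") if c in image_df.columns]
    long = image_df.melt(id_vars=id_cols, value_vars=list(metrics), var_name="metric", value_name="value")
    return long.dropna(subset=["value"]).reset_index(drop=True)


def _values_by_group(image_df: pd.DataFrame, metric: str, pooled: bool) -> dict[str, np.ndarray]:
    out: dict[str, list[float]] = {}
    for _, row in image_df.iterrows():
        v = row[metric]
        if not np.isfinite(v):
            continue
        g = row["group"]
        if pooled:
            g = "carcinoma" if GroupLabel(g).carcinoma else g
        out.setdefault(g, []).append(float(v))
    return {k: np.asarray(v) for k, v in out.items()}


def run_statistics(
    image_df: pd.DataFrame,
    metrics: Sequence[str] = IMAGE_METRICS,
    alpha: float = 0.05,
    narrow: tuple[float, float] = stats.NARROW_INTERVAL,
) -> dict:
    """Six-group and pooled-carcinoma ANOVA/Tukey for each metric.

    Also runs the narrowed-interval frequency analysis on per-image mean
    object FDs.  Returns a JSON-serializable report dict.
    """
    report: dict = {"alpha": alpha, "metrics": {}}
    for metric in metrics:
        entry: dict = {}
        for pooled, key in ((False, "six_group"), (True, "pooled_carcinoma")):
            groups = _values_by_group(image_df, metric, pooled)
            groups = {k: v for k, v in groups.items() if len(v) >= 2}
            if len(groups) < 2:
                entry[key] = None
                continue
            anova = stats.one_way_anova(groups)
            tukey = stats.tukey_hsd(groups, alpha=alpha)
            entry[key] = {
                "group_means": {k: float(np.mean(v)) for k, v in groups.items()},
                "anova": vars(anova),
                "tukey": tukey.to_dict(orient="records"),
            }
        report["metrics"][metric] = entry

    fd_groups = _values_by_group(image_df, "mean_object_fd", pooled=False)
    fd_groups = {k: v for k, v in fd_groups.items() if len(v) >= 2}
    if len(fd_groups) >= 2:
        hists, full, narrowed = stats.fd_frequency_analysis(fd_groups, narrow=narrow)
        report["fd_frequency"] = {
            "narrow_interval": list(narrow),
            "full_anova": vars(full),
            "narrowed_anova": vars(narrowed) if narrowed else None,
            "histograms": {
                k: {"bin_edges": h.bin_edges.tolist(), "counts": h.counts.tolist()} for k, h in hists.items()
            },
        }
    return report
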