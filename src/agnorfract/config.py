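"""Run configuration: YAML round-trip, validation, and orchestration.

A run is either synthetic (cohort generated in-process with exact ground
truth) or file-based (a directory of RGB images plus a labels CSV mapping
filename -> patient and group).  Every output directory receives the
configuration echo and its hash, so any table can be traced back to the
exact rule set and seed that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .groups import GroupLabel
from .pipeline import MeasureOptions, image_df_to_long, measure_cohort, run_statistics
from .segmentation import SegmentationConfig
from .stats import NARROW_INTERVAL
from .synthetic import SyntheticSpec, cohort_labels, default_group_specs, generate_cohort

__all__ = ["RunConfig", "RunReport", "validate_config", "run_pipeline", "config_from_yaml"]

logger = logging.getLogger(__name__)


@dataclass
class StatsConfig:
    alpha: float = 0.05
    narrow_interval: tuple[float, float] = NARROW_INTERVAL
    bin_width: float = 0.01


@dataclass
class SyntheticSource:
    images_per_group: int = 5
    images_per_patient: int = 5
    spec_overrides: dict = field(default_factory=dict)


@dataclass
class DirectorySource:
    image_dir: str = ""
    labels_csv: str = ""


@dataclass
class RunConfig:
    """Full configuration of one pipeline run (exactly one input source)."""

    synthetic: SyntheticSource | None = None
    images: DirectorySource | None = None
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    measure: MeasureOptions = field(default_factory=MeasureOptions)
    stats: StatsConfig = field(default_factory=StatsConfig)
    output_dir: str = "agnorfract_out"
    seed: int = 0
    verbosity: int = 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage accounting for one run."""

    images_in: int = 0
    images_skipped: int = 0
    masks_out: int = 0
    objects_before_filter: int = 0
    objects_after_filter: int = 0
    wall_time_s: dict = field(default_factory=dict)
    config_hash: str = ""
    version: str = __version__


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of violations, each naming the offending field."""
    bad: list[str] = []
    sources = [s is not None for s in (config.synthetic, config.images)]
    if sum(sources) != 1:
        bad.append("config must set exactly one input source (synthetic or images)")
    if config.synthetic is not None:
        if config.synthetic.images_per_group < 1:
            bad.append("synthetic.images_per_group must be >= 1")
        try:
            _synthetic_specs(config)
        except (ValueError, TypeError) as exc:
            bad.append(f"synthetic.spec_overrides: {exc}")
    if config.images is not None:
        if not config.images.image_dir:
            bad.append("images.image_dir must be set")
        if not config.images.labels_csv:
            bad.append("images.labels_csv must be set")
    bad += [f"segmentation.{v}" for v in config.segmentation.validate()]
    lo, hi = config.stats.narrow_interval
    if not lo < hi:
        bad.append(f"stats.narrow_interval must be increasing, got ({lo}, {hi})")
    if not 0 < config.stats.alpha < 1:
        bad.append("stats.alpha must lie in (0, 1)")
    if config.stats.bin_width <= 0:
        bad.append("stats.bin_width must be > 0")
    return bad


def _synthetic_specs(config: RunConfig) -> dict[GroupLabel, SyntheticSpec]:
    overrides = dict(config.synthetic.spec_overrides or {})
    if "image_size" in overrides:
        overrides["image_size"] = tuple(overrides["image_size"])
    specs = default_group_specs(**overrides)
    for g, sp in specs.items():
        problems = sp.validate()
        if problems:
            raise ValueError(f"group {g}: " + "; ".join(problems))
    return specs


def config_from_yaml(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file (missing sections use defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig(
        synthetic=SyntheticSource(**raw["synthetic"]) if "synthetic" in raw else None,
        images=DirectorySource(**raw["images"]) if "images" in raw else None,
        segmentation=SegmentationConfig(**raw.get("segmentation", {})),
        measure=MeasureOptions(**raw.get("measure", {})),
        stats=StatsConfig(**{**raw.get("stats", {})}),
        output_dir=raw.get("output_dir", "agnorfract_out"),
        seed=int(raw.get("seed", 0)),
        verbosity=int(raw.get("verbosity", 1)),
    )
    if isinstance(cfg.stats.narrow_interval, list):
        cfg.stats.narrow_interval = tuple(cfg.stats.narrow_interval)
    return cfg


def _load_directory_cohort(config: RunConfig):
    """Read RGB images + labels CSV; nucleus/compartment masks optional."""
    import imageio.v3 as iio

    from .synthetic import GroundTruth, RgbImage

    src = config.images
    labels = pd.read_csv(src.labels_csv)
    required = {"filename", "patient_id", "group"}
    if not required <= set(labels.columns):
        raise ValueError(f"labels CSV must have columns {sorted(required)}")
    cohort = []
    rows = []
    skipped = 0
    for _, row in labels.iterrows():
        path = Path(src.image_dir) / row["filename"]
        try:
            pixels = np.asarray(iio.imread(path))[..., :3]
        except Exception as exc:  # unreadable image: skip with warning
            logger.warning("skipping unreadable image %s: %s", path, exc)
            skipped += 1
            continue
        pixel_size = float(row.get("pixel_size_um", 0.17))
        image = RgbImage(pixels=pixels, pixel_size=pixel_size, kind=str(row.get("image_kind", "single")), image_id=Path(row["filename"]).stem)
        mask_path = path.with_name(path.stem + "_nuclei.png")
        nucleus_mask = iio.imread(mask_path).astype(np.int32) if mask_path.exists() else np.zeros(pixels.shape[:2], np.int32)
        epi_path = path.with_name(path.stem + "_epithelium.png")
        epithelium = iio.imread(epi_path) > 0 if epi_path.exists() else np.zeros(pixels.shape[:2], bool)
        gt = GroundTruth(
            object_table=pd.DataFrame(),
            nucleus_mask=nucleus_mask,
            dot_mask=np.zeros(pixels.shape[:2], bool),
            group=GroupLabel(row["group"]),
            epithelium_mask=epithelium,
        )
        cohort.append((image, gt))
        rows.append(dict(image_id=image.image_id, patient_id=row["patient_id"], group=row["group"], image_kind=image.kind))
    return cohort, pd.DataFrame(rows), skipped


def run_pipeline(config: RunConfig) -> RunReport:
    """Run synthesize/load -> segment -> measure -> statistics, writing artifacts.

    Outputs under ``config.output_dir``: ``objects.csv``, ``images.csv``,
    ``statistics.json``, ``run_report.json`` and a config echo with hash.
    Identical config + seed reproduces byte-identical CSVs.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid RunConfig: " + "; ".join(problems))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.hash())
    t0 = time.perf_counter()

    skipped = 0
    if config.synthetic is not None:
        specs = _synthetic_specs(config)
        cohort = generate_cohort(specs, config.synthetic.images_per_group, seed=config.seed)
        labels = cohort_labels(cohort, images_per_patient=config.synthetic.images_per_patient)
    else:
        cohort, labels, skipped = _load_directory_cohort(config)
        if not cohort:
            raise ValueError("empty cohort: no readable images")
    report.images_in = len(cohort) + skipped
    report.images_skipped = skipped
    report.wall_time_s["input"] = round(time.perf_counter() - t0, 3)

    t1 = time.perf_counter()
    image_df, object_df = measure_cohort(
        cohort, seg_config=config.segmentation, options=config.measure, labels=labels
    )
    report.masks_out = len(image_df)
    report.objects_after_filter = len(object_df)
    report.objects_before_filter = int(image_df["raw_dot_count"].sum()) if len(image_df) else 0
    report.wall_time_s["measure"] = round(time.perf_counter() - t1, 3)

    t2 = time.perf_counter()
    stats_report = run_statistics(
        image_df, alpha=config.stats.alpha, narrow=tuple(config.stats.narrow_interval)
    )
    report.wall_time_s["statistics"] = round(time.perf_counter() - t2, 3)

    meta = {"config": config.to_dict(), "config_hash": config.hash(), "version": __version__, "seed": config.seed}
    object_df.to_csv(out / "objects.csv", index=False)
    image_df.to_csv(out / "images.csv", index=False)
    image_df_to_long(image_df).to_csv(out / "images_long.csv", index=False)
    (out / "statistics.json").write_text(json.dumps({**stats_report, **{"meta": meta}}, indent=2, default=str))
    (out / "config_echo.json").write_text(json.dumps(meta, indent=2, default=str))
    (out / "run_report.json").write_text(json.dumps(dataclasses.asdict(report), indent=2))
    return report
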