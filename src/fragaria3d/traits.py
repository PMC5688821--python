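"""Per-sample trait extraction: segmentation -> calibration -> measurement.

The scene coordinates produced by multi-view reconstruction are in an
arbitrary image space; the known holder height (38 mm) converts them to
millimetres. All dimension measurements come from the oriented bounding
box of the body+holder union, because the holder guarantees that the major
(vertical) axis is identified consistently; a box fitted to the irregular
body alone often picks the wrong vertical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .cloud_io import ColouredCloud, read_cloud
from .geometry import (
    DegenerateGeometryError,
    euclidean_cluster,
    fit_obb,
    max_pairwise_distance,
)
from .meshing import ReconstructionError, mesh_volume, reconstruct_surface
from .segmentation import SegmentationConfig, SegmentationError, rgb_to_hsv, segment

log = logging.getLogger(__name__)

TRAIT_COLUMNS = [
    "sample_id",
    "height_mm",
    "length_mm",
    "width_mm",
    "volume_ml",
    "calyx_size_mm",
    "achene_count",
    "mean_hue_deg",
    "scale_mm_per_unit",
    "status",
]


@dataclass(frozen=True)
class CalibrationStandard:
    """Physical size of the reference holder; its true height sets the scale."""

    true_holder_height: float = 38.0  # mm

    def __post_init__(self) -> None:
        if self.true_holder_height <= 0:
            raise ValueError("true_holder_height must be positive")


@dataclass
class MeasurementOptions:
    """Tunables for volume meshing and achene clustering."""

    mesh_method: str = "poisson"
    mesh_depth: int = 7
    achene_tolerance_mm: float = 1.5   # cluster cut distance, physical units
    achene_min_size: int = 3           # points per kept cluster


@dataclass
class TraitRecord:
    """The seven calibrated traits for one sample; None marks a failed trait."""

    sample_id: str
    height_mm: Optional[float] = None
    length_mm: Optional[float] = None
    width_mm: Optional[float] = None
    volume_ml: Optional[float] = None
    calyx_size_mm: Optional[float] = None
    achene_count: Optional[int] = None
    mean_hue_deg: Optional[float] = None
    scale_mm_per_unit: Optional[float] = None
    status: str = "ok"

    def as_row(self) -> dict:
        return {c: getattr(self, c) for c in TRAIT_COLUMNS}


def calibrate_scale(
    holder: ColouredCloud, standard: CalibrationStandard | None = None
) -> float:
    """mm per cloud unit = true holder height / holder OBB major extent."""
    standard = standard or CalibrationStandard()
    obb = fit_obb(holder.points)
    major = float(obb.extents[0])
    if major <= 0:
        raise DegenerateGeometryError("holder has zero major extent")
    return standard.true_holder_height / major


def measure_dimensions(
    body: ColouredCloud,
    holder: ColouredCloud,
    scale: float,
) -> tuple[float, float, float]:
    """Height, length, width in mm from the body+holder and holder boxes.

    Height is the difference of the major extents; length and width are the
    second and third extents of the combined box, ordered so length >= width.
    """
    combined = fit_obb(np.vstack([body.points, holder.points]))
    holder_box = fit_obb(holder.points)
    h_units = float(combined.extents[0] - holder_box.extents[0])
    if h_units < -1e-9 * combined.extents[0]:
        raise DegenerateGeometryError(
            "holder major extent exceeds combined major extent: "
            "segmentation failure"
        )
    h_units = max(h_units, 0.0)
    e2, e3 = float(combined.extents[1]), float(combined.extents[2])
    length, width = (e2, e3) if e2 >= e3 else (e3, e2)
    return h_units * scale, length * scale, width * scale


def measure_volume(
    body: ColouredCloud,
    scale: float,
    method: str = "poisson",
    depth: int = 7,
) -> float:
    """Body volume in ml: mesh the cloud, integrate, convert mm^3 -> ml."""
    mesh = reconstruct_surface(body, method=method, depth=depth)
    return mesh_volume(mesh) * scale**3 / 1000.0


def measure_calyx(calyx: ColouredCloud, scale: float) -> float:
    """Calyx size in mm: maximum pairwise distance over the calyx segment."""
    if len(calyx) < 2:
        raise DegenerateGeometryError("calyx segment has fewer than 2 points")
    dist, _ = max_pairwise_distance(calyx.points)
    return dist * scale


def count_achenes(
    achene_candidates: ColouredCloud,
    scale: float,
    tolerance_mm: float = 1.5,
    min_size: int = 3,
) -> int:
    """Number of achene spots: Euclidean clusters at a physical tolerance.

    The tolerance is specified in mm and converted to cloud units through
    the calibration so one default works at any image-space scale.
    """
    if tolerance_mm <= 0:
        raise ValueError("tolerance_mm must be positive")
    if len(achene_candidates) == 0:
        return 0
    cs = euclidean_cluster(
        achene_candidates.points, tolerance=tolerance_mm / scale, min_size=min_size
    )
    return cs.n_clusters


def measure_colour(body: ColouredCloud) -> float:
    """Circular mean hue of the body segment, degrees in [0, 360).

    A circular mean is used rather than a plain average because ripe
    strawberry red straddles the 0 deg wrap, where an arithmetic mean of
    hues near 359 and 1 would wrongly report ~180.
    """
    if len(body) == 0:
        raise ValueError("empty body segment")
    hue_rad = np.deg2rad(rgb_to_hsv(body.colors)[:, 0])
    mean = np.arctan2(np.mean(np.sin(hue_rad)), np.mean(np.cos(hue_rad)))
    return float(np.rad2deg(mean) % 360.0)


def process_sample(
    cloud: ColouredCloud,
    sample_id: str = "sample",
    seg_config: SegmentationConfig | None = None,
    standard: CalibrationStandard | None = None,
    options: MeasurementOptions | None = None,
) -> TraitRecord:
    """Run the full measurement pipeline on one scene cloud.

    Trait-level failures (e.g. a missing calyx) leave that field None and
    annotate ``status``; only an unusable holder/body makes the whole
    sample fail.
    """
    options = options or MeasurementOptions()
    record = TraitRecord(sample_id=sample_id)
    problems: list[str] = []
    try:
        seg = segment(cloud, seg_config)
        scale = calibrate_scale(seg.holder, standard)
    except (SegmentationError, DegenerateGeometryError, ValueError) as exc:
        record.status = f"failed: {exc}"
        return record
    record.scale_mm_per_unit = scale

    try:
        record.height_mm, record.length_mm, record.width_mm = measure_dimensions(
            seg.body, seg.holder, scale
        )
    except DegenerateGeometryError as exc:
        problems.append(f"dimensions: {exc}")
    try:
        record.volume_ml = measure_volume(
            seg.body, scale, method=options.mesh_method, depth=options.mesh_depth
        )
    except (ReconstructionError, DegenerateGeometryError) as exc:
        problems.append(f"volume: {exc}")
    try:
        record.calyx_size_mm = measure_calyx(seg.calyx, scale)
    except DegenerateGeometryError as exc:
        problems.append(f"calyx: {exc}")
    record.achene_count = count_achenes(
        seg.achene_candidates,
        scale,
        tolerance_mm=options.achene_tolerance_mm,
        min_size=options.achene_min_size,
    )
    try:
        record.mean_hue_deg = measure_colour(seg.body)
    except ValueError as exc:
        problems.append(f"colour: {exc}")

    record.status = "ok" if not problems else "partial: " + "; ".join(problems)
    return record


def process_batch(
    cloud_paths: Iterable,
    seg_config: SegmentationConfig | None = None,
    standard: CalibrationStandard | None = None,
    options: MeasurementOptions | None = None,
) -> pd.DataFrame:
    """Process cloud files in the given order; one row per file.

    A file that cannot be read or segmented yields a failure row, and the
    batch continues.
    """
    rows = []
    for path in cloud_paths:
        path = Path(path)
        sid = path.stem
        try:
            cloud = read_cloud(path)
        except Exception as exc:  # unreadable file: record, keep going
            log.warning("skipping %s: %s", path, exc)
            rows.append(TraitRecord(sample_id=sid, status=f"failed: {exc}").as_row())
            continue
        rec = process_sample(
            cloud, sample_id=sid, seg_config=seg_config,
            standard=standard, options=options,
        )
        log.info("processed %s: %s", sid, rec.status)
        rows.append(rec.as_row())
    return pd.DataFrame(rows, columns=TRAIT_COLUMNS)
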