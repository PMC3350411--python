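"""AHA 16-segment geometry, transmural extent, and four-level lesion grading.

Three short-axis levels cover 16 of the 17 AHA segments (the apical cap has
no short-axis representation): basal 1-6 and mid-cavity 7-12 in 60 degree
sectors, apical 13-16 in 90 degree sectors.  Sector boundaries are
referenced to the anterior RV insertion point and ordered counterclockwise
starting at the insertion, with angles measured in degrees.

Lesion involvement of a segment is summarized by two fractions — the
suprathreshold area fraction and the maximal radial transmural extent — and
mapped onto the four-level grade vocabulary used for visual reading:
1 none, 2 subendocardial, 3 transmural, 4 transmural with dark core.
Because a visual "transmural" call has no printed numeric definition, the
transmurality cutoff (default 0.75) and the minimal positive area fraction
(default 0.05) are explicit configuration, echoed into all reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "GradingConfig",
    "SegmentGrade",
    "SEGMENTS_PER_LEVEL",
    "LEVELS",
    "make_aha_labels",
    "pixel_angles",
    "transmural_extent",
    "grade_segment",
    "grade_from_masks",
]

LEVELS: Tuple[str, ...] = ("basal", "mid", "apical")

#: level -> (first AHA label, number of sectors)
SEGMENTS_PER_LEVEL: Dict[str, Tuple[int, int]] = {
    "basal": (1, 6),
    "mid": (7, 6),
    "apical": (13, 4),
}


@dataclass(frozen=True)
class GradingConfig:
    """Numeric rules standing in for the visual grade vocabulary."""

    min_area_fraction: float = 0.05
    transmural_cutoff: float = 0.75


@dataclass(frozen=True)
class SegmentGrade:
    segment_id: int
    grade: int  # 1 none, 2 subendocardial, 3 transmural, 4 transmural + dark core
    extent_fraction: float
    area_fraction: float
    dark_core: bool


def pixel_angles(shape: Tuple[int, int], lv_center: Tuple[float, float]) -> np.ndarray:
    """Counterclockwise angle (degrees in [0, 360)) of every pixel center
    about the LV center, with image rows counted downward (so the angle is
    the usual mathematical one in a y-up frame)."""
    cy, cx = lv_center
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
    theta = np.degrees(np.arctan2(cy - ys, xs - cx))
    return np.mod(theta, 360.0)


def make_aha_labels(
    myocardium_mask: np.ndarray,
    lv_center: Tuple[float, float],
    rv_insertion_deg: float,
    level: str,
) -> np.ndarray:
    """Partition a myocardial annulus into AHA sector labels for one level.

    Returns an integer map, 0 outside the myocardium.  Every myocardial
    pixel receives exactly one label.
    """
    if level not in SEGMENTS_PER_LEVEL:
        raise ValueError(f"unknown level {level!r}")
    myo = np.asarray(myocardium_mask, dtype=bool)
    if not myo.any():
        raise ValueError("degenerate annulus: empty myocardium mask")
    first, count = SEGMENTS_PER_LEVEL[level]
    width = 360.0 / count
    rel = np.mod(pixel_angles(myo.shape, lv_center) - rv_insertion_deg, 360.0)
    sector = np.minimum((rel // width).astype(int), count - 1)
    return np.where(myo, first + sector, 0)


def transmural_extent(
    filled_mask: np.ndarray,
    myocardium_mask: np.ndarray,
    lv_center: Tuple[float, float],
    segment_mask: np.ndarray,
    ray_step_deg: float = 1.0,
    radial_step_px: float = 0.25,
) -> float:
    """Maximal transmural extent of a lesion within one segment.

    Casts rays from the LV center at ``ray_step_deg`` spacing.  Along each
    ray the wall thickness is the number of radial samples inside the
    myocardium and the lesion run is the number of those samples inside the
    lesion.  A ray contributes to the segment when the majority of its wall
    samples lie in the segment (so rays grazing a sector corner, where the
    apparent wall is a pixel or two, do not dominate).  Returns the maximum
    ratio over contributing rays, 0.0 if none traverse the segment.
    """
    myo = np.asarray(myocardium_mask, dtype=bool)
    seg = np.asarray(segment_mask, dtype=bool) & myo
    if not seg.any():
        return 0.0
    lesion = np.asarray(filled_mask, dtype=bool) & myo
    cy, cx = lv_center
    h, w = seg.shape
    r_max = float(np.hypot(h, w))
    angles = np.deg2rad(np.arange(0.0, 360.0, ray_step_deg))
    radii = np.arange(0.0, r_max, radial_step_px)
    # sample grid: (n_rays, n_radii) nearest-pixel indices, y-up convention
    xs = np.rint(cx + radii[None, :] * np.cos(angles)[:, None]).astype(int)
    ys = np.rint(cy - radii[None, :] * np.sin(angles)[:, None]).astype(int)
    valid = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
    xs = np.clip(xs, 0, w - 1)
    ys = np.clip(ys, 0, h - 1)
    in_myo = myo[ys, xs] & valid
    wall = in_myo.sum(axis=1)
    seg_samples = (seg[ys, xs] & valid).sum(axis=1)
    run = (in_myo & lesion[ys, xs]).sum(axis=1)
    hit = (wall > 0) & (seg_samples * 2 > wall)
    if not hit.any():
        return 0.0
    return float(np.max(run[hit] / wall[hit]))


def grade_segment(
    extent_fraction: float,
    area_fraction: float,
    dark_core_present: bool,
    config: GradingConfig = GradingConfig(),
    segment_id: int = 0,
) -> SegmentGrade:
    """Map extent/area fractions onto the four-level grade.

    A segment is positive iff its suprathreshold area fraction reaches
    ``min_area_fraction``; positive segments are transmural (grade 3) iff
    the radial extent reaches ``transmural_cutoff``, subendocardial
    (grade 2) otherwise, and upgrade to 4 when a dark core is present
    within a transmural lesion.
    """
    if not (0 <= extent_fraction <= 1 and 0 <= area_fraction <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    positive = area_fraction >= config.min_area_fraction
    if not positive:
        grade = 1
    elif extent_fraction >= config.transmural_cutoff:
        grade = 4 if dark_core_present else 3
    else:
        grade = 2
    return SegmentGrade(
        segment_id=segment_id,
        grade=grade,
        extent_fraction=float(extent_fraction),
        area_fraction=float(area_fraction),
        dark_core=bool(dark_core_present and grade == 4),
    )


def grade_from_masks(
    lesion_masks: Sequence[np.ndarray],
    core_masks: Optional[Sequence[np.ndarray]],
    label_maps: Sequence[np.ndarray],
    lv_center: Tuple[float, float],
    config: GradingConfig = GradingConfig(),
    levels: Sequence[str] = LEVELS,
) -> pd.DataFrame:
    """Grade every AHA segment of a multi-slice study from binary masks.

    Works identically for detected lesions (segmentation output, with the
    hole-filled-minus-hyperintense difference as the core mask) and for
    ground-truth phantom masks, so detection and reference grades are
    produced by the same rules.

    Returns a DataFrame with one row per segment: ``slice``, ``level``,
    ``segment``, ``grade``, ``extent_fraction``, ``area_fraction``,
    ``dark_core``.
    """
    rows = []
    for s, (lesion, labels) in enumerate(zip(lesion_masks, label_maps)):
        myo = labels > 0
        core = None if core_masks is None else np.asarray(core_masks[s], dtype=bool)
        for seg_id in np.unique(labels[myo]):
            seg = labels == seg_id
            area_fraction = float((np.asarray(lesion, bool) & seg).sum() / seg.sum())
            extent = transmural_extent(lesion, myo, lv_center, seg)
            has_core = bool(core is not None and (core & seg).any())
            g = grade_segment(extent, area_fraction, has_core, config, segment_id=int(seg_id))
            rows.append(
                {
                    "slice": s,
                    "level": levels[s] if s < len(levels) else str(s),
                    "segment": int(seg_id),
                    "grade": g.grade,
                    "extent_fraction": g.extent_fraction,
                    "area_fraction": g.area_fraction,
                    "dark_core": g.dark_core,
                }
            )
    return pd.DataFrame(rows).sort_values("segment").reset_index(drop=True)
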