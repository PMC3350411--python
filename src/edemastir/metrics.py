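"""Study-level quantities: %LV extents, myocardial salvage, diagnostic
accuracy, acuity classification, grade tabulation, and the two-sample test.

Conventions
-----------
* Lesion burden is expressed as %LV: summed lesion volume over the imaged
  slices divided by summed LV myocardial volume, times 100.
* Myocardial salvage index MSI = (AAR - infarct) / AAR, the fraction of the
  at-risk myocardium that escaped necrosis (0 = no salvage, 1 = full).
* Sensitivity/specificity are per-segment against a reference standard,
  with uninterpretable segments excluded beforehand.
* Numeric functions return unrounded values; rounding to a table's printed
  precision is left to the reporting layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UndefinedMetricError",
    "DegenerateDataWarning",
    "ConfusionCounts",
    "percent_lv",
    "msi",
    "rel_excess",
    "percentage",
    "confusion",
    "classify_acuity",
    "tabulate_grades",
    "two_sample_t",
]


class UndefinedMetricError(ValueError):
    """The metric is undefined for these inputs (e.g. MSI with zero AAR)."""


class DegenerateDataWarning(UserWarning):
    """Inputs are degenerate (zero variance, infarct exceeding AAR, ...)."""


def percent_lv(
    lesion_masks: Sequence[np.ndarray],
    myocardium_masks: Sequence[np.ndarray],
    pixel_area_mm2: float = 1.0,
    slice_thickness_mm: float = 1.0,
) -> float:
    """Lesion volume as a percentage of LV myocardial volume.

    ``100 * sum(lesion voxels) / sum(myocardial voxels)`` with voxel volume
    ``pixel_area * slice_thickness`` (the factor cancels but is carried for
    unit transparency).  Lesion and myocardium lists must align slice by
    slice.
    """
    if len(lesion_masks) != len(myocardium_masks):
        raise ValueError("slice counts differ between lesion and myocardium masks")
    voxel = pixel_area_mm2 * slice_thickness_mm
    lesion = sum(float(np.count_nonzero(m)) for m in lesion_masks) * voxel
    myo = sum(float(np.count_nonzero(m)) for m in myocardium_masks) * voxel
    if myo == 0:
        raise UndefinedMetricError("zero myocardial volume")
    return 100.0 * lesion / myo


def msi(aar_percent: float, infarct_percent: float) -> float:
    """Myocardial salvage index ``(AAR - infarct) / AAR``.

    Clipped below at 0 (with a warning) when the measured infarct exceeds
    the measured area at risk, which can happen through segmentation noise.
    """
    if aar_percent <= 0:
        raise UndefinedMetricError("MSI undefined for zero area at risk")
    if infarct_percent < 0:
        raise ValueError("infarct extent cannot be negative")
    value = (aar_percent - infarct_percent) / aar_percent
    if value < 0:
        warnings.warn("infarct extent exceeds area at risk; MSI clipped to 0", DegenerateDataWarning)
        return 0.0
    return value


def rel_excess(a: float, b: float) -> float:
    """Relative excess of ``a`` over ``b`` in percent: ``100 (a - b)/b``.

    Unrounded; reports round to the nearest integer.
    """
    if b == 0:
        raise UndefinedMetricError("relative excess undefined for zero reference")
    return 100.0 * (a - b) / b


def percentage(numerator: float, denominator: float) -> float:
    """Plain share in percent, unrounded."""
    if denominator == 0:
        raise UndefinedMetricError("percentage undefined for zero denominator")
    return 100.0 * numerator / denominator


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            raise UndefinedMetricError("sensitivity undefined: no reference positives")
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            raise UndefinedMetricError("specificity undefined: no reference negatives")
        return self.tn / (self.tn + self.fp)


def confusion(
    test_positives: Iterable[int],
    reference_positives: Iterable[int],
    evaluable: Iterable[int],
) -> ConfusionCounts:
    """Per-segment 2x2 counts over the evaluable segments.

    Uninterpretable segments are excluded by leaving them out of
    ``evaluable``; membership outside ``evaluable`` is an error.
    """
    test: Set[int] = set(test_positives)
    ref: Set[int] = set(reference_positives)
    ev: Set[int] = set(evaluable)
    if not test <= ev or not ref <= ev:
        raise ValueError("positive sets must be subsets of the evaluable segments")
    tp = len(test & ref)
    fp = len(test - ref)
    fn = len(ref - test)
    tn = len(ev - test - ref)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def classify_acuity(stir_positive: bool, lge_positive: bool) -> str:
    """Combine edema (STIR) and necrosis/scar (LGE) status of a segment.

    LGE+ with edema is an acute lesion; LGE+ without edema is chronic scar;
    LGE- without edema is normal.  Edema without any LGE correlate is
    reported as its own category (acute injury without detectable
    necrosis) rather than folded into "acute".
    """
    if lge_positive:
        return "acute" if stir_positive else "chronic"
    return "edema_without_infarct" if stir_positive else "normal"


def tabulate_grades(grades: Iterable[int]) -> pd.DataFrame:
    """Counts and (unrounded) percentages of evaluable segments per grade.

    Returns a DataFrame indexed by grade 1-4 with ``count`` and ``pct``
    columns.
    """
    values = list(grades)
    if any(g not in (1, 2, 3, 4) for g in values):
        raise ValueError("grades must be integers 1-4")
    n = len(values)
    counts = {g: values.count(g) for g in (1, 2, 3, 4)}
    return pd.DataFrame(
        {
            "count": [counts[g] for g in (1, 2, 3, 4)],
            "pct": [percentage(counts[g], n) if n else float("nan") for g in (1, 2, 3, 4)],
        },
        index=pd.Index([1, 2, 3, 4], name="grade"),
    )


def two_sample_t(group_a: Sequence[float], group_b: Sequence[float]) -> Tuple[float, float]:
    """Classical (pooled-variance) Student's t test, two-sided.

    Returns ``(t, p)`` with ``n_a + n_b - 2`` degrees of freedom.  Zero
    pooled variance is degenerate: warned, with t = 0/inf by mean equality.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
    if pooled == 0:
        warnings.warn("zero pooled variance", DegenerateDataWarning)
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
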