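"""Semi-quantitative hyperintensity delineation for STIR and LGE images.

The delineation follows the threshold-based convention of infarct CMR:

* STIR (edema): threshold = mean + 2 SD of a remote, normal-appearing
  myocardial segment (sample SD, n-1 denominator);
* LGE (necrosis/scar): full-width-at-half-maximum threshold — half the
  robust maximum myocardial intensity (99th percentile rather than the
  single brightest pixel, which is noise-dominated at clinical SNR);
* hypointense/hypoenhanced cores fully enclosed by the hyperintense zone
  are added to the lesion (microvascular obstruction convention).

The remote segment and the STIR threshold depend on each other, so the
segmenter iterates: start from the lowest-mean segment, threshold,
delineate, re-select the lesion-free segment farthest from the lesion,
repeat until the remote choice is stable (at most 10 rounds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .aha_segments import pixel_angles

__all__ = [
    "RemoteUnavailableError",
    "UnstableRemoteWarning",
    "SegmentationConfig",
    "SegmentationResult",
    "select_remote_segment",
    "stir_threshold",
    "lge_threshold",
    "delineate",
    "include_dark_cores",
    "segment_study",
]


class RemoteUnavailableError(RuntimeError):
    """Every segment contains suprathreshold pixels; no remote candidate."""


class UnstableRemoteWarning(UserWarning):
    """Remote region too small for a stable SD estimate."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Threshold constants; all echoed into output reports."""

    sd_multiplier: float = 2.0
    fwhm_fraction: float = 0.5
    robust_percentile: float = 99.0
    min_component_px: int = 5
    max_iterations: int = 10
    min_remote_px: int = 10
    pooled_remote: bool = False  # pool remote pixels across slices for one STIR threshold


@dataclass
class SegmentationResult:
    modality: str  # "stir" | "lge"
    thresholds: List[float]  # per slice
    remote_segments: List[int]  # per slice
    remote_means: List[float]
    remote_sds: List[float]
    hyper_mask: np.ndarray  # (n_slices, ny, nx) bool
    filled_mask: np.ndarray  # after dark-core inclusion
    n_iterations: int
    converged: bool
    warnings: List[str] = field(default_factory=list)


def _circular_mean_deg(angles_deg: np.ndarray) -> float:
    rad = np.deg2rad(angles_deg)
    return float(np.mod(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())), 360.0))


def _angular_dist(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def select_remote_segment(
    image: np.ndarray,
    aha_labels: np.ndarray,
    hyper_mask: Optional[np.ndarray] = None,
    lv_center: Optional[Tuple[float, float]] = None,
) -> int:
    """Choose the remote (normal-appearing) segment of one slice.

    With no hyperintensity information (first pass) the segment of lowest
    mean intensity wins.  Otherwise, among segments free of suprathreshold
    pixels, the one at maximal angular distance from the lesion centroid
    wins; ties break to the lowest segment id.  Raises
    :class:`RemoteUnavailableError` when every segment is affected.
    """
    labels = np.asarray(aha_labels)
    ids = [int(i) for i in np.unique(labels[labels > 0])]
    if not ids:
        raise ValueError("empty label map")
    means = {i: float(image[labels == i].mean()) for i in ids}
    if hyper_mask is None or not np.asarray(hyper_mask, bool).any():
        return min(ids, key=lambda i: (means[i], i))
    hyper = np.asarray(hyper_mask, bool)
    affected = [i for i in ids if (hyper & (labels == i)).any()]
    candidates = [i for i in ids if i not in affected]
    if not candidates:
        raise RemoteUnavailableError("every segment contains suprathreshold pixels")
    if lv_center is None:
        ys, xs = np.nonzero(labels > 0)
        lv_center = (float(ys.mean()), float(xs.mean()))
    theta = pixel_angles(labels.shape, lv_center)
    lesion_angle = _circular_mean_deg(theta[hyper])
    seg_angle = {i: _circular_mean_deg(theta[labels == i]) for i in candidates}
    return min(candidates, key=lambda i: (-_angular_dist(seg_angle[i], lesion_angle), i))


def stir_threshold(
    image: np.ndarray, remote_mask: np.ndarray, sd_multiplier: float = 2.0
) -> float:
    """Remote mean + ``sd_multiplier`` sample standard deviations."""
    values = np.asarray(image)[np.asarray(remote_mask, bool)]
    if values.size == 0:
        raise ValueError("remote mask is empty")
    if values.size < 10:
        warnings.warn(
            f"remote region has only {values.size} pixels; SD estimate unstable",
            UnstableRemoteWarning,
        )
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()) + sd_multiplier * sd


def lge_threshold(
    image: np.ndarray,
    myocardium_mask: np.ndarray,
    fwhm_fraction: float = 0.5,
    robust_percentile: float = 99.0,
) -> float:
    """Full-width-at-half-maximum threshold over the myocardium.

    Half (``fwhm_fraction``) of the robust maximum intensity.  On a flat
    image this returns half the constant, so the whole myocardium ends up
    suprathreshold — a degenerate all-or-nothing outcome the caller can
    detect from the resulting mask.
    """
    values = np.asarray(image)[np.asarray(myocardium_mask, bool)]
    if values.size == 0:
        raise ValueError("myocardium mask is empty")
    return fwhm_fraction * float(np.percentile(values, robust_percentile))


def delineate(
    image: np.ndarray,
    threshold: float,
    myocardium_mask: np.ndarray,
    min_component_px: int = 5,
) -> np.ndarray:
    """Binary mask of myocardial pixels strictly above the threshold, with
    connected components smaller than ``min_component_px`` removed."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    mask = (np.asarray(image) > threshold) & np.asarray(myocardium_mask, bool)
    if min_component_px > 1:
        lab, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(2, 1))
        if n:
            sizes = np.bincount(lab.ravel())
            keep = sizes >= min_component_px
            keep[0] = False
            mask = keep[lab]
    return mask


def include_dark_cores(
    hyper_mask: np.ndarray,
    myocardium_mask: np.ndarray,
    lv_center: Optional[Tuple[float, float]] = None,
    angular_tolerance_deg: float = 4.0,
) -> np.ndarray:
    """Add subthreshold regions enclosed by the hyperintense zone.

    A subthreshold connected component counts as a core when, in the
    annulus topology about the LV center:

    * it touches the hyperintense mask,
    * it is radially covered by it — every pixel of the component has
      hyperintense pixels (at some radius) within a small angular
      tolerance, about one pixel of arc at the annulus radius,
    * it has no epicardial background contact: no background neighbour
      lies at a radius beyond the component's outermost pixel.

    Hypoenhanced cores sit inside (or subendocardially under) a thicker
    enhancing wedge and satisfy all three, including cores that reach the
    endocardial edge.  Remote myocardium, and the non-enhancing epicardial
    rim over a partial-thickness lesion, border the epicardium and are
    left out.
    """
    hyper = np.asarray(hyper_mask, bool)
    myo = np.asarray(myocardium_mask, bool)
    filled = hyper.copy()
    if not hyper.any():
        return filled
    if lv_center is None:
        ys, xs = np.nonzero(myo)
        lv_center = (float(ys.mean()), float(xs.mean()))
    cy, cx = lv_center
    ys, xs = np.mgrid[0 : myo.shape[0], 0 : myo.shape[1]]
    radius = np.hypot(ys - cy, xs - cx)
    theta = pixel_angles(myo.shape, lv_center)
    # angular coverage lookup: sorted hyper angles with wraparound sentinels
    hyper_angles = np.sort(theta[hyper])
    extended = np.concatenate([hyper_angles - 360.0, hyper_angles, hyper_angles + 360.0])

    def covered(angles: np.ndarray) -> bool:
        idx = np.searchsorted(extended, angles)
        left = extended[np.maximum(idx - 1, 0)]
        right = extended[np.minimum(idx, extended.size - 1)]
        nearest = np.minimum(np.abs(angles - left), np.abs(right - angles))
        return bool((nearest <= angular_tolerance_deg).all())

    structure = ndimage.generate_binary_structure(2, 1)
    sub = myo & ~hyper
    lab, n = ndimage.label(sub, structure=structure)
    for i in range(1, n + 1):
        comp = lab == i
        border = ndimage.binary_dilation(comp, structure) & ~comp
        if not (border & hyper).any():
            continue
        outside = border & ~myo
        if outside.any() and float(radius[outside].max()) > float(radius[comp].max()):
            continue
        if covered(theta[comp]):
            filled |= comp
    return filled


def _segment_stir_slice(
    image: np.ndarray,
    labels: np.ndarray,
    cfg: SegmentationConfig,
    lv_center: Optional[Tuple[float, float]],
):
    myo = labels > 0
    notes: List[str] = []
    remote = select_remote_segment(image, labels, None, lv_center)
    threshold = float("nan")
    hyper = np.zeros_like(myo)
    converged = False
    iterations = 0
    for iterations in range(1, cfg.max_iterations + 1):
        threshold = stir_threshold(image, labels == remote, cfg.sd_multiplier)
        hyper = delineate(image, threshold, myo, cfg.min_component_px)
        try:
            new_remote = select_remote_segment(image, labels, hyper, lv_center)
        except RemoteUnavailableError:
            notes.append("remote unavailable; fell back to lowest-intensity segment")
            new_remote = select_remote_segment(image, labels, None, lv_center)
        if new_remote == remote:
            converged = True
            break
        remote = new_remote
    if not converged:
        notes.append(f"remote selection did not stabilize in {cfg.max_iterations} iterations")
    remote_px = image[labels == remote]
    return remote, threshold, hyper, iterations, converged, notes, remote_px


def segment_study(
    images: np.ndarray,
    aha_labels: np.ndarray,
    modality: str,
    config: SegmentationConfig = SegmentationConfig(),
    lv_center: Optional[Tuple[float, float]] = None,
) -> SegmentationResult:
    """Delineate hyperintensity on a multi-slice study.

    STIR slices are processed independently (per-slice remote statistics;
    set ``config.pooled_remote`` to pool remote pixels across slices into a
    single threshold).  The LGE threshold is a single FWHM value computed
    over the pooled myocardium of all slices, so slices without scar do not
    degenerate to a noise-level threshold.  Dark-core inclusion is applied
    last on every slice.
    """
    if modality not in ("stir", "lge"):
        raise ValueError(f"modality must be 'stir' or 'lge', got {modality!r}")
    images = np.asarray(images, dtype=float)
    labels = np.asarray(aha_labels)
    n_slices = images.shape[0]
    myo = labels > 0

    thresholds: List[float] = []
    remotes: List[int] = []
    remote_means: List[float] = []
    remote_sds: List[float] = []
    notes: List[str] = []
    hyper = np.zeros(images.shape, dtype=bool)
    n_iterations = 1
    converged = True

    if modality == "lge":
        thr = lge_threshold(images, myo, config.fwhm_fraction, config.robust_percentile)
        for s in range(n_slices):
            hyper[s] = delineate(images[s], thr, myo[s], config.min_component_px)
            try:
                remote = select_remote_segment(images[s], labels[s], hyper[s], lv_center)
            except RemoteUnavailableError:
                notes.append(f"slice {s}: remote unavailable; lowest-intensity fallback")
                remote = select_remote_segment(images[s], labels[s], None, lv_center)
            remote_px = images[s][labels[s] == remote]
            thresholds.append(float(thr))
            remotes.append(remote)
            remote_means.append(float(remote_px.mean()))
            remote_sds.append(float(remote_px.std(ddof=1)) if remote_px.size > 1 else 0.0)
    elif config.pooled_remote:
        remotes = [select_remote_segment(images[s], labels[s], None, lv_center) for s in range(n_slices)]
        converged = False
        for n_iterations in range(1, config.max_iterations + 1):
            pooled = np.concatenate(
                [images[s][labels[s] == remotes[s]] for s in range(n_slices)]
            )
            thr = float(pooled.mean()) + config.sd_multiplier * float(pooled.std(ddof=1))
            for s in range(n_slices):
                hyper[s] = delineate(images[s], thr, myo[s], config.min_component_px)
            new_remotes = []
            for s in range(n_slices):
                try:
                    new_remotes.append(select_remote_segment(images[s], labels[s], hyper[s], lv_center))
                except RemoteUnavailableError:
                    notes.append(f"slice {s}: remote unavailable; lowest-intensity fallback")
                    new_remotes.append(select_remote_segment(images[s], labels[s], None, lv_center))
            if new_remotes == remotes:
                converged = True
                break
            remotes = new_remotes
        if not converged:
            notes.append(f"remote selection did not stabilize in {config.max_iterations} iterations")
        for s in range(n_slices):
            remote_px = images[s][labels[s] == remotes[s]]
            thresholds.append(thr)
            remote_means.append(float(remote_px.mean()))
            remote_sds.append(float(remote_px.std(ddof=1)) if remote_px.size > 1 else 0.0)
    else:
        iters = []
        for s in range(n_slices):
            remote, thr, h, its, conv, slice_notes, remote_px = _segment_stir_slice(
                images[s], labels[s], config, lv_center
            )
            hyper[s] = h
            thresholds.append(thr)
            remotes.append(remote)
            remote_means.append(float(remote_px.mean()))
            remote_sds.append(float(remote_px.std(ddof=1)) if remote_px.size > 1 else 0.0)
            notes.extend(f"slice {s}: {m}" for m in slice_notes)
            iters.append(its)
            converged &= conv
        n_iterations = max(iters)

    filled = np.stack([include_dark_cores(hyper[s], myo[s], lv_center) for s in range(n_slices)])
    return SegmentationResult(
        modality=modality,
        thresholds=thresholds,
        remote_segments=remotes,
        remote_means=remote_means,
        remote_sds=remote_sds,
        hyper_mask=hyper,
        filled_mask=filled,
        n_iterations=n_iterations,
        converged=converged,
        warnings=notes,
    )
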