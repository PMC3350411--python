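"""Seeded digital short-axis phantom for edema-weighted CMR.

Generates three short-axis slices (basal, mid-cavity, apical) of an annular
LV myocardium with:

* a wedge-shaped area at risk (AAR) carrying the longer T1 and T2 of
  edematous myocardium (defaults 1300/80 ms vs remote 1000/50 ms at 1.5 T),
* a nested infarct wedge visible on LGE through a shortened post-contrast
  T1, with an optional hypointense/hypoenhanced core (microvascular
  obstruction / hemorrhage),
* suppressed (black-blood) cavity signal, optionally with a one-pixel
  slow-flow bright rim artifact at the endocardial border,
* Rician magnitude noise.

In the chronic stage the edema has resolved: the STIR ground-truth lesion
is empty and the area at risk collapses onto the scar seen on LGE.

Geometry is deterministic given the spec; noise is drawn from a seeded
generator, so a full study is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy import ndimage

from . import mr_signal
from .aha_segments import LEVELS, make_aha_labels
from .mr_signal import SequenceParams, TissueParams, null_ti, tr_from_heart_rate

__all__ = [
    "InvalidSpecError",
    "WedgeSpec",
    "DarkCoreSpec",
    "PhantomSpec",
    "PhantomStudy",
    "build_phantom",
    "render",
    "add_rician_noise",
    "default_stir_sequence",
    "default_lge_sequence",
    "remote_signal",
    "sigma_for_snr",
]


class InvalidSpecError(ValueError):
    """Phantom specification violates a geometric or physical constraint."""


def angular_distance(a, b):
    """Smallest absolute angle between two directions, degrees in [0, 180]."""
    d = np.mod(np.asarray(a) - np.asarray(b), 360.0)
    return np.minimum(d, 360.0 - d)


@dataclass(frozen=True)
class WedgeSpec:
    """A transmural wedge: angular sector growing outward from the
    endocardium to a fraction of the wall thickness."""

    center_angle_deg: float
    angular_width_deg: float
    transmural_fraction: float

    def __post_init__(self) -> None:
        if not (0 < self.angular_width_deg < 360):
            raise InvalidSpecError(
                f"wedge width must lie in (0, 360) deg, got {self.angular_width_deg}"
            )
        if not (0 < self.transmural_fraction <= 1):
            raise InvalidSpecError(
                f"transmural fraction must lie in (0, 1], got {self.transmural_fraction}"
            )


@dataclass(frozen=True)
class DarkCoreSpec:
    """Hypointense core nested inside the infarct.

    ``radial_band`` bounds the core radially as fractions of the infarct's
    transmural depth, so the core sits strictly inside the infarct wedge.
    """

    angular_width_deg: float = 40.0
    radial_band: Tuple[float, float] = (0.2, 0.7)

    def __post_init__(self) -> None:
        lo, hi = self.radial_band
        if not (0 <= lo < hi <= 1):
            raise InvalidSpecError(f"radial band must satisfy 0 <= lo < hi <= 1, got {self.radial_band}")


def _default_radii() -> Dict[str, Tuple[float, float]]:
    # (endocardial, epicardial) radius in mm per level
    return {"basal": (24.0, 33.0), "mid": (21.0, 30.0), "apical": (15.0, 24.0)}


def _default_tissues() -> Dict[str, TissueParams]:
    return {
        "remote": TissueParams("remote", 1000.0, 50.0),
        "edema": TissueParams("edema", 1300.0, 80.0),
        # hemorrhagic core: edema-like T1, strongly shortened T2
        "dark_core": TissueParams("dark_core", 1300.0, 30.0),
    }


def _default_post_gd_t1() -> Dict[str, float]:
    # ms; gadolinium shortens T1 everywhere it distributes: scar retains it
    # (400 ms), perfused remote myocardium washes out toward 600 ms, and the
    # obstructed core receives little contrast and stays long (700 ms).
    return {"remote": 600.0, "infarct": 400.0, "dark_core": 700.0}


@dataclass(frozen=True)
class PhantomSpec:
    """Complete description of one synthetic study.

    Defaults model the study conditions: 1.5 x 1.5 mm reconstructed pixels,
    8 mm slices, three levels covering 16 AHA segments, an inferolateral
    AAR of roughly 28 %LV with a nested infarct of roughly 13 %LV
    (salvage index ~0.5), and magnitude noise giving SNR ~20 in remote
    myocardium on STIR.
    """

    image_size: int = 128
    pixel_spacing_mm: float = 1.5
    slice_thickness_mm: float = 8.0
    lv_center: Optional[Tuple[float, float]] = None  # (row, col), defaults to image center
    radii_mm: Mapping[str, Tuple[float, float]] = field(default_factory=_default_radii)
    rv_insertion_deg: float = 60.0
    aar: WedgeSpec = field(default_factory=lambda: WedgeSpec(210.0, 120.0, 0.85))
    infarct: WedgeSpec = field(default_factory=lambda: WedgeSpec(210.0, 90.0, 0.55))
    dark_core: Optional[DarkCoreSpec] = None
    stage: str = "acute"
    tissues: Mapping[str, TissueParams] = field(default_factory=_default_tissues)
    post_gd_t1_ms: Mapping[str, float] = field(default_factory=_default_post_gd_t1)
    noise_sigma: float = 0.0036
    slow_flow_rim: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage not in ("acute", "chronic"):
            raise InvalidSpecError(f"stage must be 'acute' or 'chronic', got {self.stage!r}")
        if self.noise_sigma < 0:
            raise InvalidSpecError("noise sigma must be non-negative")
        for level in LEVELS:
            endo, epi = self.radii_mm[level]
            if not (0 < endo < epi):
                raise InvalidSpecError(f"{level}: need 0 < endo < epi, got ({endo}, {epi})")
        if self.infarct.angular_width_deg > self.aar.angular_width_deg:
            raise InvalidSpecError("infarct wedge wider than area at risk")
        if self.infarct.transmural_fraction > self.aar.transmural_fraction:
            raise InvalidSpecError("infarct deeper than area at risk")
        # angular containment of the infarct interval in the AAR interval
        shift = angular_distance(self.infarct.center_angle_deg, self.aar.center_angle_deg)
        if shift + self.infarct.angular_width_deg / 2 > self.aar.angular_width_deg / 2 + 1e-9:
            raise InvalidSpecError("infarct wedge not contained in area-at-risk wedge")

    def center_px(self) -> Tuple[float, float]:
        if self.lv_center is not None:
            return self.lv_center
        c = (self.image_size - 1) / 2.0
        return (c, c)


@dataclass(frozen=True)
class PhantomStudy:
    """Parameter maps, ground-truth masks, and AHA labels for three slices.

    All volumes are ``(n_slices, ny, nx)`` with slice order basal, mid,
    apical.  ``stir_lesion`` is the STIR ground truth (the AAR when acute,
    empty when chronic); ``aar`` equals the infarct in the chronic stage
    because the edema has resolved and only scar remains.
    """

    spec: PhantomSpec
    t1_pre: np.ndarray
    t1_post: np.ndarray
    t2: np.ndarray
    pd: np.ndarray
    myocardium: np.ndarray
    cavity: np.ndarray
    aar: np.ndarray
    infarct: np.ndarray
    dark_core: np.ndarray
    stir_lesion: np.ndarray
    labels: np.ndarray
    levels: Tuple[str, ...] = LEVELS

    @property
    def lv_center(self) -> Tuple[float, float]:
        return self.spec.center_px()


def _wedge_mask(r_mm, theta, myo, endo, epi, wedge: WedgeSpec) -> np.ndarray:
    in_angle = angular_distance(theta, wedge.center_angle_deg) <= wedge.angular_width_deg / 2
    in_depth = r_mm <= endo + wedge.transmural_fraction * (epi - endo)
    return myo & in_angle & in_depth


def build_phantom(spec: PhantomSpec) -> PhantomStudy:
    """Construct parameter maps and ground-truth masks from a spec.

    Purely geometric — no randomness — so identical specs yield bit-identical
    studies.
    """
    n = spec.image_size
    cy, cx = spec.center_px()
    ys, xs = np.mgrid[0:n, 0:n]
    dx_mm = (xs - cx) * spec.pixel_spacing_mm
    dy_mm = (cy - ys) * spec.pixel_spacing_mm  # y-up physical frame
    r_mm = np.hypot(dx_mm, dy_mm)
    theta = np.mod(np.degrees(np.arctan2(dy_mm, dx_mm)), 360.0)

    remote = spec.tissues["remote"]
    edema = spec.tissues["edema"]
    core_tissue = spec.tissues["dark_core"]

    shape = (len(LEVELS), n, n)
    t1_pre = np.full(shape, remote.t1)
    t1_post = np.full(shape, float(spec.post_gd_t1_ms["remote"]))
    t2 = np.full(shape, remote.t2)
    pd = np.zeros(shape)
    myo3 = np.zeros(shape, dtype=bool)
    cav3 = np.zeros(shape, dtype=bool)
    aar3 = np.zeros(shape, dtype=bool)
    inf3 = np.zeros(shape, dtype=bool)
    core3 = np.zeros(shape, dtype=bool)
    labels3 = np.zeros(shape, dtype=np.int16)

    acute = spec.stage == "acute"
    for s, level in enumerate(LEVELS):
        endo, epi = spec.radii_mm[level]
        myo = (r_mm >= endo) & (r_mm < epi)
        cavity = r_mm < endo
        aar_mask = _wedge_mask(r_mm, theta, myo, endo, epi, spec.aar)
        infarct = _wedge_mask(r_mm, theta, myo, endo, epi, spec.infarct)
        core = np.zeros_like(myo)
        if acute and spec.dark_core is not None:
            lo, hi = spec.dark_core.radial_band
            depth = spec.infarct.transmural_fraction * (epi - endo)
            in_angle = (
                angular_distance(theta, spec.infarct.center_angle_deg)
                <= spec.dark_core.angular_width_deg / 2
            )
            in_band = (r_mm >= endo + lo * depth) & (r_mm <= endo + hi * depth)
            # restrict to the infarct interior so the core keeps an enclosing
            # rim of enhancing tissue at least one pixel thick
            interior = ndimage.binary_erosion(
                infarct, structure=ndimage.generate_binary_structure(2, 2)
            )
            core = interior & in_angle & in_band

        myo3[s] = myo
        cav3[s] = cavity
        inf3[s] = infarct
        core3[s] = core
        aar3[s] = aar_mask if acute else infarct
        pd[s][myo] = remote.pd
        labels3[s] = make_aha_labels(myo, (cy, cx), spec.rv_insertion_deg, level)

        if acute:
            t1_pre[s][aar_mask] = edema.t1
            t2[s][aar_mask] = edema.t2
            t1_pre[s][core] = core_tissue.t1
            t2[s][core] = core_tissue.t2
            t1_post[s][infarct] = float(spec.post_gd_t1_ms["infarct"])
            t1_post[s][core] = float(spec.post_gd_t1_ms["dark_core"])
        else:
            t1_post[s][infarct] = float(spec.post_gd_t1_ms["infarct"])

    stir_lesion = aar3.copy() if acute else np.zeros(shape, dtype=bool)
    return PhantomStudy(
        spec=spec,
        t1_pre=t1_pre,
        t1_post=t1_post,
        t2=t2,
        pd=pd,
        myocardium=myo3,
        cavity=cav3,
        aar=aar3,
        infarct=inf3,
        dark_core=core3,
        stir_lesion=stir_lesion,
        labels=labels3,
    )


def default_stir_sequence(heart_rate: float = 60.0) -> SequenceParams:
    """Protocol STIR timing: TI 180 ms, TE 100 ms, TR from the gating rule."""
    return SequenceParams("stir", te=100.0, tr=tr_from_heart_rate(heart_rate), ti=180.0)


def default_lge_sequence(spec: PhantomSpec, tr: float = 2000.0) -> SequenceParams:
    """IR-GRE timing with TI chosen to null remote (post-contrast) myocardium."""
    ti = null_ti(float(spec.post_gd_t1_ms["remote"]), tr)
    return SequenceParams("ir_gre", te=2.0, tr=tr, ti=ti)


def render(study: PhantomStudy, seq: SequenceParams) -> np.ndarray:
    """Noise-free magnitude image volume for one sequence.

    STIR uses the native (pre-contrast) T1 map, IR-GRE the post-contrast
    one.  The blood pool carries zero proton density (idealized black-blood
    suppression); if the spec enables the slow-flow artifact, a one-pixel
    cavity rim adjacent to the endocardium is set to the edema signal level
    on STIR.
    """
    if seq.kind == "stir":
        t1 = study.t1_pre
    elif seq.kind == "ir_gre":
        if study.t1_post is None:  # pragma: no cover - always built
            raise InvalidSpecError("post-contrast T1 map required for ir_gre rendering")
        t1 = study.t1_post
    else:
        raise InvalidSpecError(f"render supports stir and ir_gre, got {seq.kind!r}")
    image = mr_signal.magnitude_map(t1, study.t2, study.pd, seq)
    if seq.kind == "stir" and study.spec.slow_flow_rim:
        edema = study.spec.tissues["edema"]
        rim_value = mr_signal.stir_magnitude(edema, seq).magnitude
        structure = ndimage.generate_binary_structure(2, 1)
        for s in range(image.shape[0]):
            rim = study.cavity[s] & ndimage.binary_dilation(study.myocardium[s], structure)
            image[s][rim] = rim_value
    return image


def add_rician_noise(image: np.ndarray, sigma: float, seed) -> np.ndarray:
    """Apply magnitude-MR (Rician) noise: ``sqrt((x + n1)^2 + n2^2)`` with
    independent zero-mean Gaussian components of standard deviation
    ``sigma``.  ``seed`` may be an int or a ``numpy.random.Generator``."""
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    image = np.asarray(image, dtype=float)
    if sigma == 0:
        return image.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, image.shape)
    n2 = rng.normal(0.0, sigma, image.shape)
    return np.sqrt((image + n1) ** 2 + n2**2)


def remote_signal(study: PhantomStudy, seq: SequenceParams) -> float:
    """Noise-free magnitude of remote myocardium under ``seq``."""
    remote = study.spec.tissues["remote"]
    if seq.kind == "ir_gre":
        remote = TissueParams(
            "remote_post", float(study.spec.post_gd_t1_ms["remote"]), remote.t2, remote.pd
        )
    return mr_signal.magnitude(remote, seq).magnitude


def sigma_for_snr(study: PhantomStudy, seq: SequenceParams, snr: float) -> float:
    """Noise sigma giving the requested SNR in remote myocardium."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    return remote_signal(study, seq) / snr
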