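"""NIfTI / JSON / YAML readers and writers.

Images and masks travel as 3-slice NIfTI volumes; geometry (LV center, RV
insertion angle, pixel spacing, slice thickness, level order) travels in a
JSON sidecar; phantom specs are YAML.  In-memory volumes are
``(n_slices, ny, nx)``; on disk NIfTI stores ``(nx, ny, n_slices)`` with a
diagonal affine built from pixel spacing and slice thickness.  Masks are
unsigned 8-bit.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Dict, Optional, Tuple

import nibabel as nib
import numpy as np
import yaml

from .mr_signal import TissueParams
from .phantom import DarkCoreSpec, PhantomSpec, PhantomStudy, WedgeSpec

__all__ = [
    "write_nifti",
    "read_nifti",
    "write_geometry",
    "read_geometry",
    "spec_to_dict",
    "spec_from_dict",
    "load_spec_yaml",
    "save_spec_yaml",
    "write_study",
]


def _affine(pixel_spacing_mm: float, slice_thickness_mm: float) -> np.ndarray:
    return np.diag([pixel_spacing_mm, pixel_spacing_mm, slice_thickness_mm, 1.0])


def write_nifti(
    path,
    volume: np.ndarray,
    pixel_spacing_mm: float = 1.5,
    slice_thickness_mm: float = 8.0,
    dtype=None,
) -> None:
    """Write a ``(n_slices, ny, nx)`` volume as NIfTI.

    Boolean volumes are stored as uint8.
    """
    volume = np.asarray(volume)
    if dtype is None:
        dtype = np.uint8 if volume.dtype == bool else np.float32
    data = np.transpose(volume.astype(dtype), (2, 1, 0))
    img = nib.Nifti1Image(data, _affine(pixel_spacing_mm, slice_thickness_mm))
    nib.save(img, str(path))


def read_nifti(path) -> np.ndarray:
    """Read a NIfTI written by :func:`write_nifti` back to ``(n_slices, ny, nx)``."""
    data = np.asanyarray(nib.load(str(path)).dataobj)
    return np.transpose(data, (2, 1, 0))


def write_geometry(path, study: PhantomStudy) -> None:
    spec = study.spec
    geometry = {
        "lv_center_px": list(study.lv_center),
        "rv_insertion_deg": spec.rv_insertion_deg,
        "pixel_spacing_mm": spec.pixel_spacing_mm,
        "slice_thickness_mm": spec.slice_thickness_mm,
        "levels": list(study.levels),
        "radii_mm": {k: list(v) for k, v in spec.radii_mm.items()},
        "stage": spec.stage,
    }
    Path(path).write_text(json.dumps(geometry, indent=2, sort_keys=True) + "\n")


def read_geometry(path) -> Dict[str, Any]:
    return json.loads(Path(path).read_text())


def spec_to_dict(spec: PhantomSpec) -> Dict[str, Any]:
    """Plain-dict form of a phantom spec, suitable for YAML."""
    d: Dict[str, Any] = {
        "image_size": spec.image_size,
        "pixel_spacing_mm": spec.pixel_spacing_mm,
        "slice_thickness_mm": spec.slice_thickness_mm,
        "lv_center": list(spec.lv_center) if spec.lv_center is not None else None,
        "radii_mm": {k: list(v) for k, v in spec.radii_mm.items()},
        "rv_insertion_deg": spec.rv_insertion_deg,
        "aar": dataclasses.asdict(spec.aar),
        "infarct": dataclasses.asdict(spec.infarct),
        "dark_core": dataclasses.asdict(spec.dark_core) if spec.dark_core else None,
        "stage": spec.stage,
        "tissues": {
            k: {"t1": t.t1, "t2": t.t2, "pd": t.pd} for k, t in spec.tissues.items()
        },
        "post_gd_t1_ms": dict(spec.post_gd_t1_ms),
        "noise_sigma": spec.noise_sigma,
        "slow_flow_rim": spec.slow_flow_rim,
        "seed": spec.seed,
    }
    if d["dark_core"] is not None:
        d["dark_core"]["radial_band"] = list(d["dark_core"]["radial_band"])
    return d


def spec_from_dict(d: Dict[str, Any]) -> PhantomSpec:
    """Inverse of :func:`spec_to_dict`; missing keys take the defaults."""
    kwargs: Dict[str, Any] = {}
    simple = (
        "image_size",
        "pixel_spacing_mm",
        "slice_thickness_mm",
        "rv_insertion_deg",
        "stage",
        "noise_sigma",
        "slow_flow_rim",
        "seed",
    )
    for key in simple:
        if key in d:
            kwargs[key] = d[key]
    if d.get("lv_center") is not None:
        kwargs["lv_center"] = tuple(d["lv_center"])
    if "radii_mm" in d:
        kwargs["radii_mm"] = {k: tuple(v) for k, v in d["radii_mm"].items()}
    for wedge_key in ("aar", "infarct"):
        if wedge_key in d:
            kwargs[wedge_key] = WedgeSpec(**d[wedge_key])
    if d.get("dark_core") is not None:
        core = dict(d["dark_core"])
        core["radial_band"] = tuple(core["radial_band"])
        kwargs["dark_core"] = DarkCoreSpec(**core)
    if "tissues" in d:
        kwargs["tissues"] = {
            k: TissueParams(k, v["t1"], v["t2"], v.get("pd", 1.0))
            for k, v in d["tissues"].items()
        }
    if "post_gd_t1_ms" in d:
        kwargs["post_gd_t1_ms"] = {k: float(v) for k, v in d["post_gd_t1_ms"].items()}
    return PhantomSpec(**kwargs)


def load_spec_yaml(path) -> PhantomSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return spec_from_dict(data)


def save_spec_yaml(path, spec: PhantomSpec) -> None:
    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec), sort_keys=True))


def write_study(outdir, study: PhantomStudy, images: Optional[Dict[str, np.ndarray]] = None) -> None:
    """Write every mask/label volume (and rendered images) of one study."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = study.spec
    kw = dict(pixel_spacing_mm=spec.pixel_spacing_mm, slice_thickness_mm=spec.slice_thickness_mm)
    write_nifti(outdir / "myocardium.nii.gz", study.myocardium, **kw)
    write_nifti(outdir / "aar.nii.gz", study.aar, **kw)
    write_nifti(outdir / "infarct.nii.gz", study.infarct, **kw)
    write_nifti(outdir / "dark_core.nii.gz", study.dark_core, **kw)
    write_nifti(outdir / "stir_lesion.nii.gz", study.stir_lesion, **kw)
    write_nifti(outdir / "aha_labels.nii.gz", study.labels, dtype=np.int16, **kw)
    write_geometry(outdir / "geometry.json", study)
    save_spec_yaml(outdir / "spec.yaml", spec)
    for name, image in (images or {}).items():
        write_nifti(outdir / f"{name}.nii.gz", image, dtype=np.float32, **kw)
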