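"""Readers/writers for the on-disk formats of the pipeline.

Velocity and magnitude volumes travel as NIfTI (one 5-D file, x/y/z/phase/
component, with voxel spacing in the affine) plus a JSON sidecar holding
VENC, phase spacing and origin; contours, landmark tracks, truth records
and metric summaries as JSON; cohorts and tables as CSV with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .flow_preprocess import VelocityField
from .rv_geometry import ContourStack


def save_velocity_field(field_: VelocityField, path: str) -> None:
    """Write velocity as <path>.nii + <path>.json (+ <path>_mag.nii)."""
    path = Path(path)
    dx, dy, dz = field_.voxel_mm
    affine = np.diag([dx, dy, dz, 1.0])
    affine[:3, 3] = field_.origin_mm
    # array (T, Z, Y, X, 3) -> NIfTI (X, Y, Z, T, 3)
    arr = np.transpose(field_.v, (3, 2, 1, 0, 4))
    nib.save(nib.Nifti1Image(arr.astype(np.float32), affine),
             str(path) + ".nii")
    if field_.mag is not None:
        m = np.transpose(field_.mag, (2, 1, 0))
        nib.save(nib.Nifti1Image(m.astype(np.float32), affine),
                 str(path) + "_mag.nii")
    sidecar = {"venc_cm_s": field_.venc, "phase_ms": field_.phase_ms,
               "voxel_mm": list(field_.voxel_mm),
               "origin_mm": list(field_.origin_mm)}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_velocity_field(path: str) -> VelocityField:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    img = nib.load(str(path) + ".nii")
    arr = np.transpose(np.asarray(img.dataobj), (3, 2, 1, 0, 4))
    mag = None
    mag_path = Path(str(path) + "_mag.nii")
    if mag_path.exists():
        mag = np.transpose(np.asarray(nib.load(str(mag_path)).dataobj),
                           (2, 1, 0))
    return VelocityField(arr, tuple(sidecar["voxel_mm"]), sidecar["phase_ms"],
                         sidecar["venc_cm_s"], mag=mag,
                         origin_mm=tuple(sidecar["origin_mm"]))


def save_contours(stack: ContourStack, path: str) -> None:
    """Contour JSON: records of {phase, slice_index, z_mm, points_mm}."""
    records = []
    for t in range(stack.n_phases):
        for s, poly in enumerate(stack.contours[t]):
            if poly is None:
                continue
            records.append({"phase": t, "slice_index": s,
                            "z_mm": float(stack.slice_z_mm[s]),
                            "points_mm": np.asarray(poly).tolist()})
    doc = {"n_phases": stack.n_phases,
           "slice_z_mm": stack.slice_z_mm.tolist(),
           "slice_thickness_mm": stack.slice_thickness_mm,
           "contours": records}
    Path(path).write_text(json.dumps(doc))


def load_contours(path: str) -> ContourStack:
    doc = json.loads(Path(path).read_text())
    zs = doc["slice_z_mm"]
    contours = [[None] * len(zs) for _ in range(doc["n_phases"])]
    for rec in doc["contours"]:
        contours[rec["phase"]][rec["slice_index"]] = np.asarray(
            rec["points_mm"], dtype=float)
    return ContourStack(contours, np.asarray(zs),
                        doc["slice_thickness_mm"], doc["n_phases"])


def save_masks(masks: np.ndarray, voxel_mm, path: str) -> None:
    affine = np.diag(list(voxel_mm) + [1.0])
    arr = np.transpose(masks.astype(np.uint8), (3, 2, 1, 0))
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def save_json(obj, path: str) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_default))
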