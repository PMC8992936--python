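"""File formats: MetaImage/NIfTI volumes, JSON structures and
transforms, CSV registration tables, optional DICOM RTSTRUCT reading.

All coordinates are persisted in mm on the package's LPS-like patient
axes; structure JSON preserves contour point order exactly, which the
index-correspondence distance metric requires.
"""
from __future__ import annotations

import json
import os
from typing import Optional

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .core import VolumeImage, StructureSet, DisplacementField
from .errors import ValidationError
from .geometry import SixDoF, RigidMatrix, PairedRegResult

CSV_COLUMNS = ["case", "observer", "reference", "tx", "ty", "tz", "pitch", "yaw", "roll"]


def _require(path: str) -> None:
    if not os.path.exists(path):
        raise ValidationError(f"file not found: {path}")


# --------------------------------------------------------------------------
# volumes and displacement fields


def write_volume(vol: VolumeImage, path: str) -> None:
    """Write as MetaImage (.mha/.mhd) or NIfTI (.nii/.nii.gz).

    The array axis order (x, y, z) is transposed to the (z, y, x) order
    the ITK bridge expects; dtype is preserved so integer HU volumes
    round-trip bit-exactly.
    """
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    sitk.WriteImage(img, path)


def read_volume(path: str) -> VolumeImage:
    _require(path)
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as e:
        raise ValidationError(f"cannot read volume {path!r}: {e}") from e
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 3:
        raise ValidationError(f"{path!r} is not a 3D scalar volume")
    return VolumeImage(arr.transpose(2, 1, 0), img.GetSpacing(), img.GetOrigin())


def write_displacement_field(field: DisplacementField, path: str) -> None:
    arr = np.ascontiguousarray(field.vectors.transpose(2, 1, 0, 3))
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetSpacing(tuple(float(s) for s in field.spacing))
    img.SetOrigin(tuple(float(o) for o in field.origin))
    sitk.WriteImage(img, path)


def read_displacement_field(path: str) -> DisplacementField:
    _require(path)
    img = sitk.ReadImage(path)
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 4 or arr.shape[3] != 3:
        raise ValidationError(f"{path!r} is not a 3-component vector volume")
    return DisplacementField(arr.transpose(2, 1, 0, 3), img.GetSpacing(), img.GetOrigin())


# --------------------------------------------------------------------------
# structure sets


def write_structure(s: StructureSet, path: str) -> None:
    doc = {
        "name": s.name,
        "contours": [c.tolist() for c in s.contours],
    }
    with open(path, "w") as f:
        json.dump(doc, f)


def read_structure(path: str) -> StructureSet:
    _require(path)
    with open(path) as f:
        try:
            doc = json.load(f)
        except json.JSONDecodeError as e:
            raise ValidationError(f"invalid JSON in {path!r}: {e}") from e
    if not isinstance(doc, dict) or "contours" not in doc:
        raise ValidationError(f"{path!r}: missing key $.contours")
    contours = doc["contours"]
    if not isinstance(contours, list):
        raise ValidationError(f"{path!r}: $.contours must be a list")
    arrays = []
    for i, c in enumerate(contours):
        try:
            arr = np.asarray(c, dtype=float)
        except (TypeError, ValueError) as e:
            raise ValidationError(f"{path!r}: $.contours[{i}] is not numeric") from e
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValidationError(
                f"{path!r}: $.contours[{i}] must be a list of [x, y, z] triples"
            )
        arrays.append(arr)
    try:
        return StructureSet(str(doc.get("name", "structure")), arrays)
    except ValidationError as e:
        raise ValidationError(f"{path!r}: {e}") from e


def read_structure_dicom(path: str, roi_name: Optional[str] = None) -> StructureSet:
    """Optional adapter: read one ROI from a DICOM RTSTRUCT file.

    Contour points are taken verbatim from each ContourData triple list
    (DICOM patient coordinates, mm), preserving order.
    """
    import pydicom

    _require(path)
    ds = pydicom.dcmread(path)
    if not hasattr(ds, "ROIContourSequence") or not hasattr(ds, "StructureSetROISequence"):
        raise ValidationError(f"{path!r} is not an RT Structure Set")
    names = {roi.ROINumber: roi.ROIName for roi in ds.StructureSetROISequence}
    for rc in ds.ROIContourSequence:
        name = names.get(rc.ReferencedROINumber, "structure")
        if roi_name is not None and name != roi_name:
            continue
        contours = []
        for item in getattr(rc, "ContourSequence", []):
            data = np.asarray(item.ContourData, dtype=float).reshape(-1, 3)
            contours.append(data)
        return StructureSet(name, contours)
    raise ValidationError(f"ROI {roi_name!r} not found in {path!r}")


# --------------------------------------------------------------------------
# transforms and registration tables


def write_sixdof(p: SixDoF, path: str, extra: Optional[dict] = None) -> None:
    doc = {
        "tx": p.tx, "ty": p.ty, "tz": p.tz,
        "pitch": p.pitch, "yaw": p.yaw, "roll": p.roll,
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as f:
        json.dump(doc, f, indent=1)


def read_sixdof(path: str) -> SixDoF:
    _require(path)
    with open(path) as f:
        doc = json.load(f)
    try:
        return SixDoF(**{k: float(doc[k]) for k in ("tx", "ty", "tz", "pitch", "yaw", "roll")})
    except KeyError as e:
        raise ValidationError(f"{path!r}: missing transform key {e}") from e


def write_matrix(m: RigidMatrix, path: str) -> None:
    with open(path, "w") as f:
        json.dump(
            {"matrix": m.matrix.tolist(), "rotation_center": m.rotation_center.tolist()},
            f,
        )


def read_matrix(path: str) -> RigidMatrix:
    _require(path)
    with open(path) as f:
        doc = json.load(f)
    return RigidMatrix(np.asarray(doc["matrix"]), np.asarray(doc["rotation_center"]))


def paired_results_to_frame(results: list[PairedRegResult]) -> pd.DataFrame:
    """Long CSV layout: one row per (case, observer, reference)."""
    rows = []
    for r in results:
        for ref, p in (("ct", r.ct), ("sct", r.sct)):
            rows.append(
                [r.case, r.observer, ref, p.tx, p.ty, p.tz, p.pitch, p.yaw, p.roll]
            )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def frame_to_paired_results(df: pd.DataFrame, modality: str = "2D-orth") -> list[PairedRegResult]:
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"registration table missing columns {sorted(missing)}")
    out = []
    keys = ["case", "observer"]
    for (case, obs), grp in df.groupby(keys, dropna=False, sort=True):
        byref = {}
        for ref, sub in grp.groupby("reference"):
            row = sub.iloc[0]
            byref[ref] = SixDoF(
                row.tx, row.ty, row.tz, row.pitch, row.yaw, row.roll
            )
        if "ct" not in byref or "sct" not in byref:
            raise ValidationError(
                f"case {case} observer {obs}: missing ct or sct reference row"
            )
        obs_val = None if pd.isna(obs) else int(obs)
        out.append(
            PairedRegResult(
                case=int(case), ct=byref["ct"], sct=byref["sct"],
                observer=obs_val, modality=modality,
            )
        )
    return out


def read_paired_results(path: str, modality: str = "2D-orth") -> list[PairedRegResult]:
    _require(path)
    return frame_to_paired_results(pd.read_csv(path), modality=modality)


def write_paired_results(results: list[PairedRegResult], path: str) -> None:
    paired_results_to_frame(results).to_csv(path, index=False)
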