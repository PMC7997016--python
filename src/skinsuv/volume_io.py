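"""Volume, landmark and subject-table I/O.

NIfTI-1 is the canonical on-disk format; DICOM series are supported
read-only and converted to the internal :class:`~skinsuv.core.Volume`.
Volumes are reoriented to the RAS patient convention on load so that the
cranio-caudal axis is explicit and region border planes are axis-aligned.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import Landmarks, Mask, Plane, RegionLabelMap, SubjectMeta, ValidationError, Volume

log = logging.getLogger(__name__)

#: Acquisition geometry of the emulated scanner: 600 mm transaxial FOV
#: reconstructed on a 192 x 192 matrix.
TRANSAXIAL_FOV_MM = 600.0
MATRIX_SIZE = 192
AXIAL_SPACING_MM = 2.809


def inplane_voxel_mm(fov_mm: float = TRANSAXIAL_FOV_MM, matrix: int = MATRIX_SIZE) -> float:
    """In-plane voxel size implied by the transaxial FOV and matrix."""
    return fov_mm / matrix


#: Registration tolerance for spacing/origin comparisons, mm.
REGISTRATION_TOL_MM = 1e-3

_UNIT_FACTORS = {
    "bq": 1.0, "kbq": 1e3, "mbq": 1e6, "gbq": 1e9,
    "g": 1.0, "kg": 1e3,
    "cm": 1.0, "m": 100.0,
    "years": 1.0, "y": 1.0, "yr": 1.0, "": 1.0,
}


# ---------------------------------------------------------------------------
# NIfTI / DICOM volumes

def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1; the value-semantics tag goes in ``descrip``."""
    path = Path(path)
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = vol.spacing
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), affine)
    img.header["descrip"] = f"kind={vol.kind}".encode()
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path, kind: str | None = None) -> Volume:
    """Read a NIfTI-1 volume (or a DICOM series directory) into RAS orientation.

    Parameters
    ----------
    path
        A NIfTI file, or a directory containing one DICOM series.
    kind
        Override for the value-semantics tag; otherwise taken from the
        NIfTI ``descrip`` field (default "activity").
    """
    path = Path(path)
    if path.is_dir():
        return read_dicom_series(path, kind=kind or "activity")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - surface as I/O error
        raise IOError(f"cannot read volume {path}: {exc}") from exc
    if img.ndim != 3:
        raise ValidationError(f"{path}: expected a 3D volume, got ndim={img.ndim}")
    img = nib.as_closest_canonical(img)  # reorient to RAS
    affine = img.affine
    rot = affine[:3, :3]
    if np.abs(rot - np.diag(np.diag(rot))).max() > 1e-6:
        raise ValidationError(f"{path}: oblique volumes are not supported")
    spacing = tuple(float(s) for s in np.diag(rot))
    if any(s <= 0 for s in spacing):
        raise ValidationError(f"{path}: missing or nonpositive voxel spacing {spacing}")
    if kind is None:
        descrip = img.header["descrip"].tobytes().split(b"\x00")[0].decode(errors="ignore")
        kind = descrip.removeprefix("kind=") if descrip.startswith("kind=") else "activity"
    data = np.asarray(img.dataobj, dtype=np.float64)
    origin = tuple(float(o) for o in affine[:3, 3])
    return Volume(data, spacing, origin, ("R", "A", "S"), kind)


def read_dicom_series(directory: str | Path, kind: str = "activity") -> Volume:
    """Read one axis-aligned DICOM series from a directory (read-only support).

    DICOM stores slices in LPS patient coordinates; the volume is
    converted to the internal RAS convention by flipping the first two
    axes.  Oblique series are rejected.
    """
    import SimpleITK as sitk

    directory = Path(directory)
    reader = sitk.ImageSeriesReader()
    names = reader.GetGDCMSeriesFileNames(str(directory))
    if not names:
        raise IOError(f"no DICOM series found in {directory}")
    reader.SetFileNames(names)
    img = reader.Execute()
    direction = np.array(img.GetDirection()).reshape(3, 3)
    if np.abs(direction - np.eye(3)).max() > 1e-6:
        raise ValidationError(f"{directory}: oblique DICOM series are not supported")
    # sitk arrays are (z, y, x); transpose to (x, y, z), then LPS -> RAS
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.float64)
    data = data[::-1, ::-1, :].copy()
    spacing = tuple(float(s) for s in img.GetSpacing())
    lps_origin = np.array(img.GetOrigin())
    shape = data.shape
    origin = (-(lps_origin[0] + (shape[0] - 1) * spacing[0]),
              -(lps_origin[1] + (shape[1] - 1) * spacing[1]),
              float(lps_origin[2]))
    return Volume(data, spacing, origin, ("R", "A", "S"), kind)


def write_label_map(labels: RegionLabelMap, path: str | Path) -> Path:
    vol = Volume(labels.labels.astype(np.int16), labels.spacing, labels.origin,
                 ("R", "A", "S"), "label")
    return write_volume(vol, path)


def write_mask(mask: Mask, path: str | Path) -> Path:
    vol = Volume(mask.data.astype(np.int16), mask.spacing, mask.origin,
                 ("R", "A", "S"), "label")
    return write_volume(vol, path)


# ---------------------------------------------------------------------------
# Lattice compatibility

@dataclass(frozen=True)
class RegistrationReport:
    """Outcome of a lattice-compatibility check between two volumes."""

    ok: bool
    mismatches: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.ok


def check_registration(a: Volume | Mask, b: Volume | Mask,
                       tol_mm: float = REGISTRATION_TOL_MM) -> RegistrationReport:
    """Check that two volumes share one lattice (shape, spacing, origin, orientation).

    Simultaneous PET/MRI acquisition yields intrinsically co-registered
    volumes, so any mismatch is an input error rather than something to
    resample away.
    """
    mismatches: list[str] = []
    if a.shape != b.shape:
        mismatches.append(f"shape: {a.shape} != {b.shape}")
    for name in ("spacing", "origin"):
        va, vb = np.array(getattr(a, name)), np.array(getattr(b, name))
        if np.abs(va - vb).max() > tol_mm:
            mismatches.append(f"{name}: {tuple(va)} != {tuple(vb)}")
    oa = getattr(a, "orientation", ("R", "A", "S"))
    ob = getattr(b, "orientation", ("R", "A", "S"))
    if tuple(oa) != tuple(ob):
        mismatches.append(f"orientation: {oa} != {ob}")
    return RegistrationReport(not mismatches, tuple(mismatches))


def require_registered(a: Volume | Mask, b: Volume | Mask) -> None:
    report = check_registration(a, b)
    if not report:
        raise ValidationError("volumes are not on one lattice: " + "; ".join(report.mismatches))


# ---------------------------------------------------------------------------
# Landmarks

def write_landmarks(landmarks: Landmarks, path: str | Path) -> Path:
    path = Path(path)
    payload: dict = {
        name: {"axis": p.axis, "offset_mm": p.offset_mm}
        for name, p in (("ear_canal", landmarks.ear_canal), ("mid_arm", landmarks.mid_arm),
                        ("t12", landmarks.t12), ("neck", landmarks.neck))
    }
    if landmarks.liver_cubes_mm is not None:
        payload["liver_cubes_mm"] = [list(c) for c in landmarks.liver_cubes_mm]
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_landmarks(path: str | Path) -> Landmarks:
    path = Path(path)
    if not path.exists():
        raise IOError(f"landmarks file not found: {path}")
    payload = json.loads(path.read_text())
    planes = {}
    for name in ("ear_canal", "mid_arm", "t12", "neck"):
        if name not in payload:
            raise ValidationError(f"{path}: missing landmark plane {name!r}")
        planes[name] = Plane(payload[name]["axis"], float(payload[name]["offset_mm"]))
    cubes = payload.get("liver_cubes_mm")
    return Landmarks(**planes,
                     liver_cubes_mm=tuple(tuple(c) for c in cubes) if cubes else None)


# ---------------------------------------------------------------------------
# Subject tables

#: Canonical columns of the subject table and default units.
_REQUIRED_COLUMNS = ("subject_id", "exam_id", "dose", "weight")
_NUMERIC_COLUMNS = {"dose": "dose_bq", "weight": "weight_g", "height": "height_cm",
                    "age": "age_yr"}
_TARGET_UNITS = {"dose": "bq", "weight": "g", "height": "cm", "age": "years"}


def read_subject_table(path: str | Path) -> list[SubjectMeta]:
    """Read per-exam subject metadata from CSV.

    The CSV carries a units row directly under the header (e.g. dose in
    MBq, weight in kg); values are coerced to Bq / g / cm on load.
    Records missing dose or weight are collected and reported together
    with their row numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        log.warning("subject table %s is empty", path)
        return []
    missing_cols = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing columns {missing_cols}")

    units = {c: "" for c in df.columns}
    first = df.iloc[0]
    if _is_units_row(first):
        units.update({c: str(first[c]).strip().lower() for c in df.columns
                      if isinstance(first[c], str)})
        df = df.iloc[1:].reset_index(drop=True)
        row_offset = 3  # header + units row + 1-based
    else:
        row_offset = 2

    records: list[SubjectMeta] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        vals: dict = {"subject_id": row["subject_id"], "exam_id": row["exam_id"]}
        bad = False
        for col, target in _NUMERIC_COLUMNS.items():
            if col not in df.columns or pd.isna(row[col]) or str(row[col]).strip() == "":
                if col in ("dose", "weight"):
                    errors.append(f"row {i + row_offset}: missing {col}")
                    bad = True
                continue
            factor = _unit_factor(units.get(col, ""), col, path)
            target_factor = _UNIT_FACTORS[_TARGET_UNITS[col]]
            vals[target] = float(row[col]) * factor / target_factor
        if "sex" in df.columns and isinstance(row.get("sex"), str) and row["sex"].strip():
            vals["sex"] = row["sex"].strip().upper()[0]
        if "exam_date" in df.columns and isinstance(row.get("exam_date"), str):
            vals["exam_date"] = row["exam_date"]
        if bad:
            continue
        try:
            records.append(SubjectMeta(**vals))
        except ValidationError as exc:
            errors.append(f"row {i + row_offset}: {exc}")
    if errors:
        raise ValidationError(f"{path}: invalid subject records: " + "; ".join(errors))
    if not records:
        warnings.warn(f"{path}: no subject records parsed", stacklevel=2)
    return records


def _is_units_row(row: pd.Series) -> bool:
    for col in _NUMERIC_COLUMNS:
        if col in row.index and isinstance(row[col], str):
            token = row[col].strip().lower()
            if token and not _is_number(token):
                return True
    return False


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _unit_factor(unit: str, col: str, path: Path) -> float:
    unit = unit.strip().lower()
    if unit not in _UNIT_FACTORS:
        raise ValidationError(f"{path}: unknown unit {unit!r} for column {col!r}")
    return _UNIT_FACTORS[unit]


def write_subject_table(metas: list[SubjectMeta], path: str | Path) -> Path:
    """Write subject metadata as CSV in canonical units (Bq, g, cm)."""
    path = Path(path)
    rows = [{
        "subject_id": m.subject_id, "exam_id": m.exam_id, "dose": m.dose_bq,
        "weight": m.weight_g, "height": m.height_cm, "sex": m.sex,
        "age": m.age_yr, "exam_date": m.exam_date,
    } for m in metas]
    df = pd.DataFrame(rows)
    units = pd.DataFrame([{"subject_id": "", "exam_id": "", "dose": "Bq", "weight": "g",
                           "height": "cm", "sex": "", "age": "years", "exam_date": ""}])
    pd.concat([units, df], ignore_index=True).to_csv(path, index=False)
    return path
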