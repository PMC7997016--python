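"""Core containers for skin PET quantification.

Volumes live on an axis-aligned lattice in patient (RAS) coordinates:
index axis 0 runs left->right (R), axis 1 posterior->anterior (A) and
axis 2 inferior->superior (S).  World coordinates are voxel-center based
and 0-indexed: world = origin + index * spacing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "GeometryError",
    "ValidationError",
    "SegmentationError",
    "Region",
    "REGION_NAMES",
    "Volume",
    "Mask",
    "RegionLabelMap",
    "Plane",
    "Landmarks",
    "SubjectMeta",
    "AXIS_INDEX",
]


class GeometryError(ValueError):
    """Phantom or VOI geometry is inconsistent (organ outside body, empty body...)."""


class ValidationError(ValueError):
    """Input records or parameters fail validation."""


class SegmentationError(RuntimeError):
    """A segmentation stage produced an empty or invalid mask."""


class Region(IntEnum):
    """Skin-region labels of the five-region partition."""

    BACKGROUND = 0
    FACE = 1
    SCALP = 2
    CHEST = 3
    ABDOMEN = 4
    BACK = 5


REGION_NAMES: tuple[str, ...] = ("face", "scalp", "chest", "abdomen", "back")

AXIS_INDEX: Mapping[str, int] = {"x": 0, "y": 1, "z": 2}

_RAS = ("R", "A", "S")


def _as_float3(v: Iterable[float]) -> tuple[float, float, float]:
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ValidationError(f"expected 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class Volume:
    """A 3D scalar grid with voxel spacing, origin and orientation.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values.
    spacing : (3,) float
        Voxel edge length along each axis, mm.
    origin : (3,) float
        World coordinate of the center of voxel (0, 0, 0), mm.
    orientation : tuple of str
        Axis direction codes; only the right-handed RAS convention is
        used internally.
    kind : {"attenuation", "activity", "label"}
        Value semantics; activity volumes are in Bq/mL.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (3.125, 3.125, 2.809)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: tuple[str, str, str] = _RAS
    kind: str = "activity"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"volume must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValidationError("volume must have at least 1 voxel per axis")
        self.spacing = _as_float3(self.spacing)
        self.origin = _as_float3(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        self.orientation = tuple(self.orientation)  # type: ignore[assignment]
        if not _right_handed(self.orientation):
            raise ValidationError(f"orientation {self.orientation} is not right-handed")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis (mm)."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable world-coordinate grids (mm) for all three axes."""
        cx, cy, cz = (self.axis_coords(a) for a in range(3))
        return cx[:, None, None], cy[None, :, None], cz[None, None, :]

    def like(self, data: np.ndarray, kind: str | None = None) -> "Volume":
        """A new volume on this lattice with different values."""
        return Volume(data, self.spacing, self.origin, self.orientation,
                      kind if kind is not None else self.kind)


def _right_handed(orientation: tuple[str, str, str]) -> bool:
    units = {"R": (1, 0, 0), "L": (-1, 0, 0), "A": (0, 1, 0),
             "P": (0, -1, 0), "S": (0, 0, 1), "I": (0, 0, -1)}
    try:
        m = np.array([units[c] for c in orientation], dtype=float)
    except KeyError:
        return False
    return abs(np.linalg.det(m) - 1.0) < 1e-9


@dataclass
class Mask:
    """A binary VOI on a Volume's lattice."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tag: str = "body"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValidationError(f"mask must be 3D, got ndim={arr.ndim}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.isin(uniq, (0, 1)).all():
                raise ValidationError("mask values must be binary")
            arr = arr.astype(bool)
        self.data = arr
        self.spacing = _as_float3(self.spacing)
        self.origin = _as_float3(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def count(self) -> int:
        return int(self.data.sum())

    def like(self, data: np.ndarray, tag: str | None = None) -> "Mask":
        return Mask(data, self.spacing, self.origin, tag if tag is not None else self.tag)

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    @classmethod
    def from_volume(cls, vol: Volume, data: np.ndarray, tag: str = "body") -> "Mask":
        if data.shape != vol.shape:
            raise ValidationError("mask shape differs from parent volume")
        return cls(data, vol.spacing, vol.origin, tag)


@dataclass
class RegionLabelMap:
    """Integer region label per voxel; nonzero labels only on shell voxels."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    legend: Mapping[int, str] = field(
        default_factory=lambda: {int(r): r.name.lower() for r in Region})

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int16)
        if self.labels.ndim != 3:
            raise ValidationError("label map must be 3D")
        self.spacing = _as_float3(self.spacing)
        self.origin = _as_float3(self.origin)

    def region_mask(self, region: Region | int) -> np.ndarray:
        return self.labels == int(region)

    def region_mask_by_name(self, name: str) -> np.ndarray:
        return self.labels == int(Region[name.upper()])

    @property
    def shell_mask(self) -> np.ndarray:
        return self.labels != 0

    def counts(self) -> dict[str, int]:
        return {name: int((self.labels == int(Region[name.upper()])).sum())
                for name in REGION_NAMES}


@dataclass(frozen=True)
class Plane:
    """An axis-aligned plane in world coordinates: {p : p[axis] = offset_mm}."""

    axis: str
    offset_mm: float

    def __post_init__(self) -> None:
        if self.axis not in AXIS_INDEX:
            raise ValidationError(f"plane axis must be one of x/y/z, got {self.axis!r}")

    @property
    def axis_index(self) -> int:
        return AXIS_INDEX[self.axis]


@dataclass(frozen=True)
class Landmarks:
    """Anatomical planes bounding the five skin regions.

    ``ear_canal`` and ``mid_arm`` are coronal planes (axis "y"); ``t12``
    (lower end of the 12th thoracic vertebra) and ``neck`` are axial
    planes (axis "z").  The neck plane separates head from trunk and must
    lie caudal to the ear-canal structures, i.e. between the trunk and
    the T12 plane along z.
    """

    ear_canal: Plane
    mid_arm: Plane
    t12: Plane
    neck: Plane
    liver_cubes_mm: tuple[tuple[float, float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.ear_canal.axis != "y" or self.mid_arm.axis != "y":
            raise ValidationError("ear_canal and mid_arm must be coronal (axis 'y') planes")
        if self.t12.axis != "z" or self.neck.axis != "z":
            raise ValidationError("t12 and neck must be axial (axis 'z') planes")
        if not self.neck.offset_mm > self.t12.offset_mm:
            raise ValidationError("neck plane must be cranial to the T12 plane")


@dataclass(frozen=True)
class SubjectMeta:
    """Per-exam subject metadata used for SUV normalization and grouping."""

    subject_id: str
    exam_id: str
    dose_bq: float
    weight_g: float
    height_cm: float | None = None
    sex: str | None = None  # "M" | "F"
    age_yr: float | None = None
    exam_date: str | None = None

    def __post_init__(self) -> None:
        if not self.dose_bq > 0:
            raise ValidationError(f"injected dose must be > 0, got {self.dose_bq}")
        if not self.weight_g > 0:
            raise ValidationError(f"body weight must be > 0, got {self.weight_g}")
        if self.height_cm is not None and not self.height_cm > 0:
            raise ValidationError(f"height must be > 0, got {self.height_cm}")
        if self.sex is not None and self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.age_yr is not None and self.age_yr < 0:
            raise ValidationError("age must be >= 0")

    @property
    def bmi(self) -> float | None:
        if self.height_cm is None:
            return None
        h_m = self.height_cm / 100.0
        return (self.weight_g / 1000.0) / (h_m * h_m)

    def replace(self, **kw) -> "SubjectMeta":
        return dataclasses.replace(self, **kw)
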