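"""SUV computation and per-region uptake statistics.

SUV = tissue activity [Bq/mL] / (injected dose [Bq] / body weight [g]),
the dimensionless g/mL convention.  Lean-body-mass (James) and
body-surface-area (Du Bois) normalizations are provided alongside; the
liver reference averages three 15-mm cubes placed in normal liver.
Activity volumes are taken as already decay-corrected by the scanner
(standard DICOM PET semantics); no time term appears.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import REGION_NAMES, RegionLabelMap, SubjectMeta, ValidationError, Volume
from .volume_io import require_registered

NORMALIZATIONS = ("bw", "lbm", "bsa")


# ---------------------------------------------------------------------------
# Normalization constants

def lbm_james_kg(weight_kg: float, height_cm: float, sex: str) -> float:
    """Lean body mass by the James equations (kg)."""
    if sex not in ("M", "F"):
        raise ValidationError(f"sex must be 'M' or 'F' for lbm, got {sex!r}")
    if not (weight_kg > 0 and height_cm > 0):
        raise ValidationError("weight and height must be positive")
    ratio2 = (weight_kg / height_cm) ** 2
    if sex == "M":
        return 1.10 * weight_kg - 128.0 * ratio2
    return 1.07 * weight_kg - 148.0 * ratio2


def bsa_dubois_m2(weight_kg: float, height_cm: float) -> float:
    """Body surface area by Du Bois and Du Bois (m^2)."""
    if not (weight_kg > 0 and height_cm > 0):
        raise ValidationError("weight and height must be positive")
    return 0.007184 * weight_kg**0.425 * height_cm**0.725


# ---------------------------------------------------------------------------
# SUV

def suv_bw(activity_bq_ml, dose_bq: float, weight_g: float):
    """Body-weight SUV: activity / (dose / weight)."""
    if not dose_bq > 0:
        raise ValidationError(f"dose must be > 0, got {dose_bq}")
    if not weight_g > 0:
        raise ValidationError(f"weight must be > 0, got {weight_g}")
    activity = np.asarray(activity_bq_ml, dtype=np.float64)
    if (activity < 0).any():
        raise ValidationError("activity must be >= 0")
    out = activity / (dose_bq / weight_g)
    return float(out) if np.isscalar(activity_bq_ml) else out


def suv_lbm(activity_bq_ml, dose_bq: float, weight_g: float, height_cm: float, sex: str):
    """SUV normalized by James lean body mass instead of total weight."""
    lbm_g = lbm_james_kg(weight_g / 1000.0, height_cm, sex) * 1000.0
    if not lbm_g > 0:
        raise ValidationError("James LBM is nonpositive for these inputs")
    return suv_bw(activity_bq_ml, dose_bq, lbm_g)


def suv_bsa(activity_bq_ml, dose_bq: float, weight_g: float, height_cm: float):
    """SUV normalized by Du Bois body surface area (x 10^4 scaling to cm^2)."""
    bsa_cm2 = bsa_dubois_m2(weight_g / 1000.0, height_cm) * 1e4
    return suv_bw(activity_bq_ml, dose_bq, bsa_cm2)


def normalization_constant_g(meta: SubjectMeta, normalization: str) -> float:
    """The mass-like constant (g or cm^2) dividing the dose for one normalization."""
    if normalization == "bw":
        return meta.weight_g
    if normalization == "lbm":
        if meta.sex is None or meta.height_cm is None:
            raise ValidationError("lbm normalization needs sex and height")
        return lbm_james_kg(meta.weight_g / 1000.0, meta.height_cm, meta.sex) * 1000.0
    if normalization == "bsa":
        if meta.height_cm is None:
            raise ValidationError("bsa normalization needs height")
        return bsa_dubois_m2(meta.weight_g / 1000.0, meta.height_cm) * 1e4
    raise ValidationError(f"unknown normalization {normalization!r}")


# ---------------------------------------------------------------------------
# Region statistics

@dataclass
class RegionSUV:
    """Per-region SUVmean/SUVmax for one exam under each normalization.

    ``stats[normalization][region]`` is ``(suvmean, suvmax, n_voxels)``;
    empty regions carry NaN means/maxima (never zeros) so they drop out
    of group statistics instead of biasing them.
    """

    exam_id: str
    stats: Mapping[str, Mapping[str, tuple[float, float, int]]]
    liver_suvmean: float | None = None
    liver_suvmax: float | None = None
    constants_g: Mapping[str, float] = field(default_factory=dict)

    def suvmean(self, region: str, normalization: str = "bw") -> float:
        return self.stats[normalization][region][0]

    def suvmax(self, region: str, normalization: str = "bw") -> float:
        return self.stats[normalization][region][1]

    def n_voxels(self, region: str) -> int:
        first = next(iter(self.stats.values()))
        return first[region][2]

    def to_frame(self) -> pd.DataFrame:
        """Long-format rows: exam, region, normalization, suvmean, suvmax, n_voxels."""
        rows = []
        for norm, regions in self.stats.items():
            for region, (mean, mx, n) in regions.items():
                rows.append({"exam_id": self.exam_id, "region": region,
                             "normalization": norm, "suvmean": mean, "suvmax": mx,
                             "n_voxels": n})
        df = pd.DataFrame(rows)
        if self.liver_suvmean is not None:
            df = pd.concat([df, pd.DataFrame([{
                "exam_id": self.exam_id, "region": "liver", "normalization": "bw",
                "suvmean": self.liver_suvmean, "suvmax": self.liver_suvmax,
                "n_voxels": 0}])], ignore_index=True)
        return df


def region_suv_stats(
    pet: Volume,
    labels: RegionLabelMap,
    meta: SubjectMeta,
    normalizations: Sequence[str] = NORMALIZATIONS,
) -> RegionSUV:
    """Per-region SUVmean/SUVmax over the labeled skin shell.

    The "overall" region is the union of the five named regions, so its
    voxel count is the sum of the regional counts and its SUVmax the
    maximum of the regional maxima.
    """
    require_registered(pet, labels_as_volume(labels))
    activity = np.asarray(pet.data, dtype=np.float64)
    constants = {}
    for norm in normalizations:
        try:
            constants[norm] = normalization_constant_g(meta, norm)
        except ValidationError:
            if norm == "bw":
                raise
            continue

    region_masks = {name: labels.region_mask_by_name(name) for name in REGION_NAMES}
    region_masks["overall"] = labels.shell_mask

    stats: dict[str, dict[str, tuple[float, float, int]]] = {}
    for norm, const in constants.items():
        factor = const / meta.dose_bq  # SUV = activity * weight/dose
        per_region = {}
        for name, mask in region_masks.items():
            n = int(mask.sum())
            if n == 0:
                warnings.warn(f"region {name!r} is empty for exam {meta.exam_id}; "
                              "recording missing values", stacklevel=2)
                per_region[name] = (float("nan"), float("nan"), 0)
                continue
            vals = activity[mask] * factor
            per_region[name] = (float(vals.mean()), float(vals.max()), n)
        stats[norm] = per_region
    return RegionSUV(meta.exam_id, stats, constants_g=constants)


def labels_as_volume(labels: RegionLabelMap) -> Volume:
    return Volume(labels.labels, labels.spacing, labels.origin, ("R", "A", "S"), "label")


# ---------------------------------------------------------------------------
# Liver reference

def liver_reference(
    pet: Volume,
    cube_centers_mm: Sequence[Sequence[float]],
    meta: SubjectMeta,
    edge_mm: float = 15.0,
) -> tuple[float, float]:
    """Liver reference SUV from three identical 15-mm cubes.

    Each cube is the axis-aligned box of voxels whose centers fall
    inside an ``edge_mm`` cube around the given world point.  Returns
    (mean of the three cube means, max over the three cubes).
    """
    if len(cube_centers_mm) != 3:
        raise ValidationError(f"expected 3 cube centers, got {len(cube_centers_mm)}")
    half = edge_mm / 2.0
    activity = np.asarray(pet.data, dtype=np.float64)
    coords = [pet.axis_coords(a) for a in range(3)]
    means, maxes = [], []
    for center in cube_centers_mm:
        slices = []
        for a in range(3):
            lo, hi = center[a] - half, center[a] + half
            if lo < coords[a][0] - pet.spacing[a] / 2 or hi > coords[a][-1] + pet.spacing[a] / 2:
                raise ValidationError(
                    f"liver cube at {tuple(center)} mm extends outside the volume")
            inside = np.nonzero((coords[a] >= lo) & (coords[a] <= hi))[0]
            if inside.size == 0:
                raise ValidationError(f"liver cube at {tuple(center)} mm contains no voxels")
            slices.append(slice(inside[0], inside[-1] + 1))
        cube = activity[tuple(slices)]
        means.append(float(cube.mean()))
        maxes.append(float(cube.max()))
    factor = meta.weight_g / meta.dose_bq
    return float(np.mean(means)) * factor, float(np.max(maxes)) * factor
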