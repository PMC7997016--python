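"""Digital body phantoms with known skin-uptake ground truth.

The phantom is a stacked-ellipsoid body (head sphere + trunk ellipsoid +
arms-down cylinders) on the scanner lattice (3.125 x 3.125 x 2.809 mm),
with internal hot organs (brain, salivary glands, liver, bladder), a
uniform low-uptake interior, and a 3-voxel-deep surface shell whose
activity is region-, sex- and age-dependent.  The attenuation map is
strictly positive on the body and exactly zero outside it, so the
downstream threshold contouring is exact.  Landmark planes are emitted
analytically; landmark detection is out of scope.

Dosing follows 3.5 MBq/kg, which makes dose/weight = 3500 Bq/g for every
subject, so a noise-free voxel of activity ``a`` has SUV ``a / 3500``
exactly — the analytic ground truth the acceptance checks rely on.

The forward model is deliberately simple PET: voxelwise multiplicative
Gaussian noise with a stated CV plus an exam-level lognormal scale for
repeat scans.  No scatter, randoms, point-spread blur or motion.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .core import (
    GeometryError,
    Landmarks,
    Mask,
    Plane,
    Region,
    REGION_NAMES,
    RegionLabelMap,
    SubjectMeta,
    ValidationError,
    Volume,
)
from .segmentation import classify_region_planes

log = logging.getLogger(__name__)

#: FDG dosing: 3.5 MBq per kg body weight -> dose/weight = 3500 Bq/g.
DOSE_BQ_PER_G = 3500.0
#: Linear attenuation of soft tissue at 511 keV, cm^-1.
BODY_MU = 0.096

DECADES = ("0-9", "10-19", "20-29", "30-39", "40-49", "50-59", "60-69", "70-79")
SEXES = ("M", "F")

#: Default region shell activities, Bq/mL.  At 3500 Bq/g these sit at the
#: SUV levels typical of each region (face highest, abdomen lowest).
DEFAULT_SHELL_ACTIVITY: Mapping[str, float] = {
    "face": 3.09 * DOSE_BQ_PER_G,
    "scalp": 2.07 * DOSE_BQ_PER_G,
    "chest": 1.33 * DOSE_BQ_PER_G,
    "abdomen": 1.24 * DOSE_BQ_PER_G,
    "back": 1.47 * DOSE_BQ_PER_G,
}

#: Cohort BMI medians and interquartile ranges per (sex, age decade),
#: matching the demographic structure the generator emulates.
BMI_TABLE: Mapping[tuple[str, str], tuple[float, tuple[float, float]]] = {
    ("M", "0-9"): (14.9, (13.9, 15.0)),
    ("M", "10-19"): (17.7, (13.9, 22.2)),
    ("M", "20-29"): (23.5, (20.2, 27.6)),
    ("M", "30-39"): (23.9, (19.7, 27.0)),
    ("M", "40-49"): (21.5, (19.1, 22.5)),
    ("M", "50-59"): (21.3, (19.3, 23.4)),
    ("M", "60-69"): (22.8, (21.0, 25.5)),
    ("M", "70-79"): (23.8, (21.2, 26.5)),
    ("F", "0-9"): (15.3, (15.0, 15.7)),
    ("F", "10-19"): (18.0, (13.3, 23.0)),
    ("F", "20-29"): (20.1, (19.0, 21.7)),
    ("F", "30-39"): (23.9, (19.3, 25.0)),
    ("F", "40-49"): (24.3, (20.4, 24.2)),
    ("F", "50-59"): (22.0, (19.7, 23.3)),
    ("F", "60-69"): (21.0, (19.1, 22.3)),
    ("F", "70-79"): (21.9, (18.1, 26.7)),
}

#: Typical stature per (sex, decade), cm — used to turn BMI into weight.
HEIGHT_CM: Mapping[tuple[str, str], float] = {
    ("M", "0-9"): 118, ("M", "10-19"): 160, ("M", "20-29"): 172, ("M", "30-39"): 171,
    ("M", "40-49"): 170, ("M", "50-59"): 168, ("M", "60-69"): 166, ("M", "70-79"): 163,
    ("F", "0-9"): 116, ("F", "10-19"): 155, ("F", "20-29"): 158, ("F", "30-39"): 158,
    ("F", "40-49"): 157, ("F", "50-59"): 156, ("F", "60-69"): 153, ("F", "70-79"): 150,
}

#: Face-uptake multipliers per (sex, decade) relative to the adult-male
#: level: uptake rises at puberty in both sexes, is maintained through
#: adulthood in males, and declines after menopause in females.
DEFAULT_EFFECT_TABLE: Mapping[tuple[str, str], float] = {
    ("M", "0-9"): 0.39, ("M", "10-19"): 0.59, ("M", "20-29"): 1.14, ("M", "30-39"): 1.14,
    ("M", "40-49"): 1.14, ("M", "50-59"): 1.14, ("M", "60-69"): 1.14, ("M", "70-79"): 1.10,
    ("F", "0-9"): 0.28, ("F", "10-19"): 0.88, ("F", "20-29"): 0.88, ("F", "30-39"): 1.11,
    ("F", "40-49"): 0.88, ("F", "50-59"): 0.88, ("F", "60-69"): 0.88, ("F", "70-79"): 0.67,
}

#: Face activity at effect multiplier 1 (adult male), Bq/mL.
ADULT_MALE_FACE_SUV = 3.45

#: Fraction of exams whose brain protrudes into the shell and therefore
#: needs the automated spillover exclusion (emulated adjustment rate).
DEFAULT_SPILLOVER_PROB = 0.232


@dataclass(frozen=True)
class Organ:
    """A hot internal organ: an axis-aligned ellipsoid with uniform activity."""

    name: str
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    activity_bq_ml: float

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii_mm):
            raise ValidationError(f"organ {self.name!r}: radii must be positive")
        if self.activity_bq_ml < 0:
            raise ValidationError(f"organ {self.name!r}: activity must be >= 0")


def default_organs(head_center: Sequence[float] = (100.0, 100.0, 220.0),
                   head_radius: float = 52.0,
                   brain_gap_mm: float = 20.0) -> tuple[Organ, ...]:
    """The default organ set; ``brain_gap_mm`` is the margin between the
    brain surface and the head surface (a gap smaller than the shell
    depth makes the brain protrude into the skin VOI)."""
    cx, cy, cz = head_center
    rb = head_radius - brain_gap_mm
    return (
        Organ("brain", (cx, cy, cz), (rb, rb, rb), 8.0 * DOSE_BQ_PER_G),
        Organ("salivary_l", (cx - 10, cy, cz - 20), (6, 6, 6), 4.0 * DOSE_BQ_PER_G),
        Organ("salivary_r", (cx + 10, cy, cz - 20), (6, 6, 6), 4.0 * DOSE_BQ_PER_G),
        Organ("liver", (112, 98, 128), (22, 15, 20), 2.5 * DOSE_BQ_PER_G),
        Organ("bladder", (100, 95, 35), (13, 13, 13), 10.0 * DOSE_BQ_PER_G),
    )


def small_phantom_spec(**overrides) -> PhantomSpec:
    """A half-scale phantom on a 32 x 32 x 50 grid (fast tests/simulations)."""
    organs = (
        Organ("brain", (50, 50, 110), (10, 10, 10), 8.0 * DOSE_BQ_PER_G),
        Organ("salivary_l", (47, 50, 105), (3, 3, 3), 4.0 * DOSE_BQ_PER_G),
        Organ("salivary_r", (53, 50, 105), (3, 3, 3), 4.0 * DOSE_BQ_PER_G),
        Organ("liver", (52, 50, 50), (8, 6, 8), 2.5 * DOSE_BQ_PER_G),
        Organ("bladder", (50, 49, 26), (5, 5, 5), 10.0 * DOSE_BQ_PER_G),
    )
    base = dict(
        shape=(32, 32, 50),
        head_center_mm=(50.0, 50.0, 110.0), head_radius_mm=26.0,
        trunk_center_mm=(50.0, 50.0, 44.0), trunk_radii_mm=(31.0, 22.0, 42.0),
        arm_radius_mm=6.5, arm_offset_x_mm=36.0, arm_z_mm=(10.0, 75.0),
        organs=organs, neck_z_mm=85.0, t12_z_mm=55.0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, activities and noise model of one digital phantom."""

    shape: tuple[int, int, int] = (64, 64, 100)
    spacing: tuple[float, float, float] = (3.125, 3.125, 2.809)
    head_center_mm: tuple[float, float, float] = (100.0, 100.0, 220.0)
    head_radius_mm: float = 52.0
    trunk_center_mm: tuple[float, float, float] = (100.0, 100.0, 88.0)
    trunk_radii_mm: tuple[float, float, float] = (62.0, 45.0, 84.0)
    arms: bool = True
    arm_radius_mm: float = 13.0
    arm_offset_x_mm: float = 72.0
    arm_z_mm: tuple[float, float] = (20.0, 150.0)
    shell_voxels: int = 3
    shell_activity: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SHELL_ACTIVITY))
    background_activity: float = 0.8 * DOSE_BQ_PER_G
    attenuation_value: float = BODY_MU
    organs: tuple[Organ, ...] = field(default_factory=default_organs)
    noise_cv: float = 0.05
    seed: int = 0
    # landmark planes; None -> derived from the body geometry
    neck_z_mm: float | None = 170.0
    ear_y_mm: float | None = None
    midarm_y_mm: float | None = None
    t12_z_mm: float | None = 110.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        if self.shell_voxels <= 0:
            raise ValidationError("shell thickness must be > 0 voxels")
        if self.noise_cv < 0:
            raise ValidationError("noise CV must be >= 0")
        missing = [r for r in REGION_NAMES if r not in self.shell_activity]
        if missing:
            raise ValidationError(f"shell_activity missing regions {missing}")
        if any(v < 0 for v in self.shell_activity.values()) or self.background_activity < 0:
            raise ValidationError("activities must be >= 0")

    @property
    def landmarks(self) -> Landmarks:
        hx, hy, hz = self.head_center_mm
        ty = self.trunk_center_mm[1]
        liver = next((o for o in self.organs if o.name == "liver"), None)
        cubes = None
        if liver is not None:
            lx, ly, lz = liver.center_mm
            # three separated cubes when the liver is large enough to hold
            # them; otherwise stacked at the center (half-scale phantoms)
            dx = 10.0 if liver.radii_mm[0] >= 18.0 else 0.0
            cubes = ((lx - dx, ly, lz), (lx, ly, lz), (lx + dx, ly, lz))
        return Landmarks(
            ear_canal=Plane("y", self.ear_y_mm if self.ear_y_mm is not None else hy),
            mid_arm=Plane("y", self.midarm_y_mm if self.midarm_y_mm is not None else ty),
            t12=Plane("z", self.t12_z_mm if self.t12_z_mm is not None else
                      self.trunk_center_mm[2] + 0.25 * self.trunk_radii_mm[2]),
            neck=Plane("z", self.neck_z_mm if self.neck_z_mm is not None else
                       hz - self.head_radius_mm),
            liver_cubes_mm=cubes,
        )

    def replace(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Analytic truth for one phantom: masks, labels and true SUVs."""

    body: Mask
    interior: Mask
    shell_labels: RegionLabelMap
    organ_masks: Mapping[str, Mask]
    landmarks: Landmarks
    meta: SubjectMeta
    true_region_suv: Mapping[str, float]

    @property
    def shell(self) -> Mask:
        return self.body.like(self.shell_labels.shell_mask, tag="shell")


def default_meta(subject_id: str = "phantom", exam_id: str = "phantom-01",
                 weight_kg: float = 70.0, height_cm: float = 170.0,
                 sex: str = "M", age_yr: float = 45.0) -> SubjectMeta:
    """A reference subject dosed at 3.5 MBq/kg."""
    weight_g = weight_kg * 1000.0
    return SubjectMeta(subject_id, exam_id, dose_bq=DOSE_BQ_PER_G * weight_g,
                       weight_g=weight_g, height_cm=height_cm, sex=sex, age_yr=age_yr)


# ---------------------------------------------------------------------------
# Geometry

def _ellipsoid(coords, center, radii) -> np.ndarray:
    cx, cy, cz = coords
    return (((cx - center[0]) / radii[0]) ** 2
            + ((cy - center[1]) / radii[1]) ** 2
            + ((cz - center[2]) / radii[2]) ** 2) <= 1.0


def _body_support(spec: PhantomSpec, coords) -> np.ndarray:
    head = _ellipsoid(coords, spec.head_center_mm, (spec.head_radius_mm,) * 3)
    trunk = _ellipsoid(coords, spec.trunk_center_mm, spec.trunk_radii_mm)
    body = head | trunk
    if spec.arms and spec.arm_radius_mm > 0:
        cx, cy, cz = coords
        ty = spec.trunk_center_mm[1]
        z_lo, z_hi = spec.arm_z_mm
        in_z = (cz >= z_lo) & (cz <= z_hi)
        for sign in (-1.0, 1.0):
            ax = spec.trunk_center_mm[0] + sign * spec.arm_offset_x_mm
            arm = (((cx - ax) ** 2 + (cy - ty) ** 2) <= spec.arm_radius_mm ** 2) & in_z
            body |= arm
    return body


def make_body_phantom(spec: PhantomSpec,
                      meta: SubjectMeta | None = None) -> tuple[Volume, GroundTruth]:
    """Build the attenuation map and analytic ground truth for one phantom.

    The attenuation map equals ``spec.attenuation_value`` on the body
    support and exactly 0 outside it (null background), so threshold
    contouring at 0 recovers the body mask exactly.
    """
    if meta is None:
        meta = default_meta()
    probe = Volume(np.zeros(spec.shape), spec.spacing, kind="attenuation")
    coords = probe.coordinate_grids()
    body = _body_support(spec, coords)
    if not body.any():
        raise GeometryError("phantom body support is empty")

    organ_masks: dict[str, Mask] = {}
    for organ in spec.organs:
        om = _ellipsoid(coords, organ.center_mm, organ.radii_mm)
        if not om.any():
            raise GeometryError(f"organ {organ.name!r} covers no voxels")
        if (om & ~body).any():
            raise GeometryError(f"organ {organ.name!r} extends outside the body support")
        organ_masks[organ.name] = Mask(om, spec.spacing, tag="organ-exclusion")

    pifa = probe.like(np.where(body, spec.attenuation_value, 0.0), kind="attenuation")
    body_mask = Mask.from_volume(pifa, body, tag="body")

    struct = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(body, structure=struct,
                                      iterations=spec.shell_voxels, border_value=0)
    shell = body & ~interior
    labels = classify_region_planes(shell, coords, spec.landmarks)

    dose_per_g = meta.dose_bq / meta.weight_g
    true_suv = {r: spec.shell_activity[r] / dose_per_g for r in REGION_NAMES}

    truth = GroundTruth(
        body=body_mask,
        interior=body_mask.like(interior, tag="interior"),
        shell_labels=RegionLabelMap(labels, spec.spacing),
        organ_masks=organ_masks,
        landmarks=spec.landmarks,
        meta=meta,
        true_region_suv=true_suv,
    )
    return pifa, truth


def make_pet_volume(truth: GroundTruth, spec: PhantomSpec,
                    rng: np.random.Generator | None = None) -> Volume:
    """Forward-model an activity volume (Bq/mL) from the ground truth.

    Shell voxels take their region activity, organ voxels the organ
    activity (organs override the shell where they protrude into it),
    other body voxels the background activity, and everything outside
    the body is 0.  Multiplicative Gaussian voxel noise with
    ``spec.noise_cv`` is applied inside the body; negative draws are
    clipped at 0 with a warning.
    """
    body = truth.body.data
    act = np.zeros(body.shape, dtype=np.float64)
    act[body] = spec.background_activity
    for name in REGION_NAMES:
        act[truth.shell_labels.region_mask_by_name(name)] = spec.shell_activity[name]
    for organ in spec.organs:
        act[truth.organ_masks[organ.name].data] = organ.activity_bq_ml

    if spec.noise_cv > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        factors = 1.0 + spec.noise_cv * rng.standard_normal(int(body.sum()))
        noisy = act[body] * factors
        n_neg = int((noisy < 0).sum())
        if n_neg:
            log.warning("clipped %d negative activity draws to 0", n_neg)
            noisy = np.clip(noisy, 0.0, None)
        act[body] = noisy
    return Volume(act, spec.spacing, kind="activity")


def simulate_repeat_pair(truth: GroundTruth, spec: PhantomSpec,
                         within_subject_cv: float = 0.08,
                         seed: int | None = None) -> tuple[Volume, Volume]:
    """Two repeat exams differing by independent exam-level lognormal scales.

    The scale factors have unit mean and the stated coefficient of
    variation, producing the percent-difference structure a
    Bland–Altman analysis assumes; voxel noise is drawn independently
    per exam.
    """
    if within_subject_cv < 0:
        raise ValidationError("within_subject_cv must be >= 0")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if within_subject_cv > 0:
        sigma = np.sqrt(np.log1p(within_subject_cv**2))
        factors = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=2)
    else:
        factors = np.ones(2)
    exams = []
    for f in factors:
        vol = make_pet_volume(truth, spec, rng=rng)
        exams.append(vol.like(vol.data * f))
    return exams[0], exams[1]


# ---------------------------------------------------------------------------
# Cohorts

@dataclass
class CohortSubject:
    """One simulated subject: attenuation map, PET exam(s) and truth."""

    meta: SubjectMeta
    pifa: Volume
    pets: tuple[Volume, ...]
    truth: GroundTruth
    spec: PhantomSpec

    @property
    def pet(self) -> Volume:
        return self.pets[0]


def _draw_bmi(rng: np.random.Generator, sex: str, decade: str) -> float:
    median, (q1, q3) = BMI_TABLE[(sex, decade)]
    sd = max((q3 - q1) / 1.349, 0.3)  # normal-equivalent spread of the IQR
    return float(np.clip(rng.normal(median, sd), 11.0, 45.0))


def _subject_meta(rng: np.random.Generator, sex: str, decade: str,
                  subject_id: str, exam_id: str) -> SubjectMeta:
    lo = int(decade.split("-")[0])
    age = int(rng.integers(lo, lo + 10))
    height = HEIGHT_CM[(sex, decade)]
    bmi = _draw_bmi(rng, sex, decade)
    weight_g = bmi * (height / 100.0) ** 2 * 1000.0
    return SubjectMeta(subject_id, exam_id, dose_bq=DOSE_BQ_PER_G * weight_g,
                       weight_g=weight_g, height_cm=height, sex=sex, age_yr=age)


def _subject_spec(base: PhantomSpec, face_multiplier: float, subject_factor: float,
                  spillover: bool, seed: int) -> PhantomSpec:
    shell = {r: base.shell_activity[r] * subject_factor for r in REGION_NAMES}
    shell["face"] = ADULT_MALE_FACE_SUV * DOSE_BQ_PER_G * face_multiplier * subject_factor
    organs = base.organs
    if spillover:
        # brain protrudes into the innermost shell layer -> needs exclusion
        rb = base.head_radius_mm - 6.0
        organs = tuple(
            Organ(o.name, o.center_mm, (rb, rb, rb), o.activity_bq_ml)
            if o.name == "brain" else o
            for o in organs)
    return base.replace(shell_activity=shell, organs=organs,
                        background_activity=base.background_activity * subject_factor,
                        seed=seed)


def make_cohort(
    n_per_cell: int,
    effect_table: Mapping[tuple[str, str], float] | None = None,
    seed: int = 0,
    spec: PhantomSpec | None = None,
    between_subject_cv: float = 0.30,
    spillover_prob: float = DEFAULT_SPILLOVER_PROB,
) -> list[CohortSubject]:
    """Simulate a sex x age-decade cohort with known face-uptake effects.

    ``effect_table`` maps (sex, decade) to a face-activity multiplier
    relative to the adult-male level; the default encodes the pubertal
    rise in both sexes and the post-menopausal decline in females.
    Fixed seed implies a bit-identical cohort.
    """
    if effect_table is None:
        effect_table = DEFAULT_EFFECT_TABLE
    if not effect_table:
        raise ValidationError("effect_table must not be empty")
    missing = [cell for cell in ((s, d) for s in SEXES for d in DECADES)
               if cell not in effect_table]
    if missing:
        raise ValidationError(f"effect_table missing cells {missing[:4]}...")
    if spec is None:
        spec = PhantomSpec()
    if n_per_cell == 0:
        return []
    if n_per_cell < 0:
        raise ValidationError("n_per_cell must be >= 0")

    master = np.random.default_rng(seed)
    subjects: list[CohortSubject] = []
    idx = 0
    for sex in SEXES:
        for decade in DECADES:
            for _ in range(n_per_cell):
                idx += 1
                child_seed = int(master.integers(2**31 - 1))
                rng = np.random.default_rng(child_seed)
                sid = f"S{idx:04d}"
                meta = _subject_meta(rng, sex, decade, sid, f"{sid}-E1")
                sf = _lognormal_factor(rng, between_subject_cv)
                sub_spec = _subject_spec(spec, effect_table[(sex, decade)], sf,
                                         rng.random() < spillover_prob, child_seed)
                pifa, truth = make_body_phantom(sub_spec, meta)
                pet = make_pet_volume(truth, sub_spec, rng=rng)
                subjects.append(CohortSubject(meta, pifa, (pet,), truth, sub_spec))
    return subjects


def make_repeat_cohort(
    n_subjects: int = 37,
    within_subject_cv: float = 0.08,
    seed: int = 0,
    spec: PhantomSpec | None = None,
    between_subject_cv: float = 0.30,
    spillover_prob: float = DEFAULT_SPILLOVER_PROB,
) -> list[CohortSubject]:
    """Simulate adult subjects scanned twice for the repeatability study."""
    if spec is None:
        spec = PhantomSpec()
    master = np.random.default_rng(seed)
    subjects: list[CohortSubject] = []
    for i in range(n_subjects):
        child_seed = int(master.integers(2**31 - 1))
        rng = np.random.default_rng(child_seed)
        sex = "M" if rng.random() < 0.5 else "F"
        age = int(rng.integers(20, 80))
        decade = f"{(age // 10) * 10}-{(age // 10) * 10 + 9}"
        sid = f"R{i + 1:03d}"
        meta = _subject_meta(rng, sex, decade, sid, f"{sid}-E1")
        meta = meta.replace(age_yr=age)
        sf = _lognormal_factor(rng, between_subject_cv)
        sub_spec = _subject_spec(spec, DEFAULT_EFFECT_TABLE[(sex, decade)], sf,
                                 rng.random() < spillover_prob, child_seed)
        pifa, truth = make_body_phantom(sub_spec, meta)
        e1, e2 = simulate_repeat_pair(truth, sub_spec, within_subject_cv,
                                      seed=int(rng.integers(2**31 - 1)))
        subjects.append(CohortSubject(meta, pifa, (e1, e2), truth, sub_spec))
    return subjects


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return float(rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma))
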