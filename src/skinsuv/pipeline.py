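"""End-to-end orchestration: phantom/exam -> segmentation -> SUV -> statistics.

``run_exam`` chains contour -> shell -> spillover exclusion -> region
partition -> SUV statistics for one exam; ``run_study`` runs a whole
cohort and emits the three analyses (repeatability, regional
distribution, sex/age relationship) as CSV tables, plots and a markdown
report.  Every output records the configuration and seed that produced
it, and a rerun with the same seed and config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import group_stats, quantification, repeat_stats, segmentation, volume_io
from .core import (
    Landmarks,
    Mask,
    RegionLabelMap,
    SubjectMeta,
    ValidationError,
    Volume,
    REGION_NAMES,
)
from .phantom import CohortSubject
from .quantification import RegionSUV

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Single source of truth for a pipeline run (CLI flags override it)."""

    threshold: float = 0.0
    erode_voxels: int = segmentation.DEFAULT_ERODE_VOXELS
    spillover_suv: float = segmentation.DEFAULT_SPILLOVER_SUV
    spillover_dilate: int = segmentation.DEFAULT_SPILLOVER_DILATE
    normalizations: tuple[str, ...] = quantification.NORMALIZATIONS
    loa_multiplier: float = 1.96
    ci_level: float = 0.95
    adjust: str = "holm"
    caliper: float = 2.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.erode_voxels < 1:
            raise ValidationError("erode_voxels must be >= 1 for a nonempty shell")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "normalizations" in data:
            data["normalizations"] = tuple(data["normalizations"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["normalizations"] = list(d["normalizations"])
        return d


def _stage(name: str):
    def wrap(fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    return wrap


@dataclass
class ExamResult:
    """Artifacts of one exam run."""

    region_suv: RegionSUV
    body: Mask
    shell: Mask
    labels: RegionLabelMap
    spillover: segmentation.SpilloverReport


def run_exam(
    config: RunConfig,
    pifa: Volume,
    pet: Volume,
    landmarks: Landmarks,
    meta: SubjectMeta,
    out_dir: str | Path | None = None,
) -> ExamResult:
    """Run the full skin-VOI chain on one exam and compute region SUVs."""
    _stage("registration")(volume_io.require_registered, pifa, pet)
    body = _stage("body_contour")(segmentation.body_contour_mask, pifa, config.threshold)
    interior = _stage("erosion")(segmentation.erode_mask, body, config.erode_voxels)
    if not interior.data.any():
        raise PipelineError("stage 'shell' failed: empty interior (body thinner "
                            f"than {2 * config.erode_voxels} voxels)")
    shell = body.like(body.data & ~interior.data, tag="shell")
    shell, spill = _stage("spillover_exclusion")(
        segmentation.exclude_organ_spillover, shell, pet, interior, meta,
        config.spillover_suv, config.spillover_dilate)
    labels = _stage("partition")(segmentation.partition_regions, shell, landmarks)
    rs = _stage("quantification")(
        quantification.region_suv_stats, pet, labels, meta, config.normalizations)
    if landmarks.liver_cubes_mm is not None:
        rs.liver_suvmean, rs.liver_suvmax = _stage("liver_reference")(
            quantification.liver_reference, pet, landmarks.liver_cubes_mm, meta)
    result = ExamResult(rs, body, shell, labels, spill)
    if out_dir is not None:
        _write_exam(result, config, meta, Path(out_dir))
    return result


def _write_exam(res: ExamResult, config: RunConfig, meta: SubjectMeta, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    volume_io.write_mask(res.body, out / "body_mask.nii.gz")
    volume_io.write_mask(res.shell, out / "skin_shell.nii.gz")
    volume_io.write_label_map(res.labels, out / "region_labels.nii.gz")
    (out / "spillover_report.json").write_text(json.dumps({
        "removed_voxels": res.spillover.removed_voxels,
        "n_sources": res.spillover.n_sources,
        "source_sizes": list(res.spillover.source_sizes),
        "config": config.to_dict(),
    }, indent=2))
    df = res.region_suv.to_frame()
    df.insert(0, "subject_id", meta.subject_id)
    df.to_csv(out / "region_suv.csv", index=False, float_format="%.10g")
    (out / "region_suv.json").write_text(json.dumps({
        "exam_id": res.region_suv.exam_id,
        "stats": res.region_suv.stats,
        "liver_suvmean": res.region_suv.liver_suvmean,
        "liver_suvmax": res.region_suv.liver_suvmax,
        "constants_g": dict(res.region_suv.constants_g),
    }, indent=2))


# ---------------------------------------------------------------------------
# Cohort on disk

def write_subject(subject: CohortSubject, directory: str | Path) -> Path:
    """Write one subject's volumes, landmarks, metadata and ground truth."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    volume_io.write_volume(subject.pifa, d / "pifa.nii.gz")
    for i, pet in enumerate(subject.pets, start=1):
        volume_io.write_volume(pet, d / f"pet_{i}.nii.gz")
    volume_io.write_landmarks(subject.truth.landmarks, d / "landmarks.json")
    meta = dataclasses.asdict(subject.meta)
    meta["n_exams"] = len(subject.pets)
    (d / "meta.json").write_text(json.dumps(meta, indent=2))
    volume_io.write_label_map(subject.truth.shell_labels, d / "truth_labels.nii.gz")
    (d / "truth.json").write_text(json.dumps({
        "true_region_suv": dict(subject.truth.true_region_suv),
        "seed": subject.spec.seed,
    }, indent=2))
    return d


@dataclass
class LoadedSubject:
    meta: SubjectMeta
    pifa: Volume
    pets: tuple[Volume, ...]
    landmarks: Landmarks


def load_subject(directory: str | Path) -> LoadedSubject:
    d = Path(directory)
    meta_raw = json.loads((d / "meta.json").read_text())
    n_exams = meta_raw.pop("n_exams", 1)
    meta = SubjectMeta(**meta_raw)
    pifa = volume_io.read_volume(d / "pifa.nii.gz", kind="attenuation")
    pets = tuple(volume_io.read_volume(d / f"pet_{i}.nii.gz", kind="activity")
                 for i in range(1, n_exams + 1))
    landmarks = volume_io.read_landmarks(d / "landmarks.json")
    return LoadedSubject(meta, pifa, pets, landmarks)


def load_cohort(directory: str | Path) -> list[LoadedSubject]:
    d = Path(directory)
    if not d.is_dir():
        raise ValidationError(f"cohort directory not found: {d}")
    subdirs = sorted(p for p in d.iterdir() if (p / "meta.json").exists())
    if not subdirs:
        raise ValidationError(f"cohort directory {d} contains no subjects")
    return [load_subject(p) for p in subdirs]


# ---------------------------------------------------------------------------
# Study

@dataclass
class StudyReport:
    """All tables of one study run."""

    exam_table: pd.DataFrame
    repeatability: pd.DataFrame | None
    region_comparison: group_stats.GroupComparisonResult | None
    sex_age: Mapping[str, Mapping[str, group_stats.GroupComparisonResult]]
    liver_by_age: pd.DataFrame | None
    config: RunConfig

    def significant_contrasts(self, normalization: str = "bw") -> dict[str, list]:
        return {sex: res.significant_pairs
                for sex, res in self.sex_age.get(normalization, {}).items()}


def run_study(
    config: RunConfig,
    cohort: Sequence[CohortSubject] | Sequence[LoadedSubject] | str | Path,
    out_dir: str | Path | None = None,
    make_plots: bool = True,
) -> StudyReport:
    """Run every exam of a cohort and compute the three study analyses.

    Subjects with two exams enter the repeatability and regional-
    distribution analyses; single-exam subjects enter the sex/age
    comparison under each SUV normalization.
    """
    if isinstance(cohort, (str, Path)):
        cohort = load_cohort(cohort)
    if not cohort:
        raise ValidationError("cohort is empty")
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    rows = []
    n_adjusted = 0
    for subject in cohort:
        landmarks = getattr(subject, "landmarks", None)
        if landmarks is None:
            landmarks = subject.truth.landmarks
        for i, pet in enumerate(subject.pets, start=1):
            meta = subject.meta.replace(exam_id=f"{subject.meta.subject_id}-E{i}")
            res = run_exam(config, subject.pifa, pet, landmarks, meta)
            n_adjusted += int(res.spillover.adjusted)
            df = res.region_suv.to_frame()
            df.insert(0, "subject_id", meta.subject_id)
            df.insert(1, "exam_index", i)
            df["sex"] = meta.sex
            df["age"] = meta.age_yr
            df["age_group"] = (group_stats.decade_label(meta.age_yr)
                               if meta.age_yr is not None else None)
            df["bmi"] = meta.bmi
            df["spillover_adjusted"] = res.spillover.adjusted
            rows.append(df)
    exam_table = pd.concat(rows, ignore_index=True)

    repeat_df, ba_results = _repeatability(exam_table, config, out, make_plots)
    region_cmp = _region_distribution(exam_table, config)
    sex_age = _sex_age(exam_table, config)
    liver = _liver_by_age(exam_table)

    report = StudyReport(exam_table, repeat_df, region_cmp, sex_age, liver, config)
    if out is not None:
        _write_study(report, ba_results, out, make_plots, n_adjusted)
    return report


def _pairs_for_metric(exams: pd.DataFrame, region: str, column: str,
                      metric_name: str) -> list[repeat_stats.RepeatPair]:
    sub = exams[(exams["region"] == region) & (exams["normalization"] == "bw")]
    pairs = []
    for sid, grp in sub.groupby("subject_id"):
        grp = grp.sort_values("exam_index")
        if grp["exam_index"].nunique() < 2:
            continue
        v1 = float(grp[grp["exam_index"] == 1][column].iloc[0])
        v2 = float(grp[grp["exam_index"] == 2][column].iloc[0])
        if v1 > 0 and v2 > 0:
            pairs.append(repeat_stats.RepeatPair(sid, metric_name, v1, v2))
    return pairs


def _repeatability(exam_table, config, out, make_plots):
    if exam_table["exam_index"].max() < 2:  # no repeat design in this cohort
        return None, {}
    metrics = [("overall", "suvmean"), ("overall", "suvmax"),
               ("liver", "suvmean"), ("liver", "suvmax")]
    metrics += [(r, "suvmean") for r in REGION_NAMES]
    rows, results = [], {}
    for region, column in metrics:
        name = f"{region}_{column}"
        pairs = _pairs_for_metric(exam_table, region, column, name)
        if len(pairs) < 3:
            if region == "overall":
                warnings.warn(f"fewer than 3 repeat pairs for {name}; "
                              "repeatability section skipped", stacklevel=2)
            continue
        res = repeat_stats.bland_altman(pairs, config.loa_multiplier, config.ci_level)
        results[name] = (pairs, res)
        rows.append({
            "metric": name, "n": res.n, "mean_diff_pct": res.mean_diff_pct,
            "mean_diff_ci_lo": res.mean_diff_ci[0], "mean_diff_ci_hi": res.mean_diff_ci[1],
            "loa_lower": res.loa_lower, "loa_lower_ci_lo": res.loa_lower_ci[0],
            "loa_lower_ci_hi": res.loa_lower_ci[1], "loa_upper": res.loa_upper,
            "loa_upper_ci_lo": res.loa_upper_ci[0], "loa_upper_ci_hi": res.loa_upper_ci[1],
            "cor": res.cor, "cor_ci_lo": res.cor_ci[0], "cor_ci_hi": res.cor_ci[1],
            "cor_pct": res.cor_pct,
        })
    if not rows:
        return None, results
    return pd.DataFrame(rows), results


def _region_distribution(exam_table, config):
    first = exam_table[(exam_table["exam_index"] == 1)
                       & (exam_table["normalization"] == "bw")]
    groups, labels = [], []
    for region in REGION_NAMES:
        vals = first[first["region"] == region]["suvmax"].dropna().to_numpy()
        if vals.size:
            groups.append(vals)
            labels.append(region)
    if len(groups) < 2:
        return None
    return group_stats.compare_groups(groups, labels, adjust=config.adjust)


def _sex_age(exam_table, config):
    face = exam_table[(exam_table["region"] == "face") & (exam_table["exam_index"] == 1)]
    single = face[face["age_group"].notna()]
    out: dict[str, dict[str, group_stats.GroupComparisonResult]] = {}
    for norm in exam_table["normalization"].unique():
        sub = single[single["normalization"] == norm]
        per_sex = {}
        for sex in ("M", "F"):
            s = sub[sub["sex"] == sex]
            groups, labels = [], []
            for decade in group_stats.DECADES:
                vals = s[s["age_group"] == decade]["suvmax"].dropna().to_numpy()
                if vals.size >= 2:
                    groups.append(vals)
                    labels.append(decade)
            if len(groups) >= 2:
                per_sex[sex] = group_stats.compare_groups(groups, labels,
                                                          adjust=config.adjust)
        if per_sex:
            out[norm] = per_sex
    return out


def _liver_by_age(exam_table):
    liver = exam_table[(exam_table["region"] == "liver")
                       & (exam_table["exam_index"] == 1)
                       & exam_table["age_group"].notna()]
    if liver.empty:
        return None
    return (liver.groupby(["sex", "age_group"])["suvmax"]
            .agg(["count", "mean", "std"]).reset_index())


def _write_study(report: StudyReport, ba_results, out: Path, make_plots: bool,
                 n_adjusted: int) -> None:
    report.exam_table.to_csv(out / "exam_suv.csv", index=False, float_format="%.10g")
    lines = ["# Skin FDG uptake study report", "",
             "## Configuration", "```yaml",
             yaml.safe_dump(report.config.to_dict(), sort_keys=True).strip(), "```", ""]
    n_exams = report.exam_table.groupby(["subject_id", "exam_index"]).ngroups
    lines += [f"Exams analyzed: {n_exams}; spillover exclusion applied in "
              f"{n_adjusted} ({100.0 * n_adjusted / n_exams:.1f}%).", ""]
    if report.repeatability is not None:
        report.repeatability.to_csv(out / "repeatability.csv", index=False,
                                    float_format="%.10g")
        lines += ["## Repeatability (Bland–Altman)", "",
                  report.repeatability.to_markdown(index=False, floatfmt=".3f"), ""]
        if make_plots:
            for name, (pairs, res) in ba_results.items():
                repeat_stats.bland_altman_plot(pairs, res, out / f"bland_altman_{name}.png")
    if report.region_comparison is not None:
        report.region_comparison.pairwise.to_csv(out / "region_pairwise.csv", index=False,
                                                 float_format="%.10g")
        rc = report.region_comparison
        lines += ["## Regional distribution of SUVmax",
                  f"Kruskal–Wallis H = {rc.h:.3f} (df {rc.df}), p = {rc.p:.3g}", "",
                  rc.pairwise.to_markdown(index=False, floatfmt=".4f"), ""]
        if make_plots:
            _boxplot_regions(report.exam_table, out / "region_boxplot.png")
    for norm, per_sex in report.sex_age.items():
        for sex, res in per_sex.items():
            res.pairwise.to_csv(out / f"sex_age_{norm}_{sex}.csv", index=False,
                                float_format="%.10g")
            lines += [f"## Face SUVmax ({norm}) by decade, sex {sex}",
                      f"Kruskal–Wallis H = {res.h:.3f} (df {res.df}), p = {res.p:.3g}", ""]
    if report.sex_age and make_plots:
        _boxplot_sex_age(report.exam_table, out / "face_by_decade.png")
    if report.liver_by_age is not None:
        report.liver_by_age.to_csv(out / "liver_by_age.csv", index=False,
                                   float_format="%.10g")
        lines += ["## Liver SUVmax by age group", "",
                  report.liver_by_age.to_markdown(index=False, floatfmt=".3f"), ""]
    (out / "report.md").write_text("\n".join(lines))
    summary: dict = {"config": report.config.to_dict(), "n_exams": n_exams,
                     "n_spillover_adjusted": n_adjusted}
    if report.region_comparison is not None:
        rc = report.region_comparison
        summary["region_comparison"] = {"h": rc.h, "df": rc.df, "p": rc.p,
                                        "pairwise": rc.pairwise.to_dict("records")}
    summary["sex_age"] = {
        norm: {sex: {"h": r.h, "df": r.df, "p": r.p,
                     "pairwise": r.pairwise.to_dict("records")}
               for sex, r in per_sex.items()}
        for norm, per_sex in report.sex_age.items()}
    (out / "results.json").write_text(json.dumps(summary, indent=2))


def _boxplot_regions(exam_table: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    first = exam_table[(exam_table["exam_index"] == 1)
                       & (exam_table["normalization"] == "bw")]
    data = [first[first["region"] == r]["suvmax"].dropna().to_numpy()
            for r in REGION_NAMES]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot(data, tick_labels=list(REGION_NAMES))
    ax.set_ylabel("SUVmax")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _boxplot_sex_age(exam_table: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    face = exam_table[(exam_table["region"] == "face")
                      & (exam_table["normalization"] == "bw")
                      & (exam_table["exam_index"] == 1)
                      & exam_table["age_group"].notna()]
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, sex in zip(axes, ("M", "F")):
        sub = face[face["sex"] == sex]
        data = [sub[sub["age_group"] == d]["suvmax"].dropna().to_numpy()
                for d in group_stats.DECADES]
        ax.boxplot(data, tick_labels=list(group_stats.DECADES))
        ax.set_title({"M": "male", "F": "female"}[sex])
        ax.tick_params(axis="x", rotation=45, labelsize=7)
    axes[0].set_ylabel("face SUVmax")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
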