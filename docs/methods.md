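# Methods

## Coordinate and lattice conventions

Volumes live on an axis-aligned lattice in RAS patient coordinates (axis 0
left→right, axis 1 posterior→anterior, axis 2 inferior→superior), with
0-based voxel indices and voxel-center world coordinates
`world = origin + index · spacing`. The default spacing is the scanner's
reconstruction grid, 3.125 × 3.125 × 2.809 mm (600 mm transaxial FOV on a
192 × 192 matrix). NIfTI-1 is the canonical on-disk format; DICOM series
are ingested read-only, converted from LPS to RAS, and oblique series are
rejected rather than resampled. Two volumes are "registered" when shape,
spacing, origin (within 10⁻³ mm) and orientation agree — simultaneous
PET/MRI acquisition makes resampling unnecessary, and any mismatch is
treated as an input error.

## Segmentation

The body contour is the largest 26-connected component above the threshold
(default 0, valid because the attenuation map's background is null), with
3D hole filling applied before erosion so internal air cannot create
spurious inner shells. Erosion uses the 6-connected (face-adjacent)
structuring element, iterated: "n voxels" counts surface layers, not
millimetres, so the 3-layer default is quoted as 9.375 mm using the
in-plane spacing even though the axial step is 2.809 mm. A 26-connected
erosion element would remove diagonal layers faster and give smaller
shells; the cross is fixed so that voxel counts are exactly reproducible.
A body that erodes to an empty interior (thinner than ~2n voxels) is
rejected as degenerate rather than silently returning the whole body as
"shell".

Region borders are axis-aligned planes. "Vertical line from the external
ear canal" is read as a single coronal plane through the ear-canal
landmark with face = anterior (inclusive side of every plane goes to the
anterior/cranial region, which makes the partition deterministic under
ties); a per-slice oblique border would need landmark detection, which is
out of scope. The head/trunk border (neck plane) is a required landmark
input: without it the five regions do not partition the shell. Landmarks
are always supplied analytically (by the phantom generator or a JSON
file); no detection is attempted.

Spillover exclusion automates the manual review step: interior voxels with
SUV > 2.5 are dilated by 2 voxels (6-connectivity) and subtracted from the
shell. Both parameters are configuration-exposed; 2.5 sits above normal
skin and background uptake but below brain/salivary/urinary levels, and a
2-voxel dilation covers sources that protrude up to about two layers into
the shell. The exclusion is deliberately conservative — it removes shell
voxels near any sufficiently hot interior source, whether or not they are
contaminated.

## Quantification

SUV uses the g/mL convention, `activity/(dose/weight)`, with no decay
term: activity volumes are assumed decay-corrected by the scanner, as in
standard DICOM PET semantics. Lean body mass uses the sex-specific James
equations and body surface area the Du Bois formula (×10⁴ scaling to cm²);
both are the conventional PET choices and are swappable. Empty regions
yield missing values, never zeros, so they drop out of group statistics
instead of biasing them. The liver reference averages three axis-aligned
15-mm cubes (voxels whose centers fall in the box — 5×5×5 voxels on the
default grid); the reported liver SUVmax is the maximum over the three
cubes (max-of-cubes rather than mean-of-cube-maxima, a fixed
interpretation of an ambiguous convention).

## Repeatability statistics

Percent difference is `100·(x₂−x₁)/mean(x₁,x₂)` (sign convention
second−first, flippable). Limits of agreement are `d̄ ± 1.96 s` with CIs
from the classical approximation `Var(LoA) ≈ 3s²/n` and t quantiles. The
coefficient of repeatability is computed on absolute differences as
`1.96·√(Σdᵢ²/n)` — the estimator that, for paired data with zero mean
difference, equals `1.96·√2·s_w` — with a chi-square CI placed on
`Σdᵢ²/σ²` at n degrees of freedom. The percent-scale CoR is emitted
alongside; the absolute-scale value is primary. The analytic LoA CI is
validated against a nonparametric bootstrap in the test suite; single
datasets can disagree by 20%+ purely through sample kurtosis (the
percentile bootstrap width tracks the empirical fourth moment while the
analytic width assumes normality), so the check is on the median ratio
over several datasets.

## Group statistics

The omnibus is the tie-corrected Kruskal–Wallis H (defined as 0 when all
observations are identical). Pairwise comparisons follow Conover–Iman:
t statistics on pooled ranks with variance `S²·(N−1−H)/(N−k)` and N−k
degrees of freedom, Holm-adjusted by default (the adjustment method is
configuration-exposed). "Unequal variances" in this family is ambiguous;
the squared-ranks test for variance equality is provided separately as a
diagnostic.

A sensitivity property of the pooled-rank machinery worth knowing: when
several groups are mutually indistinguishable (e.g. flat adult decades),
H is bounded well below its maximum N−1, the variance scale stays large,
and adjacent groups at the extremes of the pooled ranking (whose mean
ranks are compressed) can have low pairwise power even when their
distributions barely overlap. Contrasts between an extreme group and the
central mass are far better powered than contrasts between the two
bottom-most groups. The pipeline-level recovery tests therefore assert
power on extreme-vs-central contrasts.

Cohort matching is greedy nearest-BMI cross-sex pairing within closed age
decades (9 → "0-9", 10 → "10-19"), caliper 2 BMI units, ties broken by a
seeded shuffle; the output is balanced per decade and each decade gets a
Wilcoxon signed-rank balance check. The signed-rank test uses the exact
null distribution for n ≤ 25 without ties/zeros and the normal
approximation otherwise; the CI of the median paired difference is the
Hodges–Lehmann interval over Walsh averages with exact signed-rank
critical ranks up to n = 50.

## The phantom generator

The generator produces the topological features the pipeline exercises —
a closed body surface, internal hot organs, analytic landmark planes —
not anatomical realism. The body is a head sphere, trunk ellipsoid and
two arms-down cylinders; the attenuation map is 0.096 cm⁻¹ (soft tissue
at 511 keV) inside and exactly zero outside. Organs (brain, two salivary
glands, liver, bladder) are ellipsoids strictly inside the body; in the
default geometry every hot organ stays more than shell-depth +
dilation-reach away from the surface so the spillover exclusion removes
nothing, and a "protruding brain" variant (gap 6 mm < shell depth) is
injected per subject with probability 0.232 to emulate the observed
manual-adjustment rate. Dosing is 3.5 MBq/kg, making dose/weight exactly
3500 Bq/g for every subject — the analytic bridge between generated
activities and true SUVs.

Default region shell SUV levels are 3.09 (face), 2.07 (scalp), 1.47
(back), 1.33 (chest), 1.24 (abdomen), background 0.8, liver 2.5, brain 8,
salivary 4, bladder 10. Cohorts scale the face level by a (sex, decade)
multiplier table encoding the qualitative age pattern — pubertal rise in
both sexes, maintained adult levels in males (multiplier 1.14 of the
3.45-SUV adult-male base), post-menopausal decline in females — with a
lognormal between-subject factor (CV 0.30, unit mean) on all shell and
background activities. BMI is drawn per sex × decade from the cohort's
median/IQR table (normal with σ = IQR/1.349), weight = BMI·height², and
heights come from a fixed stature table per sex and decade.

Noise has two layers, chosen to produce the error structure the
statistics assume rather than to model PET physics: multiplicative
Gaussian voxel noise (CV 0.05 by default; the reconstructed noise level
of the real data is unknown, so it is a free parameter) and, for repeat
scans, independent exam-level lognormal scale factors with unit mean and
a stated within-subject CV (default 0.08, which yields percent-difference
limits of agreement near ±1.96·√2·8% ≈ ±22%, inside the ±30% regime).
There is no scatter, randoms, point-spread blur, motion or partial-volume
effect, so passing tests demonstrate the correctness of the pipeline's
geometry and statistics, not robustness to reconstruction artifacts. One
visible consequence of the noise model: regional SUVmax over a uniform
shell of N voxels exceeds the underlying level by roughly CV·E[max of N
standard normals] (~16% at CV 0.05 and N ≈ 4000), so simulated SUVmax
cohort means sit above the generated region levels while SUVmean matches
them closely.

## Problem sizes and determinism

All randomness flows through explicit integer seeds (child seeds drawn
below 2³¹); a fixed seed reproduces cohorts, analyses and written CSVs
byte-for-byte. The default phantom grid is 64 × 64 × 100 voxels (a
cropped-FOV body at the true voxel size); tests and replicate simulations
use a half-scale 32 × 32 × 50 grid. The acceptance script simulates 37
repeat subjects and a 224-exam sex/age cohort at full grid size; power
and calibration checks in the test suite run replicate cohorts at the
half-scale grid with 12–40 replicates. In the half-scale phantom the
liver is too small to hold three separated 15-mm reference cubes, so its
landmark file stacks the three cubes at the liver center and the cubes
deliberately sample a liver/background mixture; the full-size phantom
holds three separated cubes entirely within the liver.

## Known limitations

* Region borders are global axis-aligned planes; real regional borders
  curve, and arms/axillae are not handled (arms-down acquisition makes
  inner-arm skin unevaluable anyway).
* The spillover rule is geometric, not anatomical: it can remove clean
  shell voxels near a hot organ and cannot recover uptake genuinely
  contaminated by partial-volume spill-in, which is not simulated.
* The repeatability model attributes all within-subject variation to a
  global exam-level scale; real repeat variation has regional structure.
* SUVmax of noisy uniform regions is biased upward by the maximum
  statistic (see above); comparisons of SUVmax across groups are valid,
  absolute SUVmax levels depend on the noise CV and region size.
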