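# Methods

## Scope and model

`pefquant` implements the analysis that sits *after* pericardial-effusion
segmentation on chest CT. The segmentation itself (a trained neural
network in clinical deployments, a geometric truth mask here) is an input.
Three clinical decision rules operate on a CT/mask pair:

1. effusion present ⇔ mask volume > 50 mL,
2. large effusion ⇔ volume > 100 mL,
3. hemopericardium ⇔ median of in-mask HU values within [0, 80] > 24.5 HU,

with an alert raised when rule 2 or rule 3 fires. All three comparisons
are strict. The [0, 80] HU window removes voxels that cannot be fluid or
blood (air, fat, calcium, metal, contrast pooling); both bounds are
inclusive, the natural reading of "the range 0 to 80". The median is kept
at full float precision until the comparison — rounding first could flip
cases whose median falls in (24, 25). The alert combines the two severe
findings with OR, the clinically conservative choice; both flags are kept
per case so an AND policy is recoverable from any report.

The rationale for a *median* over, say, a mean is robustness: a segmenter
that leaks a thin rim of myocardium or contrast-enhanced pericardium into
the mask shifts the mean far more than the median, and the HU filter
removes gross outliers before the median is taken.

## Threshold calibration

ROC analysis uses candidate thresholds at midpoints between consecutive
distinct scores, plus sentinels beyond both extremes, with the positive
call defined as *score strictly above threshold*. On integer-valued HU
scores this yields half-integer operating points (24.5, 26.5, …), matching
how thresholds are reported in clinical ROC software. The AUC is the
trapezoidal area traversed in threshold order, which equals the
Mann–Whitney U statistic normalized by n⁺·n⁻ with ties counted half; a
test asserts this identity on tied data.

Both operating-point criteria are provided: Youden's J (maximizing
Se + Sp − 1) and closest-top-left (minimizing (1−Se)² + (1−Sp)²). Ties
break toward the smallest threshold, i.e. toward sensitivity — in an alert
context a missed hemopericardium costs more than a false alarm. For two
normal classes the large-sample Youden optimum is the density-crossing
point of the class distributions; the suite checks convergence to the
numerically solved crossing.

Diagnostic proportions carry exact Clopper–Pearson intervals (Beta
quantiles). The exact construction was chosen, with no normal-approximation
option for headline outputs, because it is the only construction that
reproduces standard printed bounds (97/100 → 91.48–99.38%) at every sample
size, including the degenerate 22/22 → 84.56–100.00% case.

## Synthetic phantom generator

The generator exists so every downstream stage can be exercised, with known
truth, at desk scale. Each phantom is a 128³ grid at 2 mm isotropic spacing
by default (1 mm grids are supported via the spec but quadruple memory and
time; 2 mm keeps generation under ~0.3 s/case while leaving ≥25 voxels per
100 mL of effusion). It contains:

- a soft-tissue body cylinder (40 HU) in −1000 HU air,
- two lung ellipsoids (−800 HU) that never touch the array border,
- an ellipsoidal cardiac blood pool (45 HU non-contrast, 200 HU contrast),
- the effusion: the shell between the heart surface and an outward-scaled
  copy of it, restricted to body-interior non-lung voxels. The shell
  extent is solved by rank-selecting voxels on the ellipsoid norm, so the
  truth-mask volume matches the target to within one voxel — far inside
  the ±5 % volume-fidelity contract. Geometrically unattainable targets
  raise an error naming the limiting direction.
- optionally, a pleural-effusion crescent (10 HU) hugging the posterior
  right lung, contiguous with but by construction never intersecting the
  pericardial shell — the classic adjacent-fluid confounder.

Per-case effusion attenuation is drawn once from the class distribution —
hemopericardium 36.86 ± 9.65 HU (contrast arm) / 33.99 ± 10.08 (without),
simple effusion 20.97 ± 6.35 / 17.59 ± 4.12; pooled 36.10 ± 9.72 and
19.20 ± 5.52 — and i.i.d. Gaussian voxel noise (default SD 8 HU, a typical
soft-tissue noise level at routine dose; per-voxel dispersion inside an
effusion is otherwise a free parameter) is added over the whole volume.
The across-case ± values are interpreted as the SD of *per-case median*
HU; since symmetric voxel noise cancels in the median, drawing a case mean
from N(class mean, class SD) reproduces those statistics by construction.
Volumes are stored as rounded int16, matching integer clinical HU data.

Cohorts draw positive volumes from a log-normal moment-matched to
198.20 ± 159.78 mL, truncated by rejection to [60, 900] mL (family and
bounds are modelling choices; only mean/SD are data-anchored). Negatives
carry a physiological rim drawn uniformly from 10–40 mL. Contrast is
assigned to 58 % of positives and 50 % of negatives; the pleural
confounder to 30 % of cases (prevalence choices, fixed once). A single
seeded generator drives all draws, and each case receives a derived
sub-seed, so cohorts are reproducible bit-for-bit on disk.

What the phantom does **not** emulate: real cardiac/pericardial anatomy,
motion, beam hardening, streaks, post-mortem appearances, or segmentation
error (truth masks are exact). Passing tests therefore validate the
*analysis* — volumetry, filtering, thresholding, statistics — not
segmentation robustness on real scans. One geometric caveat: rim thickness
follows from volume and heart surface area, so positives below ≈80 mL have
rims under 4 mm even though clinical convention associates >4 mm rims with
significant effusions; at the cohort's 200 mL mean the rim is ≈6–8 mm.

## Chest crop

Clinical pipelines crop the CT to the thorax with a learned lung
segmenter. Here lungs are recovered classically: threshold below −500 HU,
drop components connected to the array border (external air), keep the two
largest components. The crop is the lung bounding box dilated by a
symmetric margin (default 20 mm, ceiling-rounded to voxels per axis) and
clamped to the grid. On phantoms this recovers the constructed lungs
essentially exactly (the analytic comparison tolerates the cardiac-notch
carve-out). Cropping is a pure slice — retained voxels are bit-identical —
and idempotent at fixed margin. An empty lung mask degrades to a warning
and an uncropped pass-through rather than an error, since downstream
quantities are crop-invariant anyway.

## Agreement statistics

The ICC is fixed to the two-way random-effects, absolute-agreement,
single-measure form ICC(2,1) — the standard choice when two raters measure
the same volumes and systematic offsets should count as disagreement. It
is computed via `pingouin` and cross-checked in the tests against a
hand-coded ANOVA mean-squares oracle to 1e-10. Bland–Altman limits use the
n−1 sample SD and ±1.96. Dice of two empty masks is defined as 1.0 with a
warning (two raters agreeing there is nothing agree perfectly). Subgroup
comparisons offer Welch's unequal-variance t-test (no equal-variance
assumption between, say, contrast and non-contrast arms) and the
Mann–Whitney U test, exact by enumeration for groups of ≤8 and otherwise
the tie-corrected normal approximation with continuity correction.

## Numerical and interface choices

- Volumes at exactly 50 mL are *not* detected (strict >); half-integer HU
  thresholds make equality impossible on integer CTs, so strictness only
  matters for the volume rules.
- An empty post-filter HU list yields an undefined (NaN) median, reported
  as `null`, and hemopericardium is then false — no surviving voxel means
  no evidence of blood.
- NIfTI-1/2 is the only on-disk format (gzip transparent); masks are
  uint8, CT volumes int16/float32, round-tripped bit-exactly. Grid
  mismatch between a mask and its CT is always an error, never silently
  resampled.
- The replicate simulation behind `scripts/acceptance.py` uses 1,000
  cohorts of 39 + 61 cases; at that size the replicate-mean AUC has a
  standard error below 0.001, so the reported values are stable to the
  printed precision. The full-pipeline recovery test runs one 100-phantom
  cohort end-to-end.

## Known limitations

- The AUC confidence interval of the underlying clinical analysis is not
  reproduced (it depends on the per-case data and the CI method of the
  original ROC software); a bootstrap CI could be added but would be a
  labelled approximation.
- Phantom cohort statistics validate construction, not clinical transfer:
  Dice/ICC values measured between real readers or against a real model's
  masks are outside what the generator can emulate.
- The classical lung crop assumes air-filled lungs fully inside the field
  of view; dense consolidation or cropped shoulders/limbs would defeat it.
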