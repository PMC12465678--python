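# Methods

## Measurement model

One patient contributes one axial T2-weighted slice per timepoint
(pre-op, follow-up) at the mid-disc level of the instrumented segment,
with integer label masks drawn by each rater: 1 = left paraspinal muscle,
2 = right paraspinal muscle, 3 = L3 superior endplate. Masks must match
the slice grid exactly; nothing is resampled, because interpolation would
silently change pixel counts and hence areas. Areas are pure pixel counts
times the physical pixel area (spacing_row × spacing_col, mm²), with no
sub-pixel or partial-volume treatment. Missing pixel-spacing metadata is
a hard error: an area without a physical scale is meaningless.

### Bias-field correction

MRI receive-coil inhomogeneity is modelled as a smooth multiplicative
field. A six-coefficient quadratic surface
b(x̂,ŷ) = c₀₀ + c₁₀x̂ + c₀₁ŷ + c₂₀x̂² + c₁₁x̂ŷ + c₀₂ŷ²
(x̂, ŷ normalised to [−1, 1] across the grid) is least-squares fitted to
the raw intensities over the union of the two muscle ROIs — the
fat/muscle histogram lives inside the segmentations, so that is where the
field must be flat after correction; a whole-image fit is available via a
flag. The fitted surface is normalised to mean 1 over the fitted region
and divided out. Because the mean of a quotient is not the quotient of
means, the corrected image is then rescaled by one global factor so the
mean intensity over the fitted region is preserved exactly; for a
perfectly fitted image this factor is 1. The fit fails loudly when the
design is rank-deficient (fewer than 6 usable pixels, or all pixels on
one row/column) or when the normalised surface is non-positive anywhere
in the fitted region, since dividing by a non-positive field is
undefined. Outside the fitted region, pixels under a non-positive
extrapolated surface are left uncorrected — no measurement uses them.

### Thresholding and classification

The fat/muscle threshold maximises Otsu's inter-class variance
ω₀ω₁(μ₀−μ₁)² over candidate thresholds taken as the interior edges of 256
equal-width bins spanning the ROI intensity range. Class statistics are
computed on the actual sample split at each candidate (not on binned
approximations), ties break toward the lowest threshold, and candidates
leaving one class empty are skipped. Left and right ROIs are thresholded
jointly on their pooled histogram by default (the bilateral muscle is the
analysis unit); per-side thresholds sit behind a flag. A single-valued
ROI histogram has no threshold: the default policy records FCSA := TCSA
with a warning (no fat detectable), and a strict mode raises instead.
Fat and edema are a single high-intensity class; no attempt is made to
separate them. Pixels with corrected intensity ≤ threshold are muscle.

### ΔRCSA

RTCSA and RFCSA divide TCSA and FCSA by the L3 superior endplate CSA.
ΔRCSA is the follow-up minus pre-op value of RFCSA/RTCSA. Algebraically
the endplate CSA cancels inside each fraction, so the implementation
computes each fraction directly as FCSA/TCSA — this realises the
cancellation bit-exactly in floating point rather than only to rounding,
and it is why the endplate CSA from the pre-op study may be reused at
follow-up when no follow-up endplate mask exists without affecting
ΔRCSA. Average-ΔRCSA is the arithmetic mean of the two raters' values;
averaging the same rater twice is rejected.

## Statistics

- **Categorical**: Pearson χ² without Yates continuity correction by
  default (the correction is a flag) — uncorrected χ² is what standard
  clinical tables print; Fisher's exact (two-sided, summing
  hypergeometric probabilities ≤ the observed table's) replaces it
  whenever any expected cell is below 5. Cramér's V
  √(χ²/(n·min(r−1,c−1))) is attached as the effect size.
- **Continuous**: both groups must pass Shapiro–Wilk at 0.05 for the
  pooled-variance Student t (Welch is deliberately not the default: the
  pooled form is what summary-statistics tables imply); otherwise
  Mann–Whitney U reported as the tie-corrected normal-approximation Z
  without continuity correction, since clinical tables print Z.
- **ICC**: two-way ANOVA of the n×2 ratings grid; ICC(A,k) =
  (MSR − MSE)/(MSR + (MSC − MSE)/n); 95% CI from the McGraw–Wong
  single-measure limits with a Satterthwaite denominator df, stepped up
  by Spearman–Brown; F = MSR/MSE against a true value of 0. Bands:
  > 0.90 excellent, 0.80–0.90 good, 0.70–0.80 acceptable, < 0.70 poor.
  Identical ratings (MSE = 0) return ICC = 1 with a degenerate CI.
  Missing cells are an error; no imputation.
- **Regression**: OLS of Average-ΔRCSA on group, age, sex, BMI, fused
  level, BMD, ASA, spondylolisthesis, diabetes, smoking (binary factors
  0/1, TLIF = 1, female = 1, L5S1 = 1). Standardized betas use n−1 sample
  SDs. Tolerance = 1 − R²ⱼ from regressing covariate j on the others;
  VIF = 1/tolerance. Exact collinearity raises an error naming the
  dependent columns. Residual diagnostics (fitted values, standardized
  residuals, normal P–P coordinates) are exported as data, not plots.
- **Significance** is strict: p < 0.01. Missing data are handled by
  complete-case analysis per model.

## Synthetic data

The phantom is two disjoint elliptical muscle ROIs plus an endplate
ellipse on a 256×256 grid at 0.7×0.7 mm (a typical lumbar axial T2
matrix). Muscle pixels carry intensity 100, fat 300, background 40;
exactly ⌊f·N⌋ of the N pooled ROI pixels are replaced by fat via seeded
sampling without replacement (scattered by default; this stresses the
histogram split harder than contiguous streaks would). The image is
tissue intensity × bias field + Gaussian noise (SD 30 by default, i.e. a
6.7-SD class separation), clipped at zero. Noise is Gaussian rather than
Rician: adequate at these SNRs, and the thresholding step only sees the
upper intensity range where the two coincide. The bias field is
1 + a·q(x̂,ŷ)/max|q| with the quadratic shape q scaled so its peak
magnitude **over the muscle ROI** equals the amplitude a (default 0.3):
a phantom advertising a ±30% field should realise ±30% where the
measurement happens, not in unmeasured grid corners. Every phantom ships
a ground-truth record (per-side pixel and fat counts, the exact field)
sufficient to score the pipeline without re-deriving anything.

The cohort generator draws 48 + 42 patients whose covariate marginals
follow the demographic profile of a 90-patient lumbar-fusion cohort, and
sets

Average-ΔRCSA = −0.02 − 0.160·I(TLIF) − 0.105·I(smoker) + ε,
ε ~ N(0, 0.078²),

with all other covariates carrying no generating effect. The residual SD
0.078 is calibrated so the fitted group coefficient's t magnitude is near
10 at this sample size (SE ≈ 0.160/9.75 ≈ 0.0164 ≈ σ·√(1/48+1/42)).
Per-rater ΔRCSA columns add independent N(0, 0.02²) rater noise; the
averaged outcome therefore carries slightly more than the nominal
residual SD, which leaves coefficient estimates unbiased. Patient-level
clinical scores (VAS, ODI, CK, CRP, ESR) are drawn from per-arm normal
profiles so the comparison stage has realistic columns; they are
descriptive scaffolding, not recovery targets.

What the phantoms do **not** emulate: anatomical muscle shapes, implant
artifact, Rician noise floors, contiguous fat marbling (available as a
qualitative mode only via scattered default), or rater disagreement about
boundaries (rater masks are identical; rater noise enters at the
measurement level). Passing tests therefore demonstrate correctness of
the measurement chain under the stated signal model, not segmentation
robustness on clinical images.

## Problem sizes

The simulation-backed checks use 100 seeds for phantom fat-fraction
recovery (three fat fractions × 100 phantoms of 256×256), 200 seeds for
regression recovery and null-ICC means, and 2000 replicates for the
gated-comparison type-I-error check — sizes at which the binomial/SE
bands in the assertions are meaningful while the whole suite stays fast.

## Known limitations

Single-slice 2-D areas only (no volumetry); no automatic segmentation —
rater masks are inputs; the Otsu split has a small systematic bias when
class weights are very unequal and separation is at the low end (≈4 SD),
visible as a ~1% fat-fraction error there; the exact Mann–Whitney
distribution is not used (normal approximation only); Fisher's exact is
2×2 only, and larger sparse tables fall back to χ² with a flagged
minimum expected count.
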