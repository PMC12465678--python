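# paramuscle

Quantifies early paraspinal muscle injury after lumbar fusion surgery from
axial T2-weighted MRI, and runs the cohort statistics that accompany such
a study.

After posterior lumbar surgery the multifidus and erector spinae can lose
lean muscle to fat infiltration and edema. On a single axial slice at the
mid-disc level of the instrumented segment, with rater-drawn regions of
interest (ROIs) for the left/right paraspinal muscles and the L3 superior
vertebral endplate, the package measures:

- **TCSA** — total cross-sectional area of the bilateral paraspinal ROI (mm²);
- **FCSA** — functional CSA, the low-intensity lean-muscle subset of TCSA
  after a binary fat/muscle split;
- **RTCSA = TCSA / endplate CSA**, **RFCSA = FCSA / endplate CSA** —
  size-normalised ratios removing anthropometric confounders;
- **ΔRCSA = RFCSA_fu/RTCSA_fu − RFCSA_pre/RTCSA_pre** — the change in the
  functional fraction from pre-op to follow-up (negative = muscle-quality
  loss), averaged over two independent raters (**Average-ΔRCSA**).

The fat/muscle split is fully automated: a quadratic polynomial intensity
surface is fitted over the muscle ROIs and divided out (multiplicative MRI
bias-field correction), then Otsu's method picks the threshold maximising
the inter-class variance ω₀ω₁(μ₀−μ₁)² of the pooled bilateral ROI
histogram, and ROI pixels at or below the threshold are classified as
muscle.

The statistics stage mirrors a two-arm (endoscopic vs open fusion)
clinical analysis: Pearson χ² with a Fisher's-exact fallback when any
expected cell is below 5, Shapiro–Wilk-gated Student t vs Mann–Whitney Z
comparisons, inter-rater reliability as ICC(A,k=2) (two-way model,
absolute agreement, mean of two raters, McGraw–Wong confidence limits),
multivariable OLS of Average-ΔRCSA on the clinical covariates with
standardized betas and tolerance/VIF diagnostics, and the gravimetric
blood-loss estimator (0.56 mL per gram of gauze weight gain).
Significance is declared at α = 0.01 throughout.

Because no patient images can ship with the package, a synthetic-data
module generates seed-deterministic phantom slices (elliptical ROIs,
bimodal muscle/fat intensities, quadratic bias field, Gaussian noise),
rater pairs, and cohort tables with known generating coefficients, each
with a ground-truth sidecar — so every stage is testable end to end.

## Worked example

`examples/quantify_phantom.py` builds a phantom slice whose pooled muscle
ROI contains exactly 30% scattered fat pixels under a ±30% bias field and
unit-free noise, then runs the measurement chain:

```
pixel area            : 0.49 mm²
Otsu threshold        : 202.6 (scanner units, corrected)
TCSA (bilateral)      : 4429 mm²
FCSA (muscle only)    : 3097 mm²
functional fraction   : 0.6994
ground-truth fraction : 0.7000
```

The recovered functional fraction FCSA/TCSA (0.6994) matches the
generating value (0.7000) to 6·10⁻⁴; the residual gap is noise pixels
crossing the threshold. `examples/cohort_regression.py` fits the
covariate-adjusted regression on one synthetic cohort:

```
n = 90, R² = 0.571
         covariate     beta  std.beta       t       p    VIF
             group   -0.166    -0.676   -8.43  0.0000   1.19
           smoking   -0.118    -0.466   -6.00  0.0000   1.11
               ...
```

The surgical-approach and smoking rows are significant at α = 0.01 with
estimates near their generating −0.160 and −0.105; the eight null
covariates are not, and all VIFs stay below 5 (no collinearity).
`examples/reliability_icc.py` and `examples/blood_loss.py` demonstrate the
ICC and blood-loss estimators the same way.

## Command line

A thin CLI wraps the library for batch runs:

```
paramuscle generate --kind phantom --out fixtures --seed 1
paramuscle quantify --manifest manifest.csv --out results/
paramuscle stats    --cohort cohort.csv --out results/
paramuscle report   --stats-json results/stats.json
```

`quantify` consumes a manifest CSV (one row per patient/timepoint/rater
pointing at an image and mask file) and writes per-patient metrics and
ΔRCSA tables; `stats` writes the full report bundle as JSON plus
residual-diagnostic CSVs.

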