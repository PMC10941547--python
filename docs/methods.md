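# Methods

## Problem and model

Durable benefit from immune-checkpoint inhibitors (ICIs) in advanced NSCLC
is predicted from two minimally invasive sources: texture of the tumor on
the pre-treatment CT (radiomics) and the early on-treatment dynamic change
of PD-L1 carried by plasma extracellular vesicles (ΔEV PD-L1).  The
combined biomarker is a binary logistic regression of durable
**non-response** — progressive disease (PD) at the ~6-month evaluation
(21 ± 3 weeks); partial response (PR) or stable disease (SD) count as
durable response — on 6 selected radiomic features plus ΔEV PD-L1.  The
positive class is deliberately the non-responder: the clinical use case is
flagging patients unlikely to benefit, and this choice fixes the meaning
of sensitivity (non-responders correctly flagged high) and specificity.

ΔEV PD-L1 defaults to the relative change (on-treatment − baseline) /
baseline; absolute difference and log-ratio modes are available.  The
responder rule (PR/SD vs PD) is configurable.

## Radiomic feature layout

Each lesion VOI yields exactly 400 features.

* **Within-phase normalization** (optional, default on): the whole scan is
  z-scored against a normal pectoralis-major muscle VOI, `(x − μ_m)/σ_m`
  with population SD.  The step is named after its purpose — removing
  scanner/phase intensity offsets within an acquisition phase — and makes
  all downstream intensity features invariant to positive affine
  rescalings of the scan.  Normalization is applied *before* gray-level
  quantization (configurable; either order is defensible, this one keeps
  histogram features on the normalized scale).
* **10 histogram features**: mean, median, SD, variance (sample, ddof=1),
  skewness and excess kurtosis (0 for zero-variance VOIs), min, max,
  10th/90th percentiles.
* **195 GLCM features**: gray levels quantized to G ∈ {8, 16, 32, 64, 128}
  by equal-width binning between the VOI min and max (fixed-bin-width
  offered as an option; powers of two are the common radiomics choice for
  G).  For each G, symmetric normalized co-occurrence matrices are
  accumulated at the 13 unique unit-offset directions of the
  26-neighbourhood (offset length 1 in index space; anisotropic spacing is
  ignored for offsets — a documented limitation).  The 13 classical
  Haralick statistics of each matrix (energy, contrast, correlation,
  variance, inverse difference moment, sum average, sum variance, sum
  entropy, entropy, difference variance, difference entropy, IMC1, IMC2;
  entropies in bits, 0·log 0 ≡ 0) are aggregated over directions by mean,
  range (max − min) and population variance, giving 13 × 3 = 39
  rotation-invariant features per G.  A 90° grid rotation or reflection
  only permutes the direction set (symmetry makes ±offset equivalent), so
  these aggregates are exactly invariant under the 48 axis-aligned grid
  symmetries.
* **195 volume-dependent second-order features**: each GLCM feature
  divided by the physical lesion volume in cm³ (voxel count × voxel
  volume; a voxel-count mode exists).

Degenerate cases are defined rather than propagated as NaN: correlation
and the information measures are 0 when a marginal has zero
variance/entropy; a constant VOI quantizes to level 1 everywhere; offset
directions with no valid voxel pair are excluded from aggregation with a
warning (an error only if *all* directions are empty).  IMC2 uses the
conventional `sqrt(1 − exp(−2(HXY2 − HXY)))` with bit-entropies, matching
classic implementations.

Feature identities are carried by a programmatically generated registry
(`feature_registry()` / `evrad registry`): codes `F001`–`F010` histogram,
`F011`–`F205` GLCM (G-major, statistic-major, aggregation-minor),
`F206`–`F400` the volume-normalized block in the same order.  Both the
39-statistic construction and the five G values are configurable, so a
user with a different published feature list can match it.

**Feature maps.** For visualization, any of the 39 texture features can be
computed per voxel on a cubic window (radius ≥ 1 voxel) intersected with
the lesion mask; windows with no valid pair are NaN.  Maps use a small G
(default 8) because windows hold few voxels.

## Model fitting and evaluation

Inputs (6 features + ΔEV PD-L1) are z-scored on the training records so
coefficients are per-SD and comparable with the heatmap's standardization.
The fit is maximum likelihood (Newton-type); standard errors come from the
observed information.  Perfect separation — likely at n ≈ 17–44 — is
detected via non-convergence or exploding coefficients and triggers an
L2-penalized fallback (α = 1, i.e. C = 1) with a warning; fallback models
carry no SEs.  ROC uses all score thresholds with trapezoidal area and
midrank tie handling, so AUC ≡ U/(n₁·n₀); AUC on a single-class subset is
an error, not 0.5.  The high/low cutoff maximizes the Youden index on
training scores; ties break toward the highest qualifying threshold.

## Association battery

Per arm: Kruskal–Wallis (tie-corrected H, chi-square p) of score across
PR/SD/PD; Mann–Whitney U (exact when n₁+n₂ ≤ 20 and tie-free, otherwise
tie-corrected normal approximation) of tumor change by high/low score;
Pearson chi-square without continuity correction (Yates optional) of
high/low score and of TPS positivity against durable response.  TPS
positivity uses the clinical convention ≥ 1%.  p-values are unadjusted by
default (Benjamini–Hochberg available) — the analysis is a small
exploratory battery, not a screen.  Degenerate strata (one response
category, an empty score class, a zero margin) skip the test with a
logged reason and a NaN row rather than failing the suite.

## Clustering heatmap

Patients (rows) are clustered over the 7 model variables after per-variable
Z-scoring (sample SD; population-SD flag available; constant columns are
dropped with a warning), with Euclidean distance and complete linkage —
merge heights are the maximum inter-cluster pairwise distance and are
therefore monotone.  SciPy's tie-breaking (lowest-index pair first) is
inherited and deterministic.  Output is a PNG/SVG plus a JSON sidecar
(leaf order, merge heights) so layouts are machine-checkable.  Columns
stay in fixed order by default; a both-axes mode is a straightforward
transpose of the same machinery.

## Synthetic data

No patient-level data are public, so the generator produces cohorts with
the structure the analysis assumes, at the study's scale (17 ICI + 13
chemotherapy patients by default; the pooled ICI analyses use n = 44).

* **Volumes**: ~40³ voxels at 1 mm spacing; background ≈ −50 HU, muscle
  box ≈ 50 HU, spherical lesion ≈ 30 HU plus a unit-variance Gaussian
  random field scaled by an amplitude (default 20 HU).  The field is white
  noise smoothed to a class-dependent correlation length (responder
  σ = 0.7 voxels, non-responder σ = 1.8): GLCM contrast-type features
  respond monotonically to correlation length, giving a controllable
  ground-truth texture effect.  Additive Gaussian noise (default SD 5 HU)
  and the texture field come from independent RNG streams, so switching
  texture class changes lesion voxels only.  Everything is a deterministic
  function of the seed.
* **Cohorts**: responder status is Bernoulli per arm (default responder
  fraction 0.6 ICI / 0.5 chemo, roughly the proportions implied by the
  reported 2×2 performance).  A latent texture parameter and ΔEV PD-L1
  are standard normal, shifted by the effect sizes (standardized mean
  differences, default 1.0 each) in **ICI-arm non-responders only** —
  the chemotherapy arm carries no biomarker signal, encoding the
  ICI-specificity the biomarker claims.  The 6 model features load on the
  latent texture parameter (loadings ±0.5–0.6) plus idiosyncratic noise.
  Tumor change (%) is drawn consistent with status on a RECIST-style axis
  (responders below +20%, non-responders above; PR at ≤ −30%) and nudged
  by the latent score in the ICI arm, so category, durable-responder label
  and tumor change are mutually consistent and the score–tumor-change
  association holds.  TPS is an independent Beta(0.5, 1)·100 draw — most
  patients low, a tail near 100 — uncorrelated with tumor change by
  construction.  With `images=True` each patient also gets a volume whose
  lesion correlation length tracks their latent texture parameter, and the
  feature columns are replaced by actual extractor output.

What this does **not** emulate: anatomical realism, inter-scanner
variation, segmentation variability, correlated multi-lesion structure,
or any real distribution of ΔEV PD-L1 (unpublished) — so passing tests
validate the pipeline's arithmetic and its qualitative arm-specific
behaviour, not clinical performance.

## Validation design and problem sizes

The acceptance script and test suite size simulations so the full
validation runs in seconds while keeping Monte-Carlo error well inside
the asserted bands: brute-force GLCM checks on 50 arrays ≤ 5³; rotation
invariance on a ~900-voxel lesion at tolerance 1e−9; AUC/U identity on
100 sets (n ≤ 30); parameter recovery at n = 500 (all coefficients within
3 SE); arm specificity over 200 replicate train/validation pairs at
n = 44/30, fitting on an ICI training cohort and scoring an independent
validation cohort — the out-of-sample design mirrors applying a
pre-trained model to a validation trial, and under null effects the same
design measures calibration (AUC ≈ 0.5) without the optimism of training
AUC; test calibration over 2000 null replicates per test; clustering
oracle on 20 random 8×4 matrices.

## Known limitations

* Offsets are unit steps in index space; strongly anisotropic voxels bias
  direction aggregation.
* The voxelwise feature map is a Python loop over lesion voxels — fine for
  single lesions, slow for whole-organ masks.
* The 6 default model features are this package's choice (contrast,
  entropy, IDM, correlation and difference-variance aggregates across G);
  any 6 extracted features can be substituted.
* Exact Mann–Whitney switches to the normal approximation in the presence
  of ties regardless of sample size.
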