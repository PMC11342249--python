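# Methods

This note documents the models and procedures `strokeconn` implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real data.

## Connectome correction and the fibre-length statistic

A subject's raw connectome is a square nonnegative streamline-count matrix
from probabilistic tractography, indexed by the regions of an atlas table
(integer id, hemisphere, centroid in mm, volume in mm³). Tractography
direction is an artefact, so the two directions are averaged; the count for
a pair is divided by the sum of the two region volumes to remove seed-size
bias. Distance correction of streamline counts is assumed to have been
applied by the tractography tool and is not re-applied here.

**Percentile thresholding.** Connections below the 20th percentile are
treated as possibly spurious and zeroed. Two choices are deliberately
pinned down:

* *Population:* the subject's own **nonzero upper-triangle weights**.
  Including structural zeros would put the cutoff at 0 for any sparse
  matrix and disable the step; pooling across subjects would let one
  subject's scale shift another's support.
* *Method:* nearest-rank (the `ceil(p·n)`-th order statistic), so the
  cutoff is always an observed weight and results are exactly reproducible;
  interpolated percentiles are available via `method="linear"`. Removal is
  strict (`w < cutoff`), so ties at the cutoff survive and thresholding at
  p = 0 is a no-op.

**Distance banding.** Pair distances are Euclidean between atlas centroids.
The Q1/Q3 cutoffs are the 25th/75th percentiles (linear interpolation) of
**all unordered pair distances of the atlas** — a fixed atlas property, not
a per-subject quantity, so band membership is identical across subjects.
Ties: short is inclusive (`d ≤ Q1`), long exclusive (`d > Q3`). An atlas
whose pair distances are all equal is permitted but flagged degenerate
(everything lands in the short band) with a warning.

**The ratio.** `N_long / N_short` counts surviving (nonzero) connections —
edges, not streamline weight. A weight-sum variant is available
(`mode="weights"`) since "number of fibres" is ambiguous between the two; a
ratio with no surviving short-range connections raises an explicit error
rather than returning inf.

Useful consequences, all property-tested: the ratio is invariant to global
weight rescaling (the percentile is scale-equivariant) and to region
relabeling, and is unaffected by medium-band connections.

## Lesion-symptom mapping

Per candidate region, a simple linear regression of the behavioural score
on the region's damage fraction (the proportion of the region's voxels
inside the lesion, in [0, 1]). The test is one-tailed for a negative slope:
a lesion is assumed only able to worsen performance. Regions with fewer
than `min_affected` (default 10) subjects having any damage are excluded
before testing — a slope estimated from a handful of lesioned subjects is
noise — as are constant damage columns. Benjamini–Hochberg step-up FDR is
applied across the tested regions at q ≤ 0.05. Candidate regions default
to the lesioned (left) hemisphere when an atlas is supplied.

The per-region statistic is a deliberate choice: ROI-LSM toolboxes differ
in their defaults, and the GLM-t on the continuous damage fraction is the
standard, interpretable option. The "key damage" covariate is the
arithmetic mean of damage over a measure's significant regions; an empty
set yields an *undefined* score and the downstream model drops the
covariate — never a silent zero, which would conflate "no key regions"
with "no damage".

## Association model

The behavioural analysis is two-step by design, mirroring common practice
in clinical neuroimaging: first OLS of each score on age, years post
stroke, lesion volume and (when defined) key damage; then a Pearson
correlation between the **standardized residuals** (residual divided by the
sample SD of the residuals, so SD = 1; internally studentized residuals are
available behind `studentized=True`) and the fibre ratio. `ΔR² = r²` by
construction. BH-FDR is applied across the measure family (default: the
four measures analysed together).

The literal two-step is not identical to adding the ratio to the OLS. The
exact decomposition is the Frisch–Waugh relation: the **part (semipartial)
correlation** — raw score against the ratio residualized on the same
covariates — squares to the exact increment in model R² when the ratio
joins the regression. Correlating *residualized* score with residualized
ratio instead gives the partial correlation, whose square is that increment
inflated by 1/(1−R²) of the covariate model. Both interpretations matter,
so `mode="literal"` (default) and `mode="semipartial"` (exact-increment
part correlation) are implemented, and the semipartial identity is verified
against a full-model fit in the tests.

A one-way ANOVA of the ratio across stroke aetiologies screens for
confounding before the main analysis. Aetiology groups with fewer than 2
members are pooled into "other" (or, if still too small, into the largest
group) with a warning, rather than failing a whole cohort for one rare
label.

Degenerate inputs raise typed errors: constant vectors (undefined
correlation/ANOVA), rank-deficient designs (collinearity, naming the
offending columns), misaligned subject sets.

## Synthetic cohorts

The generator emulates the structure of chronic left-hemisphere stroke
aphasia cohorts so that every stage runs against known ground truth:

* **Atlas** — `n` regions per hemisphere (default 20), centroids uniform in
  mirrored hemispheric boxes on the MNI millimetre scale (~140 mm total
  extent), log-normal volumes around 3.5 cm³. The 40-region default keeps
  hundreds of replicate cohorts affordable while leaving ~780 pair
  distances for quartile banding; it is a deliberately coarse stand-in for
  a real parcellation.
* **Demographics** — n = 87 subjects; age ~ N(60.5, 11.2) clipped to
  [29, 80]; years post stroke gamma-distributed (mean 3.87, SD 3.98);
  aetiology ischaemic : haemorrhagic : other = 57 : 23 : 7.
* **Lesions** — a seed region drawn among left-hemisphere regions with
  weight `exp(−d/15 mm)` toward the hemisphere centre (middle-cerebral-
  artery territory dominates these cohorts); damage decays as
  `severity · exp(−d/extent)` with severity ~ 0.95·Beta(2, 1.2) and extent
  ~ U(25, 55) mm, truncated below 0.01 for compact support. Right-
  hemisphere damage is identically zero. These parameters reproduce
  key-region damage fractions around 0.25–0.45 with SDs around 0.2–0.3,
  the range reported for such cohorts.
* **Connectomes** — expected count
  `base · exp(−d/decay) · (1−dmg_i)(1−dmg_j)`, with base = 5000 (one count
  per tractography sample), decay 45 mm; pairs beyond the atlas Q3 distance
  are further attenuated by `exp(−γ·L)` where L is the volume-weighted mean
  damage over the lesioned hemisphere and γ = 2.5 — lesioned subjects lose
  long-range connectivity preferentially, which is the phenomenon under
  study. Counts are overdispersed (gamma-Poisson, shape 4) and drawn
  independently per direction, so raw matrices are asymmetric like real
  tractography output; `dispersion=None` gives the noise-free limit.
* **Behaviour** — per measure,
  `score = β₀ + β_age·age + β_ypo·ypo + β_lv·LV + β_key·key + β_g·(g−ḡ) + ε`,
  clipped to the instrument scale (WAB-AQ and PNT 0–100, PPTT 0–52, matrix
  reasoning 1–19). The ratio term is centred so the intercept remains the
  expected score at the cohort-mean ratio. Key regions are planted for the
  language measures (3 for WAB-AQ, a nested 2 for PNT) and not for
  PPTT/matrix reasoning, reproducing the regime in which lesion mapping
  finds nothing and the key-damage covariate is dropped. Default effect
  sizes and noise SDs were chosen to land the covariate models' adjusted R²
  in the ranges reported for such cohorts (roughly 0.36/0.33/0.07/0.08
  across the four measures).
* **Planting a partial correlation.** The ratio effect can be specified as
  a raw coefficient or as a target correlation ρ between
  covariate-residualized behaviour and the ratio. In the latter mode the
  coefficient is solved per cohort from the realized design: with g̃ the
  part of the ratio orthogonal to the covariates and κ = sd(g̃)/sd(g), the
  population correlation equals κ·c/√(c²+σ²) with c = β_g·sd(g̃), inverted
  as c = σ(ρ/κ)/√(1−(ρ/κ)²). This makes "planted r = 0.4" a statement
  about the quantity the analysis actually measures.
* A **global-null configuration** (`null_truth`) zeroes every
  lesion-behaviour and ratio-behaviour path (β_key = β_lv = β_g = 0, no
  planted regions) while keeping the age and years-post-stroke effects;
  it is the reference for type-I-error calibration.

All randomness flows through one PCG64 generator seeded from the
configuration, so cohorts regenerate bit-identically.

**Recovery checks** are run with the covariate design built from the
*planted* key-region set and with score clipping disabled: censoring biases
linear-coefficient recovery, and substituting the estimated key set would
mix LSM's selection error into a test of the regression machinery. Both
sources of distortion are exercised separately (clipping in the default
cohorts, key-set estimation in the LSM sensitivity checks).

**What passing tests do not show.** The generator's lesions are smooth
monotone functions of centroid distance, not real vascular territories; the
atlas is uniform, not anatomical; behavioural scores are linear in their
predictors apart from clipping; damage affects connectivity only through
node attenuation and the hemisphere-level long-range factor. Calibration
and recovery results therefore validate the *machinery* — thresholding,
banding, FDR, residualization — under a plausible generative model, not the
substantive neuroscience on any particular clinical dataset.

## Numerical choices

* Percentile cutoffs and band assignments are exactly reproducible
  (nearest-rank order statistics; quantiles of a fixed distance multiset).
* OLS via ordinary least squares with intercept; residual orthogonality to
  the design holds to a relative tolerance of 1e-10 and is asserted in
  tests at 1e-8 (cosine).
* All CSV/TSV output uses 12-significant-digit floats; `run-all` passes the
  profiles table through its written file so a pipeline run is exactly the
  composition of the stage commands on the same files, and two runs with
  one seed are byte-identical.
* Behavioural missingness is handled complete-case per measure, with
  counts logged.

## Known limitations

* Edge counts weight a 6000-streamline connection and a just-surviving one
  equally; the weight-sum mode is provided but shares the arbitrariness of
  any weighting of corrected streamline counts.
* The one-tailed LSM direction is an assumption; paradoxical protective
  associations are invisible by design.
* The literal residual-correlation p-values use n−2 degrees of freedom and
  ignore the covariate projection (n−p−1 would be marginally wider); with
  n ≈ 90 and 4 covariates the difference is negligible and the null
  calibration stays within its Monte-Carlo band.
* With a coarse 40-region atlas, mass-univariate LSM on spatially
  correlated lesions flags neighbours of truly critical regions; this is a
  property of ROI-LSM itself, not a defect of the implementation, and is
  why specificity is tested on independent damage columns.
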