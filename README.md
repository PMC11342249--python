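# strokeconn

White-matter network integrity and post-stroke cognition: a tested pipeline
for relating the **proportion of long-range fibres** in a structural
connectome to behavioural outcomes in left-hemisphere stroke cohorts.

## The problem

After a stroke, language and non-verbal cognitive outcomes vary widely
between people with similar lesions. One candidate explanation is the state
of the white-matter network *beyond* the lesion: long-range association
fibres are metabolically expensive and especially vulnerable, and their
preservation may support both language and general cognition. Testing that
idea requires a chain of analyses:

1. **Connectome correction.** Each subject's tractography streamline-count
   matrix `A` (region × region) is symmetrized and volume-normalized,
   `w_ij = ((A_ij + A_ji)/2) / (v_i + v_j)`, then connections below the
   subject's 20th percentile of nonzero weights are zeroed as possibly
   spurious.
2. **Fibre-length banding.** Every region pair is classed by the Euclidean
   distance `d_ij` between atlas centroids: *short* if `d ≤ Q1`, *long* if
   `d > Q3` of all pair distances, else *medium*. The statistic of interest
   is the ratio `N_long / N_short` of surviving connections — the
   *proportion of long-range fibres*.
3. **Lesion-symptom mapping (LSM).** For each behavioural measure, each
   region's damage fraction is regressed on the score (one-tailed: damage
   can only hurt), with Benjamini–Hochberg FDR at q ≤ 0.05 across regions.
   The per-subject mean damage over the significant regions becomes the
   "key damage" covariate; when no region survives, the covariate is
   dropped.
4. **Variance partitioning.** Each score is regressed on age, years post
   stroke, lesion volume and key damage (OLS); the standardized residuals
   are correlated with the fibre ratio (Pearson, BH-FDR across the measure
   family). `ΔR² = r²` is the additional variance the fibre ratio explains
   beyond the covariates.

No public dataset of this kind exists, so the package ships a first-class
synthetic-cohort generator (`strokeconn.simulate`) with distance-dependent
connectivity decay, contiguous left-hemisphere lesions that preferentially
sever long-range connections, and behavioural scores generated from a known
linear model — every stage is testable against planted ground truth.

## Worked example

```python
from strokeconn import LongRangeModel, default_truth, simulate_cohort

cohort = simulate_cohort(default_truth(seed=7))   # n = 87, 40 regions
results = LongRangeModel.from_cohort(cohort).fit()
print(results.summary())
```

Output (abridged):

```
One-way ANOVA: fibre ratio ~ stroke aetiology
  F(2, 84) = 0.483, p = 0.618

Lesion-symptom mapping (one-tailed, BH-FDR)
  wab_aq: 20 regions tested, 0 excluded, 11 significant at q<=0.05
  matrix_reasoning: ... 0 significant -> key-damage covariate dropped

Residual correlation with long-range fibre proportion (BH family of 4)
         measure  n      r  delta_r2     p_raw     p_fdr  significant
          wab_aq 87 0.3217    0.1035  0.002378  0.004756         True
             pnt 87 0.1477   0.02183    0.1721    0.2063        False
            pptt 87 0.1368   0.01872    0.2063    0.2063        False
matrix_reasoning 87 0.5122    0.2623 3.957e-07 1.583e-06         True
```

Reading it: stroke aetiology does not confound the fibre ratio (ANOVA
p = 0.62); lesion mapping finds key regions for aphasia severity but none
for matrix reasoning, whose covariate model therefore omits key damage
("N/A"); and after removing the covariates' share, the fibre ratio still
explains e.g. 10.4% of the variance in aphasia severity (r = 0.32,
corrected p = 0.005). Each cohort is one Monte-Carlo draw, so the
realized correlations scatter around the planted effect sizes.

The same analysis runs from the shell on directories of TSV matrices:

```bash
strokeconn simulate --seed 7 --out cohort/
strokeconn connectome-metrics --matrix-dir cohort/connectomes \
    --atlas cohort/atlas.csv --percentile 0.20 --out profiles.csv
strokeconn associate --subjects cohort/subjects.csv --profiles profiles.csv \
    --damage cohort/damage.csv --atlas cohort/atlas.csv --out results/
# or everything at once, from a reviewable YAML config:
strokeconn run-all --config config.yaml
```

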