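# lesionkit

Out-of-sample outcome prediction and mass-univariate lesion mapping for
stroke lesion imaging, with a fully synthetic, ground-truthed cohort
generator.

## The problem

Acute stroke lesions can be mapped onto clinical outcome in two conceptually
different ways. *Brain mapping* fits one statistical model per imaging
feature — per voxel, or per white-matter connection — to locate
anatomo-clinical associations within a sample. *Prediction* asks whether a
model trained on some patients can anticipate the outcome of patients it has
never seen. The two can disagree sharply: an outcome may have robust,
FDR-surviving neural correlates and still be essentially unpredictable
out-of-sample, because lesion-independent factors (age, reserve, comorbidity,
measurement noise) dominate its variance. `lesionkit` implements both arms
over the same inputs so that this dissociation can be measured rather than
assumed, and ships a synthetic lesion-cohort generator with planted ground
truth so that every stage — feature extraction, cross-validation hygiene,
exact tests, FDR calibration — is verifiable without patient data.

It is written for methods researchers in lesion-symptom mapping and
clinical-outcome modelling who need a tested, leakage-free reference
pipeline.

## What is implemented

- **Synthetic cohorts** (`SimConfig`, `generate_cohort`, `generate_toy_atlas`):
  contiguous territory-seeded lesions; acute severity
  `NIHSS = round(42(1−e^{−s/τ}))` of a planted eloquent-voxel load `s` plus
  noise; 3-month outcomes from a latent `c = λs + β·age − reserve + ε` with
  shrinkage `λ < 1`; toy parcellation + streamline atlas.
- **Features** (`compute_disconnection`, `build_voxel_features`,
  `build_connection_features`, `overlap_map`): binary voxel status and
  symmetric region×region disconnected-streamline counts (a streamline is
  disconnected iff its path meets the lesion), both filtered by the min-10
  prevalence rule.
- **Prediction** (`nested_cv_predict` and friends): repeated nested 5-fold
  cross-validation (inner 4-fold hyperparameter search) of SVR, Gaussian
  process regression, SVM and 100-tree random forests, with fold-wise
  normalization, optional fold-wise PCA (components ≥ 1% variance), the age
  covariate, `log(1+y)` target handling, and mean/majority aggregation;
  metrics R², Pearson r, accuracy, PPV, NPV.
- **Mapping** (`fisher_map`, `logistic_map`, `ttest_map`, `fdr_correct`,
  `region_median_or`, `hemisphere_or_correlation`, `map_overlap`): exact
  Fisher odds-ratio maps, per-connection logistic regressions, two-sample t
  maps with mean-difference effect sizes, Benjamini–Hochberg FDR at q = 0.01,
  regional median-OR tables (≥ 50-voxel rule) and per-hemisphere map
  correlations.
- **Comparison** (`binarize_outcomes`, `stratify_base_rates`,
  `paired_residual_test`, `mcnemar_test`, `loglinear_lrt`, `chance_level`,
  `rank_correlation_taub`, `chisq_from_margins`): base-rate stratification
  for fair two-target contests, paired model tests, and log-linear
  likelihood-ratio tests on the target × data-type × accuracy table.

See `docs/methods.md` for the model details and numerical choices.

## Worked example

`examples/01_simulate_cohort.py` generates the default 685-subject cohort:

```
n subjects              685
age, mean (sd)          65.6 (13.9)
left-hemisphere, %      57.4
NIHSS 24h, median (IQR) 3 (0; 8)
NIHSS 3m,  median (IQR) 0 (0; 2)
mRS 3m,    median (IQR) 1 (0; 2)
poor outcome (mRS>=2),% 43.5
tau-b NIHSS24h ~ mRS3m  0.20
```

The acute score is right-skewed around a median of 3, 43.5% of subjects have
a poor 3-month outcome, and acute severity only loosely orders the 3-month
outcome (tau-b ≈ 0.2) because the chronic latent mixes the shrunken lesion
signal with age, reserve and noise.

`examples/03_predict_outcomes.py` then runs nested cross-validated SVR on a
componential voxel space (n = 300 toy cohort):

```
nihss_24h: R2 = 0.566 (paper-style 0.566), Pearson r = 0.79
nihss_3m: R2 = -0.011 (paper-style 0.000), Pearson r = 0.33
```

Acute severity is predictable out-of-sample; the 3-month score is not
(negative raw R², clamped to 0 in summary style) — even though
`examples/04_map_lesion_impact.py` shows FDR-significant anatomical
correlates for both horizons. That contrast — statistical correlates without
predictive value — is the pipeline's central measured property.

The remaining examples cover disconnection feature extraction (`02`), impact
mapping with regional summaries and hemispheric correlations (`04`), and the
stratified model-comparison statistics (`05`).

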