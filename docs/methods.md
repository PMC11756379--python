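# Methods

`lesionkit` implements a combined out-of-sample prediction and
mass-univariate mapping pipeline for stroke lesion imaging, together with a
synthetic cohort generator that makes every stage verifiable against known
ground truth. This note documents the models, the generator's assumptions,
the numerical choices, and what passing tests do and do not establish.

## The two analysis arms

Both arms consume the same input: a cohort of binary lesion masks on a
common voxel grid plus a clinical table (age; NIHSS at 24 h; NIHSS and mRS
at 3 months).

**Prediction arm.** Features are either voxel lesion status (binary, one
column per voxel lesioned in ≥ 10 subjects), region-to-region disconnection
counts (strict upper triangle of the per-subject disconnection matrix,
retained when non-zero in ≥ 10 subjects), or a componential reduction of
either (principal components explaining ≥ 1% of total variance each). Age is
always appended as a covariate; lesion volume is deliberately not included.
Models are evaluated in nested cross-validation: outer 5-fold splits
estimate generalization, inner 4-fold cross-validation inside each outer
training set selects hyperparameters, and the whole procedure is repeated
with fresh fold assignments. Per-subject predictions are aggregated across
repetitions (mean for regression, majority vote for classification) and
scored with R², Pearson r, accuracy, PPV and NPV. Skewed severity scores
are fitted on a `log(1 + y)` scale and re-transformed before evaluation.

**Mapping arm.** One statistical model per feature: exact Fisher tests with
odds-ratio impact scores for voxel lesion status against a binary outcome;
single-predictor logistic regressions for disconnection data; two-sample
t-tests with mean-difference effect sizes for continuous outcomes. Each map
is corrected with Benjamini–Hochberg FDR at q = 0.01. Regional summaries
report the median voxel odds ratio for regions with ≥ 50 tested voxels, and
hemispheric agreement between two odds-ratio maps is the per-hemisphere
Pearson correlation with Fisher-z confidence intervals.

The pipeline's headline property is the *dissociation* between the arms:
statistically mappable correlates of an outcome do not imply out-of-sample
predictive value, and the synthetic generator is constructed so this
dissociation is reproducible (see "What the generator emulates").

## The synthetic cohort generator

`SimConfig` / `generate_cohort` emulate, at toy spatial scale, the structure
of a single-centre first-ever anterior-circulation stroke cohort:

- **Lesions** are contiguous 6-connected blobs grown by random-walk region
  growing from a seed voxel drawn near a per-hemisphere territory centre.
  Hemisphere is Bernoulli with left fraction 0.545; sizes are log-uniform in
  `lesion_size_range`; lesions never cross the midline column.
- **Planted deficit weights** form a left-lateralized "language" block
  around the left territory centre plus smaller bilateral dorsal "motor"
  blocks; weights are uniform inside blocks and exactly zero outside, so
  recovery of the planted set is well defined.
- **Acute severity** is `NIHSS24h = round(42·(1 − exp(−(s + ε)/τ)))` clipped
  to 0–42, where `s` is the normalized lesion-weight load,
  `ε ~ N(0, acute_noise_sd)` and `τ = nihss_link_scale` (default 4). The
  link is bounded, monotone and right-skewed — the shape the prediction arm
  log-transforms. The load normalization constant was calibrated once so the
  default configuration yields an acute median near 3 with an IQR of a few
  points and roughly 40% of subjects above the NIHSS > 4 cut.
- **3-month outcome** derives from a latent chronic score
  `c = shrinkage·s + age_effect·z(age) − reserve + ε'`, with
  `reserve ~ N(0, reserve_sd)` a lesion-independent resilience term. The
  mRS grade is obtained by rank-binning `c` at fixed cumulative proportions
  whose mRS ≥ 2 cut sits at a 43.5% poor-outcome rate (median 1, IQR 0–2);
  the NIHSS at 3 months applies the acute link to a down-shifted `c`, which
  makes it strongly zero-inflated (median 0). The shrinkage factor (< 1)
  plus the reserve term encode the assumption that lesion-independent
  factors dominate recovery, which is what drives the prediction–mapping
  dissociation.
- **Ages** are normal (mean 67.4, SD 15.1) truncated to 18–95 years.
- All randomness flows from one integer seed through spawned substreams
  (one per subject plus one clinical stream), so every output is
  bit-reproducible.

The toy streamline atlas partitions the outer rim of an ellipsoidal brain
volume into angular-sector regions (half per hemisphere) and connects random
region-voxel pairs with 26-connected straight-line voxel paths; every region
terminates at least one streamline.

**What the generator does not emulate:** MRI intensities and segmentation
error, curved fibre geometry, reperfusion effects, recurrent strokes,
ordinal-scale measurement error in NIHSS/mRS, and the partial missingness of
the 3-month NIHSS (generated for all subjects; callers can mask). With one
shared lesion-load pathway the generator also cannot simultaneously hit a
high acute–chronic rank correlation and a near-zero chronic imaging R²; the
defaults favour the dissociation and land the tau-b between acute severity
and 3-month mRS around 0.2–0.3. Passing tests therefore establish the
*machinery* (no leakage, correct exact tests, calibrated FDR, recoverable
planted signal), not patient-level realism.

## Numerical and design choices

- **Disconnection rule**: a streamline is disconnected iff ≥ 1 path voxel is
  lesioned; it counts once regardless of how many voxels are hit. Diagonal
  (intra-region) hits are recorded in the matrix but never become features.
- **Feature ordering**: voxel columns in raster order with x fastest;
  connection columns lexicographic by (i, j). Constant columns are dropped.
- **Exact Fisher p**: two-sided as the sum of hypergeometric probabilities ≤
  the observed table's (scipy implementation, verified exhaustively against
  integer enumeration for all tables with n ≤ 30).
- **Odds ratios**: cross-product ratio; Haldane–Anscombe +0.5 on all four
  cells only when a zero cell exists, and only for the OR — p-values always
  use the uncorrected table.
- **Logistic maps**: default predictor is disconnection status dichotomized
  at ≥ 1 streamline; the single-binary-predictor model is saturated, so the
  MLE is computed in closed form and the p-value is the likelihood-ratio
  test against the intercept-only model (χ², 1 df). Separated connections
  are flagged and fall back to the corrected 2×2 OR. A raw-count mode fits
  numerically.
- **t maps**: pooled-variance two-sample t by default (Welch switchable),
  vectorized across voxels; zero-variance/equal-mean voxels get t = 0, p = 1.
- **FDR**: Benjamini–Hochberg step-up, one family per map.
- **PCA scope**: components are fitted inside each outer training fold by
  default (`pca_scope="fold"`); a `"global"` option reproduces the leakier
  reading of fitting once on all subjects. Covariate columns bypass the PCA.
- **Normalization**: continuous features and covariates are z-scored with
  training-fold statistics; binary voxel features are left unscaled by
  default (switchable). Regression targets are additionally standardized
  per training fold so hyperparameter ranges are scale-free.
- **Hyperparameter search**: random search (default budget 30 draws;
  smaller in tests) over per-family spaces, scored by inner 4-fold CV loss
  (squared error on the fitting scale / misclassification rate). Any
  optimizer honouring the inner/outer separation would do; random search
  keeps the implementation dependency-free and reproducible.
- **Null-model floor**: for regression, the inner CV also scores the
  intercept-only predictor, and the fold model falls back to that constant
  unless the best candidate beats it by one standard error of the null's
  fold losses. Selecting among flexible candidates on a signal-free target
  otherwise yields systematically negative out-of-sample R² (selection
  variance), which would masquerade as a pipeline defect.
- **Prediction clipping**: retransformed regression predictions are clipped
  to the training-fold target range; the exponential re-transform can
  otherwise map extrapolated held-out cases far beyond the score maximum.
- **Paired model comparison**: paired t-test on per-subject absolute errors
  (raw and squared modes available — a paired t on signed residuals tests
  bias, not accuracy); McNemar switches from the exact conditional binomial
  to the continuity-corrected χ² above 25 discordant pairs.
- **Stratification**: removes uniformly random subjects positive on the
  more prevalent variable and negative on the other until positive counts
  match; the removal count is exactly the initial count difference.
- **Log-linear models**: Poisson GLMs on the 8 cells of the 2×2×2
  (target × data type × accuracy) table with effect-coded, hand-built design
  matrices; likelihood-ratio tests compare nested term sets; zero cells get
  +0.5 on all cells with a warning.

## Problem sizes used in the shipped checks

The property suites run on deliberately small instances: leakage guards on
n = 200 cohorts (16×16×12 grid) with 10 target permutations per condition
and 2 repetitions of the nested procedure; the dissociation suite on
n = 600 cohorts (24×24×16 grid, chronic shrinkage 0.4, reserve SD 1.0)
across 10 seeds; planted-signal recovery on n = 600 (20×20×14 grid, strong
planted effect); FDR calibration on ~1000-feature global-null t maps across
100+ replicates. These sizes were chosen so the full suite runs on a laptop
CPU while each property remains comfortably away from its threshold.

## Known limitations

- The leakage guard evaluates R² on the identity target scale; with the log
  link, an information-free constant prediction retransforms to the
  geometric mean of a skewed score and reads as R² ≈ −0.1 without any
  leakage. That bias is a property of evaluating re-transformed predictions
  with R², not of the cross-validation.
- Exact Fisher maps on a dichotomized outcome have limited power for
  low-prevalence voxels at q = 0.01 when the positive base rate is high;
  continuous-outcome t maps retain more power at the same n.
- The toy atlas's straight-line streamlines make disconnection counts more
  local than real tractography; conclusions about connectomic feature
  *quality* should not be read off the synthetic comparisons.
- No cluster-extent or permutation-based family-wise correction, no ordinal
  mRS models, and no lesion-volume covariate adjustment are provided.
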