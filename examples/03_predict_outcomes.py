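"""Out-of-sample prediction of acute severity via repeated nested CV.

Kernel support vector regression on a fold-wise componential voxel space
plus age, log-transformed target, nested 5-fold cross-validation repeated
twice.  Every preprocessing statistic, the PCA basis, hyperparameters and
the model itself are derived from outer-training subjects only.
"""

import lesionkit as lk

cfg = lk.SimConfig(
    n_subjects=300,
    grid_shape=(24, 24, 16),
    midline_x=12,
    lesion_size_range=(10, 200),
    seed=11,
)
cohort, _ = lk.generate_cohort(cfg)
space = lk.build_voxel_features(cohort, min_patients=10)
age = cohort.clinical["age"].to_numpy()
scheme = lk.make_fold_scheme(cohort.subject_ids, n_repetitions=2, seed=11)

for target in ("nihss_24h", "nihss_3m"):
    y = cohort.clinical[target].to_numpy(float)
    run = lk.nested_cv_predict(
        space,
        y,
        scheme,
        lk.LearnerSpec("svr", n_iter=4),
        use_pca=True,
        covariates=age,
        target_name=target,
    )
    m = lk.regression_metrics(run)
    print(f"{target}: R2 = {m['r2']:.3f} (paper-style {m['r2_nonneg']:.3f}), "
          f"Pearson r = {m['pearson_r']:.2f}")

print()
print("Acute severity is predictable from lesion anatomy; the 3-month score")
print("is dominated by lesion-independent factors, so its out-of-sample R2")
print("sits at or below zero despite real anatomical correlates (see 04).")
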