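"""Out-of-sample outcome prediction via repeated nested cross-validation.

The prediction arm follows a strict out-of-sample protocol: an outer K-fold
split (default 5) estimates generalization; within each outer training set an
inner 4-fold cross-validation selects hyperparameters; the whole procedure is
repeated with fresh fold assignments (default 5 repetitions) and per-subject
predictions are aggregated across repetitions (mean for regression, majority
vote for classification).  Every data-dependent quantity — normalization
statistics, the principal-component basis, hyperparameters, the fitted
model — is derived from outer-training subjects only.

Skewed severity scores (NIHSS) are modelled on a ``log(1 + y)`` scale and
predictions are re-transformed to the original scale before any metric is
computed.  Age (or any other clinical covariate) is appended untouched by the
PCA step and z-scored with training-fold statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sstats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.svm import SVC, SVR

from .datatypes import FeatureProvenance, FeatureSpace

__all__ = [
    "FoldScheme",
    "LearnerSpec",
    "PredictionRun",
    "transform_target",
    "retransform_target",
    "make_fold_scheme",
    "pca_reduce",
    "nested_cv_predict",
    "regression_metrics",
    "classification_metrics",
]


# --------------------------------------------------------------------------
# target transform


def transform_target(nihss: np.ndarray | float) -> np.ndarray | float:
    """Log-transform a nonnegative skewed score: ``log(1 + y)``."""
    y = np.asarray(nihss, dtype=float)
    if np.any(y < 0):
        raise ValueError("scores must be nonnegative")
    out = np.log1p(y)
    return float(out) if out.ndim == 0 else out


def retransform_target(y: np.ndarray | float) -> np.ndarray | float:
    """Inverse of :func:`transform_target`: ``exp(y) - 1``, floored at 0."""
    out = np.clip(np.expm1(np.asarray(y, dtype=float)), 0.0, None)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# fold scheme


@dataclass(frozen=True)
class FoldScheme:
    """Outer-fold assignments for every repetition of the nested procedure.

    ``assignment`` has shape (n_repetitions, n_subjects) with fold ids
    ``0..n_outer-1``; per repetition the folds partition the subjects with
    sizes differing by at most one.  The same scheme object is reused across
    feature conditions so every condition sees identical splits.
    """

    n_outer: int
    n_inner: int
    n_repetitions: int
    assignment: np.ndarray
    seed: int

    def outer_split(self, rep: int, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_indices, test_indices) for one repetition and outer fold."""
        a = self.assignment[rep]
        test = np.nonzero(a == fold)[0]
        train = np.nonzero(a != fold)[0]
        return train, test


def make_fold_scheme(
    subject_ids: Sequence[str],
    n_outer: int = 5,
    n_repetitions: int = 5,
    seed: int = 0,
    n_inner: int = 4,
) -> FoldScheme:
    """Balanced pseudo-randomized outer-fold assignment, one per repetition."""
    n = len(subject_ids)
    if n_outer > n:
        raise ValueError("more outer folds than subjects")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 40427]))
    assignment = np.empty((n_repetitions, n), dtype=int)
    base = np.arange(n) % n_outer  # round-robin gives sizes differing by <= 1
    for rep in range(n_repetitions):
        perm = rng.permutation(n)
        assignment[rep, perm] = base
    return FoldScheme(
        n_outer=n_outer,
        n_inner=n_inner,
        n_repetitions=n_repetitions,
        assignment=assignment,
        seed=seed,
    )


# --------------------------------------------------------------------------
# PCA reduction


def pca_reduce(
    space: FeatureSpace,
    min_var_fraction: float = 0.01,
    fit_subjects: np.ndarray | None = None,
) -> FeatureSpace:
    """Project a feature space onto principal components fitted on a subset.

    Components are fitted on ``fit_subjects`` only (default: all subjects)
    and each retained component explains at least ``min_var_fraction`` of the
    total variance of the fitted data.  The projection is applied to every
    subject, so held-out rows are expressed in the training basis.  Columns
    with covariate provenance pass through untouched.
    """
    n = space.matrix.shape[0]
    fit_idx = np.arange(n) if fit_subjects is None else np.asarray(fit_subjects)
    if fit_idx.size < 2:
        raise ValueError("need at least 2 subjects to fit components")
    feat_cols = np.array(
        [k for k, p in enumerate(space.provenance) if p.kind != "covariate"],
        dtype=int,
    )
    cov_cols = space.columns_of_kind("covariate")
    X = space.matrix[:, feat_cols]
    max_comp = min(fit_idx.size - 1, X.shape[1])
    pca = PCA(n_components=max_comp, svd_solver="auto", random_state=0)
    pca.fit(X[fit_idx])
    keep = pca.explained_variance_ratio_ >= min_var_fraction
    n_keep = int(keep.sum())
    if n_keep == 0:
        raise ValueError("empty_feature_space")
    scores = pca.transform(X)[:, :n_keep]
    provenance = [
        FeatureProvenance(kind="component", component=k) for k in range(n_keep)
    ]
    matrix = scores
    if cov_cols.size:
        matrix = np.column_stack([scores, space.matrix[:, cov_cols]])
        provenance += [space.provenance[k] for k in cov_cols]
    return FeatureSpace(
        matrix=matrix, provenance=provenance, subject_ids=list(space.subject_ids)
    )


# --------------------------------------------------------------------------
# learners


_DEFAULT_SPACES: dict[str, dict] = {
    "svr": {
        "kernel": ["rbf", "linear"],
        "C": ("loguniform", 1e-2, 1e2),
        "epsilon": ("loguniform", 1e-3, 1.0),
    },
    "gpr": {
        "alpha": ("loguniform", 1e-3, 1.0),
        "length_scale": ("loguniform", 1e-1, 1e2),
    },
    "svm": {
        "kernel": ["rbf", "linear"],
        "C": ("loguniform", 1e-2, 1e2),
    },
    "rf": {
        "max_features": ["sqrt", "log2", 0.5],
        "min_samples_leaf": [1, 2, 5, 10],
    },
}

Family = Literal["svr", "gpr", "svm", "rf"]


@dataclass(frozen=True)
class LearnerSpec:
    """A prediction algorithm plus its hyperparameter search space.

    ``family`` is one of ``svr`` (kernel support vector regression), ``gpr``
    (Gaussian process regression), ``svm`` (kernel support vector
    classification) or ``rf`` (bagged decision trees with 100 trees).
    Candidates are drawn at random from ``search_space`` (``n_iter`` draws)
    and scored by inner-fold cross-validation loss: mean squared error on the
    transformed scale for regression, misclassification rate for
    classification.
    """

    family: Family
    search_space: dict | None = None
    n_iter: int = 30

    @property
    def task(self) -> str:
        return "regression" if self.family in ("svr", "gpr") else "classification"

    def space(self) -> dict:
        return self.search_space or _DEFAULT_SPACES[self.family]


def _sample_params(space: dict, rng: np.random.Generator) -> dict:
    out = {}
    for name, spec in space.items():
        if isinstance(spec, tuple) and spec[0] == "loguniform":
            lo, hi = np.log(spec[1]), np.log(spec[2])
            out[name] = float(np.exp(rng.uniform(lo, hi)))
        else:
            out[name] = spec[int(rng.integers(len(spec)))]
    return out


def _make_estimator(family: Family, params: dict, random_state: int):
    if family == "svr":
        return SVR(**params)
    if family == "gpr":
        kernel = ConstantKernel(1.0) * RBF(
            length_scale=params.get("length_scale", 1.0)
        ) + WhiteKernel(noise_level=1e-2)
        return GaussianProcessRegressor(
            kernel=kernel,
            alpha=params.get("alpha", 1e-2),
            normalize_y=True,
            n_restarts_optimizer=0,
            random_state=random_state,
        )
    if family == "svm":
        return SVC(**params, random_state=random_state)
    if family == "rf":
        return RandomForestClassifier(
            n_estimators=100, **params, random_state=random_state, n_jobs=1
        )
    raise ValueError(f"unknown learner family {family!r}")


# --------------------------------------------------------------------------
# nested CV


@dataclass
class PredictionRun:
    """Out-of-sample predictions of one (feature condition, target) cell.

    ``per_repetition`` has shape (n_repetitions, n_subjects) and holds the
    out-of-sample prediction of each subject in each repetition (original
    target scale for regression, class labels for classification);
    ``aggregated`` is the across-repetition mean respectively majority vote.
    """

    subject_ids: list[str]
    target_name: str
    task: str
    condition: str
    observed: np.ndarray
    per_repetition: np.ndarray
    aggregated: np.ndarray
    chosen_params: list[dict] = field(default_factory=list)

    @property
    def n_repetitions(self) -> int:
        return self.per_repetition.shape[0]


def _normalize_columns(
    X: np.ndarray, train_idx: np.ndarray, scale_binary: bool
) -> np.ndarray:
    """Z-score columns with training statistics; binary columns optionally."""
    Xt = X[train_idx]
    mean = Xt.mean(axis=0)
    sd = Xt.std(axis=0)
    is_binary = np.array(
        [np.isin(np.unique(col), (0.0, 1.0)).all() for col in X.T]
    )
    scale = ~is_binary | scale_binary
    sd_safe = np.where(sd > 0, sd, 1.0)
    out = X.copy()
    out[:, scale] = (X[:, scale] - mean[scale]) / sd_safe[scale]
    return out


def _fit_quiet(est, X: np.ndarray, y: np.ndarray):
    """Fit suppressing kernel-bound convergence chatter (expected for GPR
    hyperparameter candidates pinned at their search-space bounds)."""
    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return est


def _inner_cv_loss(
    family: Family,
    params: dict,
    X: np.ndarray,
    y: np.ndarray,
    n_inner: int,
    rng: np.random.Generator,
    task: str,
) -> float:
    n = len(y)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[perm] = np.arange(n) % n_inner
    losses = []
    for f in range(n_inner):
        tr = fold_of != f
        va = ~tr
        if task == "classification" and len(np.unique(y[tr])) < 2:
            return np.inf
        est = _make_estimator(family, params, random_state=int(rng.integers(2**31)))
        _fit_quiet(est, X[tr], y[tr])
        pred = est.predict(X[va])
        if task == "regression":
            losses.append(float(np.mean((pred - y[va]) ** 2)))
        else:
            losses.append(float(np.mean(pred != y[va])))
    return float(np.mean(losses))


def _null_inner_loss(
    y: np.ndarray, n_inner: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Inner-CV squared-error loss of the intercept-only predictor.

    Returns (mean loss, standard error over inner folds).  Used as a floor
    for model selection: a candidate that cannot beat the constant predictor
    by one standard error has not demonstrated any signal, and fitting it
    would only add prediction variance.
    """
    n = len(y)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[perm] = np.arange(n) % n_inner
    losses = []
    for f in range(n_inner):
        tr = fold_of != f
        losses.append(float(np.mean((y[~tr] - y[tr].mean()) ** 2)))
    losses = np.asarray(losses)
    return float(losses.mean()), float(losses.std(ddof=1) / np.sqrt(n_inner))


def nested_cv_predict(
    space: FeatureSpace,
    target: np.ndarray,
    scheme: FoldScheme,
    learner: LearnerSpec,
    use_pca: bool = False,
    covariates: np.ndarray | None = None,
    target_name: str = "target",
    condition: str = "",
    min_var_fraction: float = 0.01,
    pca_scope: Literal["fold", "global"] = "fold",
    scale_binary: bool = False,
    log_target: bool | None = None,
) -> PredictionRun:
    """Repeated nested cross-validation with out-of-sample predictions only.

    Parameters
    ----------
    space:
        Feature matrix (voxel status or disconnection counts); covariate
        columns inside the space are treated like ``covariates``.
    target:
        Per-subject target.  Regression targets are fitted on a
        ``log(1 + y)`` scale when ``log_target`` is true (the default for
        regression) and re-transformed before aggregation and metrics.
    scheme:
        Shared fold assignment; identical across conditions by construction.
    covariates:
        (n,) or (n, k) clinical covariates (typically age) appended after any
        PCA step and z-scored with training-fold statistics.
    use_pca / min_var_fraction / pca_scope:
        Componential feature space: components fitted within each outer
        training fold (default) or once globally, keeping components that
        explain at least ``min_var_fraction`` of total variance.
    """
    X_all = space.matrix
    n = X_all.shape[0]
    y_obs = np.asarray(target, dtype=float)
    if y_obs.shape[0] != n or np.any(~np.isfinite(y_obs)):
        raise ValueError("target must be finite and cover every subject")
    task = learner.task
    if log_target is None:
        log_target = task == "regression"
    y_fit = transform_target(y_obs) if (task == "regression" and log_target) else y_obs
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]

    global_pca_space = None
    if use_pca and pca_scope == "global":
        global_pca_space = pca_reduce(space, min_var_fraction).matrix

    per_rep = np.full((scheme.n_repetitions, n), np.nan)
    chosen: list[dict] = []
    for rep in range(scheme.n_repetitions):
        for fold in range(scheme.n_outer):
            train, test = scheme.outer_split(rep, fold)
            if task == "classification" and len(np.unique(y_fit[train])) < 2:
                raise ValueError("degenerate_training_fold")
            rng = np.random.default_rng(
                np.random.SeedSequence([scheme.seed, 911, rep, fold])
            )
            if use_pca:
                if pca_scope == "global":
                    Xb = global_pca_space
                else:
                    Xb = pca_reduce(
                        space, min_var_fraction, fit_subjects=train
                    ).matrix
                Xb = _normalize_columns(Xb, train, scale_binary=True)
            else:
                Xb = _normalize_columns(X_all, train, scale_binary=scale_binary)
            if covariates is not None:
                cov = _normalize_columns(covariates, train, scale_binary=False)
                Xb = np.column_stack([Xb, cov])

            # standardize the fitting-scale target with training statistics
            # so hyperparameter ranges (epsilon, alpha) are scale-free
            if task == "regression":
                y_m = float(y_fit[train].mean())
                y_s = float(y_fit[train].std()) or 1.0
                y_run = (y_fit - y_m) / y_s
            else:
                y_m, y_s, y_run = 0.0, 1.0, y_fit

            null_mean = null_se = None
            if task == "regression":
                null_mean, null_se = _null_inner_loss(
                    y_run[train], scheme.n_inner, rng
                )
            best_loss, best_params = np.inf, {}
            for _ in range(learner.n_iter):
                params = _sample_params(learner.space(), rng)
                loss = _inner_cv_loss(
                    learner.family,
                    params,
                    Xb[train],
                    y_run[train],
                    scheme.n_inner,
                    rng,
                    task,
                )
                if loss < best_loss:
                    best_loss, best_params = loss, params
            use_constant = (
                task == "regression" and best_loss > null_mean - null_se
            )
            if use_constant:
                pred = np.full(len(test), float(y_run[train].mean()))
                best_params = {"constant": True}
            else:
                est = _make_estimator(
                    learner.family,
                    best_params,
                    random_state=int(rng.integers(2**31)),
                )
                _fit_quiet(est, Xb[train], y_run[train])
                pred = est.predict(Xb[test])
            if task == "regression":
                pred = pred * y_s + y_m
                if log_target:
                    pred = retransform_target(pred)
                # clinical scores are bounded; clip to the training-fold
                # target range to keep the exp re-transform from exploding
                # on extrapolated held-out cases (training data only)
                pred = np.clip(pred, y_obs[train].min(), y_obs[train].max())
            per_rep[rep, test] = pred
            chosen.append(
                {"repetition": rep, "fold": fold, "loss": best_loss, **best_params}
            )

    if np.isnan(per_rep).any():  # pragma: no cover - scheme partitions subjects
        raise RuntimeError("incomplete out-of-sample coverage")
    if task == "regression":
        aggregated = per_rep.mean(axis=0)
    else:
        votes = per_rep.sum(axis=0)
        aggregated = (votes * 2 >= scheme.n_repetitions).astype(float)
    return PredictionRun(
        subject_ids=list(space.subject_ids),
        target_name=target_name,
        task=task,
        condition=condition,
        observed=y_obs,
        per_repetition=per_rep,
        aggregated=aggregated,
        chosen_params=chosen,
    )


# --------------------------------------------------------------------------
# metrics


def regression_metrics(run: PredictionRun) -> dict:
    """R-squared and Pearson r of aggregated out-of-sample predictions.

    R-squared is ``1 - SS_res / SS_tot`` on the original target scale and may
    be negative out-of-sample; ``r2_nonneg`` clamps it at 0 for paper-style
    summary tables ("no variance explained").
    """
    y, p = run.observed, run.aggregated
    if len(y) < 3:
        raise ValueError("need at least 3 subjects")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("target has zero variance")
    ss_res = float(np.sum((y - p) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    pearson = float(sstats.pearsonr(y, p).statistic) if np.std(p) > 0 else np.nan
    return {"r2": r2, "r2_nonneg": max(r2, 0.0), "pearson_r": pearson}


def classification_metrics(run: PredictionRun) -> dict:
    """Accuracy, PPV, NPV and the majority-class chance level (fractions).

    PPV (respectively NPV) is returned as NaN with a warning when no
    positive (negative) predictions exist.
    """
    y = run.observed.astype(int)
    p = run.aggregated.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in observations")
    tp = int(np.sum((p == 1) & (y == 1)))
    fp = int(np.sum((p == 1) & (y == 0)))
    tn = int(np.sum((p == 0) & (y == 0)))
    fn = int(np.sum((p == 0) & (y == 1)))
    accuracy = (tp + tn) / len(y)
    if tp + fp == 0:
        warnings.warn("no positive predictions; PPV undefined", stacklevel=2)
        ppv = np.nan
    else:
        ppv = tp / (tp + fp)
    if tn + fn == 0:
        warnings.warn("no negative predictions; NPV undefined", stacklevel=2)
        npv = np.nan
    else:
        npv = tn / (tn + fn)
    chance = max(np.mean(y == 1), np.mean(y == 0))
    return {
        "accuracy": accuracy,
        "ppv": ppv,
        "npv": npv,
        "chance_level": float(chance),
    }
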