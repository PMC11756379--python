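"""Mass-univariate lesion-symptom and disconnection-symptom mapping.

One statistical model per feature: exact Fisher tests with odds-ratio impact
scores for binary voxel lesion status against a binary outcome; per-connection
logistic regressions for disconnection data; two-sample t-tests with
mean-difference effect sizes for continuous outcomes.  Multiple comparisons
are controlled within each map by a Benjamini-Hochberg false-discovery-rate
correction (default q = 0.01).  Regional summaries report the median voxel
odds ratio per labelled region with at least ``min_voxels`` tested voxels,
and hemispheric agreement between two impact maps is quantified by Pearson
correlation of the voxel odds ratios per hemisphere with Fisher-z confidence
intervals.

Odds ratios are the cross-product ratio ``(a d)/(b c)`` of the per-voxel
2x2 (lesioned x outcome) table; when any cell is zero the Haldane-Anscombe
+0.5 correction is applied to all four cells for the odds ratio only — the
exact p-value is always computed from the uncorrected table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .datatypes import FeatureSpace, VoxelGrid

__all__ = [
    "VoxelMapResult",
    "ConnectionMapResult",
    "ContinuousMapResult",
    "fisher_map",
    "logistic_map",
    "ttest_map",
    "fdr_correct",
    "region_median_or",
    "hemisphere_or_correlation",
    "map_overlap",
]


# --------------------------------------------------------------------------
# results


@dataclass
class VoxelMapResult:
    """Per-voxel Fisher-test map: 2x2 tables, p, odds ratio, FDR flag."""

    outcome_name: str
    n_subjects: int
    q: float
    voxels: np.ndarray  # (F, 3) coordinates of the tested voxels
    tables: np.ndarray  # (F, 4) cells a, b, c, d
    p_values: np.ndarray
    odds_ratios: np.ndarray
    significant: np.ndarray


@dataclass
class ConnectionMapResult:
    """Per-connection logistic map: coefficient, OR, LRT p, FDR flag."""

    outcome_name: str
    n_subjects: int
    q: float
    connections: list[tuple[int, int]]
    coefficients: np.ndarray
    odds_ratios: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    separation: np.ndarray  # bool: OR taken from the corrected 2x2 table


@dataclass
class ContinuousMapResult:
    """Per-voxel two-sample t map: t, p, mean difference, FDR flag."""

    outcome_name: str
    n_subjects: int
    q: float
    voxels: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    mean_differences: np.ndarray  # lesioned minus intact
    significant: np.ndarray


# --------------------------------------------------------------------------
# FDR


def fdr_correct(p_values: np.ndarray, q: float = 0.01) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


# --------------------------------------------------------------------------
# odds ratio helpers


def odds_ratio_2x2(a: float, b: float, c: float, d: float) -> float:
    """Cross-product odds ratio with +0.5 on all cells iff any cell is 0."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def _tables_from_binary(
    X: np.ndarray, outcome: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized 2x2 cells per column: a=lesioned&pos, b=lesioned&neg,
    c=intact&pos, d=intact&neg."""
    pos = outcome.astype(bool)
    lesioned = X.astype(bool)
    a = lesioned[pos].sum(axis=0)
    b = lesioned[~pos].sum(axis=0)
    c = (~lesioned)[pos].sum(axis=0)
    d = (~lesioned)[~pos].sum(axis=0)
    return a, b, c, d


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided exact Fisher p for one 2x2 table (hypergeometric)."""
    table = np.array([[a, b], [c, d]])
    return float(sstats.fisher_exact(table, alternative="two-sided")[1])


# --------------------------------------------------------------------------
# maps


def fisher_map(
    voxel_features: FeatureSpace,
    outcome: np.ndarray,
    q: float = 0.01,
    outcome_name: str = "outcome",
) -> VoxelMapResult:
    """Exact Fisher test and odds-ratio impact score per retained voxel."""
    outcome = np.asarray(outcome).astype(int)
    if len(np.unique(outcome)) < 2:
        raise ValueError("outcome is constant")
    X = voxel_features.matrix
    a, b, c, d = _tables_from_binary(X, outcome)
    F = X.shape[1]
    p = np.empty(F)
    # cache: many voxels share the same 2x2 table
    seen: dict[tuple[int, int, int, int], float] = {}
    for k in range(F):
        key = (int(a[k]), int(b[k]), int(c[k]), int(d[k]))
        if key not in seen:
            seen[key] = fisher_exact_p(*key)
        p[k] = seen[key]
    ors = np.array(
        [odds_ratio_2x2(a[k], b[k], c[k], d[k]) for k in range(F)]
    )
    flags = fdr_correct(p, q)
    return VoxelMapResult(
        outcome_name=outcome_name,
        n_subjects=X.shape[0],
        q=q,
        voxels=voxel_features.voxel_coordinates(),
        tables=np.column_stack([a, b, c, d]),
        p_values=p,
        odds_ratios=ors,
        significant=flags,
    )


def _binary_logistic_lrt(a: int, b: int, c: int, d: int) -> tuple[float, float, bool]:
    """Logistic regression of a binary outcome on one binary predictor.

    With a single binary predictor the model is saturated, so the MLE is
    available in closed form: the coefficient is the log cross-product odds
    ratio and the likelihood-ratio statistic is twice the difference of
    binomial log-likelihoods between the two-group and pooled fits.  Returns
    (coefficient, LRT p, separation flag).  Under separation (a zero cell)
    the coefficient is taken from the +0.5-corrected table.
    """
    n1, n0 = a + b, c + d  # lesioned / intact group sizes
    separation = min(a, b, c, d) == 0
    coef = float(np.log(odds_ratio_2x2(a, b, c, d)))

    def ll(k: float, n: float) -> float:
        if n == 0 or k == 0 or k == n:
            return 0.0
        p_ = k / n
        return k * np.log(p_) + (n - k) * np.log(1 - p_)

    ll_full = ll(a, n1) + ll(c, n0)
    ll_null = ll(a + c, n1 + n0)
    dev = 2.0 * (ll_full - ll_null)
    p = float(sstats.chi2.sf(max(dev, 0.0), df=1))
    return coef, p, separation


def logistic_map(
    connection_features: FeatureSpace,
    outcome: np.ndarray,
    q: float = 0.01,
    dichotomize: bool = True,
    outcome_name: str = "outcome",
) -> ConnectionMapResult:
    """Single-predictor logistic regression per connection with LRT p-values.

    By default the disconnection count is dichotomized at >= 1 streamline;
    ``dichotomize=False`` uses the raw count as the predictor (fitted
    numerically).  P-values come from the likelihood-ratio test against the
    intercept-only model; FDR flags at ``q``.  Perfectly separated
    connections are flagged and their odds ratio falls back to the
    +0.5-corrected 2x2 cross-product ratio.
    """
    outcome = np.asarray(outcome).astype(int)
    if len(np.unique(outcome)) < 2:
        raise ValueError("outcome is constant")
    X = connection_features.matrix
    F = X.shape[1]
    coefs = np.empty(F)
    ps = np.empty(F)
    sep = np.zeros(F, dtype=bool)
    if dichotomize:
        Xb = (X > 0).astype(int)
        for k in range(F):
            col = Xb[:, k]
            if col.min() == col.max():
                raise ValueError("constant predictor reached logistic_map")
            a = int(np.sum((col == 1) & (outcome == 1)))
            b = int(np.sum((col == 1) & (outcome == 0)))
            c = int(np.sum((col == 0) & (outcome == 1)))
            d = int(np.sum((col == 0) & (outcome == 0)))
            coefs[k], ps[k], sep[k] = _binary_logistic_lrt(a, b, c, d)
    else:
        import statsmodels.api as sm

        ll_null = sm.Logit(outcome, np.ones((len(outcome), 1))).fit(disp=0).llf
        for k in range(F):
            col = X[:, k]
            if col.min() == col.max():
                raise ValueError("constant predictor reached logistic_map")
            Xd = sm.add_constant(col)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = sm.Logit(outcome, Xd).fit(disp=0, maxiter=200)
                    coefs[k] = res.params[1]
                    dev = 2.0 * (res.llf - ll_null)
                    ps[k] = float(sstats.chi2.sf(max(dev, 0.0), df=1))
                    sep[k] = not res.mle_retvals.get("converged", True)
                except Exception:
                    sep[k] = True
                    colb = (col > 0).astype(int)
                    a = int(np.sum((colb == 1) & (outcome == 1)))
                    b = int(np.sum((colb == 1) & (outcome == 0)))
                    c = int(np.sum((colb == 0) & (outcome == 1)))
                    d = int(np.sum((colb == 0) & (outcome == 0)))
                    coefs[k], ps[k], _ = _binary_logistic_lrt(a, b, c, d)
    ors = np.exp(coefs)
    flags = fdr_correct(ps, q)
    return ConnectionMapResult(
        outcome_name=outcome_name,
        n_subjects=X.shape[0],
        q=q,
        connections=[p_.connection for p_ in connection_features.provenance],
        coefficients=coefs,
        odds_ratios=ors,
        p_values=ps,
        significant=flags,
        separation=sep,
    )


def ttest_map(
    voxel_features: FeatureSpace,
    outcome: np.ndarray,
    q: float = 0.01,
    welch: bool = False,
    outcome_name: str = "outcome",
) -> ContinuousMapResult:
    """Two-sample t-test per voxel on a continuous outcome, vectorized.

    Groups are subjects with versus without a lesion in the voxel; the effect
    size is the mean difference (lesioned minus intact).  Pooled-variance t
    by default, Welch optional.
    """
    y = np.asarray(outcome, dtype=float)
    X = voxel_features.matrix.astype(bool)
    n1 = X.sum(axis=0).astype(float)
    n0 = (~X).sum(axis=0).astype(float)
    if np.any(n1 < 2) or np.any(n0 < 2):
        warnings.warn("voxels with a group of size < 2 skipped", stacklevel=2)
    sum1 = X.T @ y
    sum0 = (~X).T @ y
    m1 = np.divide(sum1, n1, out=np.full_like(n1, np.nan), where=n1 > 0)
    m0 = np.divide(sum0, n0, out=np.full_like(n0, np.nan), where=n0 > 0)
    sq = y**2
    ss1 = X.T @ sq - n1 * m1**2
    ss0 = (~X).T @ sq - n0 * m0**2
    valid = (n1 >= 2) & (n0 >= 2)
    t = np.full(X.shape[1], np.nan)
    p = np.full(X.shape[1], np.nan)
    if welch:
        v1 = ss1 / (n1 - 1)
        v0 = ss0 / (n0 - 1)
        se2 = v1 / n1 + v0 / n0
        df = se2**2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1)
        )
    else:
        sp2 = (ss1 + ss0) / (n1 + n0 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n0)
        df = n1 + n0 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t[valid] = ((m1 - m0) / np.sqrt(se2))[valid]
    p[valid] = 2.0 * sstats.t.sf(np.abs(t[valid]), df[valid] if welch else df[valid])
    # zero-variance voxels with equal means: t = 0/0; define t=0, p=1
    degenerate = valid & ~np.isfinite(t)
    t[degenerate & (np.abs(m1 - m0) < 1e-12)] = 0.0
    p[degenerate & (np.abs(m1 - m0) < 1e-12)] = 1.0
    flags = np.zeros(X.shape[1], dtype=bool)
    flags[valid] = fdr_correct(p[valid], q)
    return ContinuousMapResult(
        outcome_name=outcome_name,
        n_subjects=X.shape[0],
        q=q,
        voxels=voxel_features.voxel_coordinates(),
        t_values=t,
        p_values=p,
        mean_differences=m1 - m0,
        significant=flags,
    )


# --------------------------------------------------------------------------
# summaries


def region_median_or(
    result: VoxelMapResult,
    region_labels: np.ndarray,
    min_voxels: int = 50,
) -> "pd.DataFrame":
    """Median voxel odds ratio per labelled region with enough tested voxels.

    Returns a table with one row per region present in ``region_labels``
    (label > 0): the number of tested voxels falling in the region and, only
    for regions with at least ``min_voxels`` tested voxels, the median of
    their odds ratios.
    """
    import pandas as pd

    region_labels = np.asarray(region_labels, dtype=int)
    vx = result.voxels
    labels_at_voxels = region_labels[vx[:, 0], vx[:, 1], vx[:, 2]]
    rows = []
    for r in np.unique(region_labels[region_labels > 0]):
        in_region = labels_at_voxels == r
        count = int(in_region.sum())
        median = (
            float(np.median(result.odds_ratios[in_region]))
            if count >= min_voxels
            else np.nan
        )
        rows.append({"region": int(r), "n_tested_voxels": count, "median_or": median})
    return pd.DataFrame(rows)


def hemisphere_or_correlation(
    map_a: VoxelMapResult, map_b: VoxelMapResult, grid: VoxelGrid
) -> dict:
    """Pearson correlation of voxel odds ratios per hemisphere, with 95% CIs.

    Both maps must cover the same retained voxel set.  Midline voxels belong
    to neither hemisphere and are excluded.  Confidence intervals use the
    Fisher z transform; hemispheres with fewer than 3 voxels are returned as
    NaN with a warning.
    """
    if map_a.voxels.shape != map_b.voxels.shape or not np.array_equal(
        map_a.voxels, map_b.voxels
    ):
        raise ValueError("maps must share the same retained voxel set")
    hemi = grid.hemisphere_of_x(map_a.voxels[:, 0])
    out: dict = {}
    for side, name in ((-1, "left"), (+1, "right")):
        sel = hemi == side
        n = int(sel.sum())
        if n < 3:
            warnings.warn(f"fewer than 3 voxels in {name} hemisphere", stacklevel=2)
            out[f"r_{name}"] = np.nan
            out[f"ci_{name}"] = (np.nan, np.nan)
            out[f"n_{name}"] = n
            continue
        r = float(
            sstats.pearsonr(map_a.odds_ratios[sel], map_b.odds_ratios[sel]).statistic
        )
        z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
        half = 1.959963984540054 / np.sqrt(n - 3)
        out[f"r_{name}"] = r
        out[f"ci_{name}"] = (float(np.tanh(z - half)), float(np.tanh(z + half)))
        out[f"n_{name}"] = n
    return out


def map_overlap(map_a, map_b) -> dict:
    """Venn counts of FDR-significant features unique to / shared by two maps."""
    fa = np.asarray(map_a.significant, dtype=bool)
    fb = np.asarray(map_b.significant, dtype=bool)
    if fa.shape != fb.shape:
        raise ValueError("maps must share the same feature set")
    return {
        "n_only_a": int(np.sum(fa & ~fb)),
        "n_only_b": int(np.sum(fb & ~fa)),
        "n_both": int(np.sum(fa & fb)),
    }
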