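"""Comparison machinery: base-rate stratification, paired model tests,
log-linear contingency analysis and chance-level accounting.

To compare the predictability of an acute severity score and a 3-month
outcome on equal footing, both are dichotomized (NIHSS > 4 = non-mild,
mRS >= 2 = poor) and the sample is stratified by randomly removing subjects
from the discordant cell of the more prevalent variable until both positive
counts are equal, which levels the majority-class chance level.  Models are
compared with a paired t-test on per-subject absolute regression errors or a
McNemar test on classification decisions, and three-way (target x data type x
accuracy) contingency structure is tested with log-linear likelihood-ratio
tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "StratifiedSample",
    "binarize_outcomes",
    "stratify_base_rates",
    "paired_residual_test",
    "mcnemar_test",
    "loglinear_lrt",
    "chance_level",
    "rank_correlation_taub",
    "chisq_from_margins",
]


# --------------------------------------------------------------------------
# binarization & stratification


def binarize_outcomes(clinical: pd.DataFrame) -> pd.DataFrame:
    """Dichotomize the clinical outcomes at the standard cut-offs.

    NIHSS > 4 is non-mild stroke (positive); mRS >= 2 is poor outcome
    (positive).  Missing scores propagate as missing.
    """
    out = pd.DataFrame(index=clinical.index)
    if "nihss_24h" in clinical:
        x = clinical["nihss_24h"]
        out["nihss_24h_nonmild"] = (x > 4).where(x.notna())
    if "nihss_3m" in clinical:
        x = clinical["nihss_3m"]
        out["nihss_3m_nonmild"] = (x > 4).where(x.notna())
    if "mrs_3m" in clinical:
        x = clinical["mrs_3m"]
        out["mrs_3m_poor"] = (x >= 2).where(x.notna())
    return out


@dataclass
class StratifiedSample:
    """Result of base-rate stratification of two binary variables."""

    retained: np.ndarray  # subject indices kept
    removed: np.ndarray  # subject indices removed
    binary_a: np.ndarray  # values of variable A on the retained subjects
    binary_b: np.ndarray
    rate_a: float
    rate_b: float
    seed: int


def stratify_base_rates(
    binary_a: np.ndarray, binary_b: np.ndarray, seed: int = 0
) -> StratifiedSample:
    """Equalize the positive counts of two binary variables by removal.

    Repeatedly removes a uniformly random subject that is positive on the
    currently more prevalent variable and negative on the other, until both
    positive counts are equal.  The number of removals is exactly the initial
    count difference; deterministic given ``seed``.
    """
    a = np.asarray(binary_a).astype(bool)
    b = np.asarray(binary_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("variables must be observed on the same subjects")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 21211]))
    keep = np.ones(len(a), dtype=bool)
    removed: list[int] = []
    while True:
        ca, cb = int(a[keep].sum()), int(b[keep].sum())
        if ca == cb:
            break
        if ca > cb:
            cell = keep & a & ~b
        else:
            cell = keep & b & ~a
        candidates = np.nonzero(cell)[0]
        if candidates.size == 0:
            raise ValueError("cannot_stratify")
        drop = int(rng.choice(candidates))
        keep[drop] = False
        removed.append(drop)
    retained = np.nonzero(keep)[0]
    n = retained.size
    rate = float(a[retained].sum() / n) if n else np.nan
    return StratifiedSample(
        retained=retained,
        removed=np.array(removed, dtype=int),
        binary_a=a[retained],
        binary_b=b[retained],
        rate_a=rate,
        rate_b=float(b[retained].sum() / n) if n else np.nan,
        seed=seed,
    )


# --------------------------------------------------------------------------
# paired model comparisons


def paired_residual_test(
    residuals_a: np.ndarray,
    residuals_b: np.ndarray,
    mode: str = "absolute",
) -> dict:
    """Paired two-sided t-test on per-subject regression errors.

    ``mode`` selects the error summary per subject: ``absolute`` (|residual|,
    the default — a test on accuracy), ``squared``, or ``raw`` (signed
    residuals — a test on bias, rarely what a model comparison wants).
    Returns t, df = n - 1, and the two-sided p.
    """
    ra = np.asarray(residuals_a, dtype=float)
    rb = np.asarray(residuals_b, dtype=float)
    if ra.shape != rb.shape:
        raise ValueError("runs must cover the same subjects")
    if ra.size < 3:
        raise ValueError("need at least 3 pairs")
    if mode == "absolute":
        ea, eb = np.abs(ra), np.abs(rb)
    elif mode == "squared":
        ea, eb = ra**2, rb**2
    elif mode == "raw":
        ea, eb = ra, rb
    else:
        raise ValueError(f"unknown mode {mode!r}")
    d = ea - eb
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        return {"t": 0.0, "df": n - 1, "p": 1.0}
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * sstats.t.sf(abs(t), df=n - 1))
    return {"t": t, "df": n - 1, "p": p}


def mcnemar_test(
    correct_a: np.ndarray, correct_b: np.ndarray, exact_threshold: int = 25
) -> dict:
    """McNemar test on paired correct/incorrect classification decisions.

    Uses the exact conditional binomial two-sided p when the discordant total
    b + c is at most ``exact_threshold``, and the chi-squared statistic with
    continuity correction otherwise.  Returns p and the discordant counts
    (b = A correct only, c = B correct only).
    """
    ca = np.asarray(correct_a).astype(bool)
    cb = np.asarray(correct_b).astype(bool)
    if ca.shape != cb.shape:
        raise ValueError("decisions must cover the same subjects")
    b = int(np.sum(ca & ~cb))
    c = int(np.sum(~ca & cb))
    m = b + c
    if m == 0:
        warnings.warn("no discordant pairs; McNemar p = 1", stacklevel=2)
        return {"p": 1.0, "b": b, "c": c, "method": "degenerate"}
    if m <= exact_threshold:
        p = float(min(1.0, 2.0 * sstats.binom.cdf(min(b, c), m, 0.5)))
        method = "exact"
    else:
        chi2 = (abs(b - c) - 1) ** 2 / m
        p = float(sstats.chi2.sf(chi2, df=1))
        method = "chi2_cc"
    return {"p": p, "b": b, "c": c, "method": method}


# --------------------------------------------------------------------------
# log-linear models


_FACTORS = ("target", "datatype", "accuracy")


def _loglinear_design(terms) -> np.ndarray:
    """Effect-coded design matrix for a 2x2x2 log-linear model.

    ``terms`` is a collection over {"target", "datatype", "accuracy"} and
    their interactions written with ":" (e.g. "target:accuracy");
    "saturated" expands to all seven terms.  Cells are ordered by
    itertools.product over (target, datatype, accuracy) levels (0, 1).
    """
    terms = set(terms)
    if "saturated" in terms:
        terms = {
            "target",
            "datatype",
            "accuracy",
            "target:datatype",
            "target:accuracy",
            "datatype:accuracy",
            "target:datatype:accuracy",
        }
    codes = np.array(list(product((1.0, -1.0), repeat=3)))
    col_of = dict(zip(_FACTORS, range(3)))
    cols = [np.ones(8)]
    # fixed canonical order for reproducible designs
    order = [
        "target",
        "datatype",
        "accuracy",
        "target:datatype",
        "target:accuracy",
        "datatype:accuracy",
        "target:datatype:accuracy",
    ]
    for term in order:
        if term not in terms:
            continue
        parts = term.split(":")
        col = np.ones(8)
        for pt in parts:
            if pt not in col_of:
                raise ValueError(f"unknown factor {pt!r}")
            col = col * codes[:, col_of[pt]]
        cols.append(col)
    unknown = terms - set(order)
    if unknown:
        raise ValueError(f"unknown terms {sorted(unknown)}")
    return np.column_stack(cols)


def _poisson_deviance(counts: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Deviance and parameter count of a Poisson log-linear fit by IRLS."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        # a saturated model has zero residual df; statsmodels warns benignly
        warnings.simplefilter("ignore")
        res = sm.GLM(counts, X, family=sm.families.Poisson()).fit()
    return float(res.deviance), X.shape[1]


def loglinear_lrt(
    table: np.ndarray,
    model_small,
    model_large,
) -> dict:
    """Likelihood-ratio test between two nested log-linear models.

    ``table`` is the 2x2x2 count array over (target, datatype, accuracy) —
    any array reshapeable to (2, 2, 2) in that order.  Models are term sets
    (see :func:`_loglinear_design`); the statistic is the deviance
    difference, the df the difference in free parameters, and the p-value is
    read from the chi-squared reference distribution.  Zero cells that make a
    model inestimable get +0.5 added to all cells, with a warning.
    """
    counts = np.asarray(table, dtype=float).reshape(-1)
    if counts.size != 8 or np.any(counts < 0):
        raise ValueError("table must hold 8 nonnegative counts")
    Xs = _loglinear_design(model_small)
    Xl = _loglinear_design(model_large)
    small_set = {tuple(c) for c in Xs.T}
    large_set = {tuple(c) for c in Xl.T}
    if not small_set <= large_set:
        raise ValueError("model_small must be nested in model_large")
    if np.any(counts == 0):
        warnings.warn(
            "zero cells: +0.5 added to all cells for estimability", stacklevel=2
        )
        counts = counts + 0.5
    dev_s, k_s = _poisson_deviance(counts, Xs)
    dev_l, k_l = _poisson_deviance(counts, Xl)
    stat = max(dev_s - dev_l, 0.0)
    df = k_l - k_s
    p = float(sstats.chi2.sf(stat, df)) if df > 0 else 1.0
    return {"statistic": stat, "df": df, "p": p}


def comparison_table(
    correct: dict[tuple[str, str], np.ndarray]
) -> np.ndarray:
    """Build the 2x2x2 (target, datatype, accuracy) count table.

    ``correct`` maps (target_level, datatype_level) — with exactly two levels
    each — to boolean per-subject correctness vectors.  Accuracy level 0 is
    'true', 1 is 'false', matching the cell order of :func:`loglinear_lrt`.
    """
    targets = sorted({k[0] for k in correct})
    datatypes = sorted({k[1] for k in correct})
    if len(targets) != 2 or len(datatypes) != 2:
        raise ValueError("need exactly two targets and two data types")
    out = np.zeros((2, 2, 2), dtype=int)
    for it, t in enumerate(targets):
        for idt, dt in enumerate(datatypes):
            v = np.asarray(correct[(t, dt)]).astype(bool)
            out[it, idt, 0] = int(v.sum())
            out[it, idt, 1] = int((~v).sum())
    return out


# --------------------------------------------------------------------------
# simple summaries


def chance_level(binary_outcome: np.ndarray) -> float:
    """Majority-class proportion, as a percentage."""
    y = np.asarray(binary_outcome)
    y = y[~pd.isna(y)].astype(bool)
    if y.size == 0:
        raise ValueError("empty outcome vector")
    frac = max(y.mean(), 1.0 - y.mean())
    return float(100.0 * frac)


def rank_correlation_taub(x: np.ndarray, y: np.ndarray) -> dict:
    """Kendall tau-b rank correlation with tie correction.

    Returns {"tau_b", "p"}; constant input yields NaN with a warning.  The
    p-value uses the asymptotic normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("paired vectors of length >= 3 required")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant vector: tau-b undefined", stacklevel=2)
        return {"tau_b": np.nan, "p": np.nan}
    res = sstats.kendalltau(x, y, variant="b", method="asymptotic")
    return {"tau_b": float(res.statistic), "p": float(res.pvalue)}


def chisq_from_margins(
    n: int, pos_a: int, pos_b: int, agreement: float
) -> dict:
    """Reconstruct a paired 2x2 table from margins + agreement, and its chi2.

    Given n subjects, positive counts of two binary variables and the
    fraction of subjects on which the variables agree, the four cells are
    determined: with agree = round(agreement * n),
    ``a = (agree + pos_a + pos_b - n) / 2`` (both positive), then
    ``b = pos_a - a``, ``c = pos_b - a``, ``d = n - a - b - c``.  Returns the
    table and the Pearson chi-squared statistic (1 df, no continuity
    correction) of the association between the two variables.
    """
    agree = round(agreement * n)
    twice_a = agree + pos_a + pos_b - n
    if twice_a % 2 != 0:
        raise ValueError("inconsistent_margins")
    a = twice_a // 2
    b = pos_a - a
    c = pos_b - a
    d = n - a - b - c
    if min(a, b, c, d) < 0:
        raise ValueError("inconsistent_margins")
    table = np.array([[a, b], [c, d]], dtype=float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = float(np.nansum((table - expected) ** 2 / expected))
    p = float(sstats.chi2.sf(chi2, df=1))
    return {"table": table.astype(int), "chi2": chi2, "df": 1, "p": p}
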