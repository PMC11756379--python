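"""Mass-univariate maps: exact Fisher, logistic, t maps, FDR, summaries."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats

import lesionkit as lk
from lesionkit.mapping import fisher_exact_p, odds_ratio_2x2
from conftest import make_space


def fisher_oracle(a, b, c, d):
    """Full hypergeometric enumeration with exact integer arithmetic."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    probs = {
        k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(kmin, kmax + 1)
    }
    p_obs = probs[a]
    return sum(v for v in probs.values() if v <= p_obs) / denom


def binary_features_from_tables(tables, n_pos, n_neg):
    """Construct a feature matrix + outcome realizing given 2x2 tables."""
    outcome = np.array([1] * n_pos + [0] * n_neg)
    cols = []
    for a, b, c, d in tables:
        assert a + c == n_pos and b + d == n_neg
        col = np.concatenate([np.ones(a), np.zeros(c), np.ones(b), np.zeros(d)])
        cols.append(col)
    return make_space(np.column_stack(cols), kind="voxel"), outcome


# ------------------------------------------------------------------- fisher


def test_fisher_p_balanced_diagonal_table():
    # (5,0,0,5): only the two extreme tables are as unlikely -> p = 2/252
    space, outcome = binary_features_from_tables([(5, 0, 0, 5)], 5, 5)
    res = lk.fisher_map(space, outcome, q=0.01)
    assert res.p_values[0] == pytest.approx(2 / 252, rel=1e-9)


@pytest.mark.parametrize(
    "table,expected",
    [((2, 1, 1, 2), 4.0), ((3, 0, 1, 2), (3.5 * 2.5) / (0.5 * 1.5))],
)
def test_odds_ratio_values(table, expected):
    assert odds_ratio_2x2(*table) == pytest.approx(expected)


def test_fisher_map_matches_enumeration_oracle():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = int(rng.integers(4, 31))
        a = int(rng.integers(0, n + 1))
        b = int(rng.integers(0, n - a + 1))
        c = int(rng.integers(0, n - a - b + 1))
        d = n - a - b - c
        assert fisher_exact_p(a, b, c, d) == pytest.approx(
            fisher_oracle(a, b, c, d), abs=1e-12
        )


def test_fisher_map_constant_outcome_rejected(tiny_cohort):
    cohort, _ = tiny_cohort
    space = lk.build_voxel_features(cohort, min_patients=5)
    with pytest.raises(ValueError):
        lk.fisher_map(space, np.ones(cohort.n_subjects))


# ----------------------------------------------------------------------- FDR


def test_fdr_step_up_reference_case():
    flags = lk.fdr_correct(np.array([0.001, 0.002, 0.5, 0.9]), q=0.01)
    assert flags.tolist() == [True, True, False, False]
    assert not lk.fdr_correct(np.full(20, 0.5), q=0.01).any()
    assert lk.fdr_correct(np.array([]), q=0.01).size == 0


def test_fdr_flags_monotone_in_p():
    rng = np.random.default_rng(1)
    p = rng.uniform(size=500) ** 3
    flags = lk.fdr_correct(p, q=0.05)
    if flags.any():
        assert p[flags].max() <= p[~flags].min() or not (~flags).any()
    # number of rejections equals the classical step-up count on sorted p
    ps = np.sort(p)
    m = len(ps)
    below = np.nonzero(ps <= (np.arange(1, m + 1) / m) * 0.05)[0]
    k = 0 if below.size == 0 else below[-1] + 1
    assert flags.sum() == k


# -------------------------------------------------------------------- t maps


def test_ttest_map_hand_computed_case():
    # lesioned group outcomes (1,2,3), intact (4,5,6): pooled t = -3.674
    X = np.array([[1], [1], [1], [0], [0], [0]], dtype=float)
    y = np.array([1, 2, 3, 4, 5, 6], dtype=float)
    res = lk.ttest_map(make_space(X, kind="voxel"), y)
    assert res.t_values[0] == pytest.approx(-3.674, abs=1e-3)
    assert res.mean_differences[0] == pytest.approx(-3.0)


def test_ttest_map_sign_convention_and_null():
    X = np.array([[1], [1], [1], [0], [0], [0]], dtype=float)
    y_high_lesioned = np.array([4.0, 5, 6, 1, 2, 3])
    res = lk.ttest_map(make_space(X, kind="voxel"), y_high_lesioned)
    assert res.mean_differences[0] > 0  # higher outcome in lesioned -> positive
    y_equal = np.array([1.0, 2, 3, 1, 2, 3])
    res0 = lk.ttest_map(make_space(X, kind="voxel"), y_equal)
    assert res0.t_values[0] == pytest.approx(0.0)
    assert res0.p_values[0] == pytest.approx(1.0)


@pytest.mark.parametrize("welch", [False, True])
def test_ttest_map_matches_scipy(welch):
    rng = np.random.default_rng(2)
    X = (rng.random((40, 8)) < 0.4).astype(float)
    X = X[:, X.sum(axis=0) >= 2]
    X = X[:, X.sum(axis=0) <= 38]
    y = rng.normal(size=40)
    res = lk.ttest_map(make_space(X, kind="voxel"), y, welch=welch)
    for k in range(X.shape[1]):
        g1, g0 = y[X[:, k] == 1], y[X[:, k] == 0]
        ref = stats.ttest_ind(g1, g0, equal_var=not welch)
        assert res.t_values[k] == pytest.approx(ref.statistic, rel=1e-9)
        assert res.p_values[k] == pytest.approx(ref.pvalue, rel=1e-9)


# ------------------------------------------------------------------ logistic


def test_logistic_or_equals_cross_product_and_statsmodels():
    import statsmodels.api as sm

    rng = np.random.default_rng(3)
    x = (rng.random(200) < 0.45).astype(float)
    logit = -0.3 + 1.1 * x
    y = (rng.random(200) < 1 / (1 + np.exp(-logit))).astype(int)
    space = make_space(x[:, None], kind="connection")
    res = lk.logistic_map(space, y)
    a = np.sum((x == 1) & (y == 1))
    b = np.sum((x == 1) & (y == 0))
    c = np.sum((x == 0) & (y == 1))
    d = np.sum((x == 0) & (y == 0))
    assert res.odds_ratios[0] == pytest.approx((a * d) / (b * c), abs=1e-4)
    # independent numerical oracle: statsmodels Logit fit + LRT
    fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
    assert res.coefficients[0] == pytest.approx(fit.params[1], abs=1e-6)
    null = sm.Logit(y, np.ones((200, 1))).fit(disp=0)
    lrt = 2 * (fit.llf - null.llf)
    assert res.p_values[0] == pytest.approx(stats.chi2.sf(lrt, 1), abs=1e-9)


def test_logistic_null_p_values_uniform():
    """Under independence the LRT p-values are uniform on [0, 1]."""
    rng = np.random.default_rng(4)
    n, reps = 500, 200
    ps = np.empty(reps)
    for r in range(reps):
        x = (rng.random(n) < 0.5).astype(float)
        y = (rng.random(n) < 0.5).astype(int)
        res = lk.logistic_map(make_space(x[:, None], kind="connection"), y)
        ps[r] = res.p_values[0]
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_logistic_separation_flagged_and_constant_rejected():
    x = np.array([1.0, 1, 1, 0, 0, 0, 1, 0])
    y = np.array([1, 1, 1, 0, 0, 0, 1, 0])  # perfect separation
    res = lk.logistic_map(make_space(x[:, None], kind="connection"), y)
    assert res.separation[0]
    assert np.isfinite(res.odds_ratios[0])
    with pytest.raises(ValueError):
        lk.logistic_map(make_space(np.ones((8, 1)), kind="connection"), y)


def test_logistic_count_mode_runs():
    rng = np.random.default_rng(5)
    counts = rng.poisson(2.0, size=200).astype(float)
    y = (rng.random(200) < 1 / (1 + np.exp(-(counts - 2) * 0.5))).astype(int)
    space = make_space(counts[:, None], kind="connection")
    res = lk.logistic_map(space, y, dichotomize=False)
    assert res.odds_ratios[0] > 1.0 and res.p_values[0] < 0.05


# ----------------------------------------------------------------- summaries


def test_region_median_or_threshold_and_oracle():
    rng = np.random.default_rng(6)
    # region 1 holds 3 tested voxels with ORs {1,2,3}; region 2 holds 2
    labels = np.zeros((8, 4, 4), dtype=int)
    labels[:3, 0, 0] = 1
    labels[3:5, 0, 0] = 2
    voxels = np.array([[i, 0, 0] for i in range(5)])
    res = lk.VoxelMapResult(
        outcome_name="o",
        n_subjects=10,
        q=0.01,
        voxels=voxels,
        tables=np.zeros((5, 4)),
        p_values=np.full(5, 0.5),
        odds_ratios=np.array([1.0, 2.0, 3.0, 5.0, 7.0]),
        significant=np.zeros(5, dtype=bool),
    )
    table = lk.region_median_or(res, labels, min_voxels=3)
    row1 = table[table.region == 1].iloc[0]
    assert row1.n_tested_voxels == 3 and row1.median_or == pytest.approx(2.0)
    row2 = table[table.region == 2].iloc[0]
    assert row2.n_tested_voxels == 2 and np.isnan(row2.median_or)
    # oracle: independent sort-based median
    assert row1.median_or == sorted([1.0, 2.0, 3.0])[1]


def _fake_voxel_map(voxels, ors):
    F = len(ors)
    return lk.VoxelMapResult(
        outcome_name="o",
        n_subjects=100,
        q=0.01,
        voxels=voxels,
        tables=np.zeros((F, 4)),
        p_values=np.full(F, 0.5),
        odds_ratios=np.asarray(ors, float),
        significant=np.zeros(F, dtype=bool),
    )


def test_hemisphere_correlation_identity_and_planted():
    rng = np.random.default_rng(7)
    grid = lk.VoxelGrid(shape=(20, 6, 6), midline_x=10)
    voxels = np.array(
        [[x, y, z] for x in list(range(10)) + list(range(11, 20))
         for y in range(6) for z in range(6)]
    )
    ors = rng.lognormal(0, 0.5, size=len(voxels))
    mapA = _fake_voxel_map(voxels, ors)
    res = lk.hemisphere_or_correlation(mapA, mapA, grid)
    assert res["r_left"] == pytest.approx(1.0)
    assert res["r_right"] == pytest.approx(1.0)
    # planted: correlated in the right hemisphere only
    right = grid.hemisphere_of_x(voxels[:, 0]) > 0
    ors_b = rng.lognormal(0, 0.5, size=len(voxels))
    ors_b[right] = ors[right] * np.exp(rng.normal(0, 0.1, right.sum()))
    res2 = lk.hemisphere_or_correlation(mapA, _fake_voxel_map(voxels, ors_b), grid)
    assert res2["r_right"] > res2["r_left"]


def test_hemisphere_correlation_shuffle_ci_covers_zero():
    rng = np.random.default_rng(8)
    grid = lk.VoxelGrid(shape=(22, 8, 8), midline_x=11)
    voxels = np.array(
        [[x, y, z] for x in list(range(11)) + list(range(12, 22))
         for y in range(8) for z in range(8)]
    )
    ors = rng.lognormal(0, 0.5, size=len(voxels))
    mapA = _fake_voxel_map(voxels, ors)
    covered = 0
    n_shuffles = 40
    for _ in range(n_shuffles):
        mapB = _fake_voxel_map(voxels, rng.permutation(ors))
        res = lk.hemisphere_or_correlation(mapA, mapB, grid)
        lo, hi = res["ci_left"]
        covered += lo <= 0 <= hi
        assert abs(res["r_left"]) < 0.2
    assert covered >= 0.85 * n_shuffles


def test_map_overlap_set_oracle():
    rng = np.random.default_rng(9)
    fa = rng.random(300) < 0.3
    fb = rng.random(300) < 0.3

    class M:
        def __init__(self, f):
            self.significant = f

    res = lk.map_overlap(M(fa), M(fb))
    A = set(np.nonzero(fa)[0])
    B = set(np.nonzero(fb)[0])
    assert res["n_only_a"] == len(A - B)
    assert res["n_only_b"] == len(B - A)
    assert res["n_both"] == len(A & B)
    same = lk.map_overlap(M(fa), M(fa))
    assert same["n_only_a"] == same["n_only_b"] == 0
    disjoint = lk.map_overlap(M(fa), M(~fa))
    assert disjoint["n_both"] == 0
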