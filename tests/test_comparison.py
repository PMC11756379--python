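"""Comparison statistics: stratification, paired tests, log-linear models."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lesionkit as lk


# --------------------------------------------------------------- binarization


def test_binarize_cutoffs():
    clinical = pd.DataFrame(
        {
            "nihss_24h": [0, 4, 5, np.nan],
            "mrs_3m": [0, 1, 2, 6],
            "nihss_3m": [0, 2, 10, np.nan],
        }
    )
    out = lk.binarize_outcomes(clinical)
    assert out["nihss_24h_nonmild"].tolist()[:3] == [False, False, True]
    assert pd.isna(out["nihss_24h_nonmild"].iloc[3])
    assert out["mrs_3m_poor"].tolist() == [False, False, True, True]
    assert out["nihss_3m_nonmild"].tolist()[:3] == [False, False, True]


# -------------------------------------------------------------- stratification


def _vectors(n, pos_a, pos_b, overlap):
    """Binary vectors with given positive counts and joint-positive count."""
    a = np.zeros(n, dtype=bool)
    b = np.zeros(n, dtype=bool)
    a[:pos_a] = True
    b[:overlap] = True
    b[pos_a : pos_a + (pos_b - overlap)] = True
    return a, b


def test_stratify_already_equal_removes_nothing():
    a, b = _vectors(100, 30, 30, 20)
    res = lk.stratify_base_rates(a, b, seed=0)
    assert res.removed.size == 0
    assert res.rate_a == res.rate_b


def test_stratify_298_vs_270_removes_28():
    a, b = _vectors(685, 298, 270, 240)
    res = lk.stratify_base_rates(a, b, seed=1)
    assert res.removed.size == 28
    assert res.retained.size == 657
    assert res.binary_a.sum() == res.binary_b.sum() == 270
    assert res.rate_a == pytest.approx(270 / 657)
    # only subjects positive on A and negative on B were removed
    assert all(a[i] and not b[i] for i in res.removed)


def test_stratify_deterministic_and_partition():
    a, b = _vectors(50, 20, 12, 8)
    r1 = lk.stratify_base_rates(a, b, seed=3)
    r2 = lk.stratify_base_rates(a, b, seed=3)
    assert np.array_equal(r1.removed, r2.removed)
    assert sorted(np.concatenate([r1.retained, r1.removed])) == list(range(50))


def test_stratify_small_cases_exhaustive_property():
    """Each removal shrinks the count gap by one; removals are minimal."""
    rng = np.random.default_rng(4)
    for _ in range(300):
        n = int(rng.integers(2, 9))
        a = rng.random(n) < 0.5
        b = rng.random(n) < 0.5
        gap = abs(int(a.sum()) - int(b.sum()))
        res = lk.stratify_base_rates(a, b, seed=int(rng.integers(1000)))
        assert res.removed.size == gap
        assert res.binary_a.sum() == res.binary_b.sum()


# -------------------------------------------------------------- paired tests


def test_paired_residual_test_identical_runs():
    r = np.array([1.0, -2.0, 0.5, 3.0])
    res = lk.paired_residual_test(r, r)
    assert res["t"] == 0.0 and res["p"] == 1.0
    assert res["df"] == 3


def test_paired_residual_test_constructed_difference():
    rng = np.random.default_rng(5)
    d = rng.normal(1.0, 1.0, 100)
    res = lk.paired_residual_test(d, np.zeros(100), mode="raw")
    ref = stats.ttest_rel(d, np.zeros(100))
    assert res["t"] == pytest.approx(ref.statistic)
    assert res["p"] == pytest.approx(ref.pvalue)
    assert res["df"] == 99
    assert 5 < res["t"] < 15 and res["p"] < 1e-8


def test_paired_residual_df_convention():
    rng = np.random.default_rng(6)
    res = lk.paired_residual_test(rng.normal(size=685), rng.normal(size=685))
    assert res["df"] == 684


# ------------------------------------------------------------------ McNemar


def test_mcnemar_reference_values():
    # b = c = 10 -> symmetric discordance, p = 1
    a_correct = np.concatenate([np.ones(10), np.zeros(10), np.ones(30)]).astype(bool)
    b_correct = np.concatenate([np.zeros(10), np.ones(10), np.ones(30)]).astype(bool)
    assert lk.mcnemar_test(a_correct, b_correct)["p"] == pytest.approx(1.0)
    # b = 15, c = 5 -> exact p = 2 P(X <= 5 | n=20)
    a2 = np.concatenate([np.ones(15), np.zeros(5), np.ones(10)]).astype(bool)
    b2 = np.concatenate([np.zeros(15), np.ones(5), np.ones(10)]).astype(bool)
    res = lk.mcnemar_test(a2, b2)
    expected = 2 * sum(math.comb(20, k) for k in range(6)) / 2**20
    assert res["p"] == pytest.approx(expected)
    assert res["p"] == pytest.approx(0.0414, abs=5e-4)
    assert (res["b"], res["c"]) == (15, 5)


def test_mcnemar_no_discordance_warns():
    v = np.array([True, False, True])
    with pytest.warns(UserWarning):
        res = lk.mcnemar_test(v, v)
    assert res["p"] == 1.0


def test_mcnemar_chi2_branch_matches_statsmodels():
    from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

    b, c = 40, 20  # discordant total > 25 -> chi-squared with correction
    a_correct = np.concatenate([np.ones(b), np.zeros(c), np.ones(10)]).astype(bool)
    b_correct = np.concatenate([np.zeros(b), np.ones(c), np.ones(10)]).astype(bool)
    res = lk.mcnemar_test(a_correct, b_correct)
    table = [[10, b], [c, 0]]
    ref = sm_mcnemar(table, exact=False, correction=True)
    assert res["p"] == pytest.approx(ref.pvalue)


def test_mcnemar_exact_matches_enumeration_for_small_discordance():
    for b in range(0, 13):
        for c in range(0, 13):
            if b + c == 0 or b + c > 25:
                continue
            a_correct = np.concatenate([np.ones(b), np.zeros(c)]).astype(bool)
            b_correct = np.concatenate([np.zeros(b), np.ones(c)]).astype(bool)
            res = lk.mcnemar_test(a_correct, b_correct)
            m = b + c
            expected = min(
                1.0, 2 * sum(math.comb(m, k) for k in range(min(b, c) + 1)) / 2**m
            )
            assert res["p"] == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------- log-linear


MAIN = {"target", "datatype", "accuracy"}


def test_loglinear_identical_models_and_saturated():
    rng = np.random.default_rng(7)
    table = rng.integers(5, 50, size=(2, 2, 2))
    res = lk.loglinear_lrt(table, MAIN, MAIN)
    assert res["statistic"] == pytest.approx(0.0, abs=1e-8)
    assert res["p"] == 1.0
    res_sat = lk.loglinear_lrt(table, {"saturated"}, {"saturated"})
    assert res_sat["statistic"] == pytest.approx(0.0, abs=1e-8)


def test_loglinear_deviance_monotone_in_terms():
    rng = np.random.default_rng(8)
    table = rng.integers(5, 60, size=8).astype(float)
    from lesionkit.comparison import _loglinear_design, _poisson_deviance

    models = [
        MAIN,
        MAIN | {"target:accuracy"},
        MAIN | {"target:accuracy", "datatype:accuracy"},
        {"saturated"},
    ]
    devs = [_poisson_deviance(table, _loglinear_design(m))[0] for m in models]
    assert all(d1 >= d2 - 1e-9 for d1, d2 in zip(devs, devs[1:]))
    # saturated model fits exactly
    assert devs[-1] == pytest.approx(0.0, abs=1e-8)


def test_loglinear_detects_planted_interaction():
    # planted target x accuracy association, no three-way structure
    p_acc = {0: 0.8, 1: 0.55}  # accuracy depends on target level
    rng = np.random.default_rng(9)
    n = 800
    table = np.zeros((2, 2, 2))
    for t in (0, 1):
        for d in (0, 1):
            correct = rng.binomial(n // 4, p_acc[t])
            table[t, d, 0] = correct
            table[t, d, 1] = n // 4 - correct
    with_int = MAIN | {"target:accuracy"}
    res = lk.loglinear_lrt(table, MAIN, with_int)
    assert res["df"] == 1 and res["p"] < 0.001
    # absent datatype x accuracy interaction: comparison vs saturated
    both = with_int | {"datatype:accuracy"}
    res2 = lk.loglinear_lrt(table, both, {"saturated"})
    assert res2["df"] == 2


def test_loglinear_requires_nesting_and_valid_table():
    table = np.ones((2, 2, 2))
    with pytest.raises(ValueError):
        lk.loglinear_lrt(table, {"saturated"}, MAIN)
    with pytest.raises(ValueError):
        lk.loglinear_lrt(np.ones(5), MAIN, {"saturated"})


def test_comparison_table_counts():
    correct = {
        ("nihss", "lesion"): np.array([True, True, False]),
        ("nihss", "disconnection"): np.array([True, False, False]),
        ("mrs", "lesion"): np.array([True, True, True]),
        ("mrs", "disconnection"): np.array([False, False, True]),
    }
    table = lk.comparison_table(correct)
    assert table.sum() == 12
    assert table[1, 1, 0] == 2  # nihss x lesion correct (sorted order: mrs first)


# ----------------------------------------------------------- simple summaries


def test_chance_level_values():
    y = np.array([1] * 270 + [0] * 387)
    assert lk.chance_level(y) == pytest.approx(58.9, abs=0.05)
    assert lk.chance_level([1] * 50 + [0] * 50) == pytest.approx(50.0)
    assert lk.chance_level([1] * 298 + [0] * 387) == pytest.approx(56.5, abs=0.05)
    with pytest.raises(ValueError):
        lk.chance_level([])


def test_taub_reference_values_and_oracle():
    assert lk.rank_correlation_taub([1, 2, 3, 4], [1, 2, 3, 4])[
        "tau_b"
    ] == pytest.approx(1.0)
    assert lk.rank_correlation_taub([1, 2, 3, 4], [4, 3, 2, 1])[
        "tau_b"
    ] == pytest.approx(-1.0)
    assert lk.rank_correlation_taub([1, 2, 3, 4], [1, 3, 2, 4])[
        "tau_b"
    ] == pytest.approx(4 / 6)

    def taub_oracle(x, y):
        n = len(x)
        sx = np.sign(x[:, None] - x[None, :])
        sy = np.sign(y[:, None] - y[None, :])
        iu = np.triu_indices(n, k=1)
        conc = (sx[iu] * sy[iu] > 0).sum()
        disc = (sx[iu] * sy[iu] < 0).sum()
        tx = (sx[iu] == 0).sum()
        ty = (sy[iu] == 0).sum()
        n0 = n * (n - 1) / 2
        return (conc - disc) / math.sqrt((n0 - tx) * (n0 - ty))

    rng = np.random.default_rng(10)
    for _ in range(20):
        n = int(rng.integers(5, 40))
        x = rng.integers(0, 8, n).astype(float)
        y = rng.integers(0, 8, n).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            continue
        assert lk.rank_correlation_taub(x, y)["tau_b"] == pytest.approx(
            taub_oracle(x, y), abs=1e-12
        )


def test_taub_constant_vector_missing():
    with pytest.warns(UserWarning):
        res = lk.rank_correlation_taub([1, 1, 1, 1], [1, 2, 3, 4])
    assert np.isnan(res["tau_b"])


# --------------------------------------------------------- table reconstruction


def test_chisq_from_margins_reference_cells():
    res = lk.chisq_from_margins(657, 270, 270, 0.708)
    assert res["table"].ravel().tolist() == [174, 96, 96, 291]
    assert res["chi2"] == pytest.approx(103.2, abs=0.3)


def test_chisq_from_margins_limits():
    # perfect agreement with equal margins: off-diagonal empty, chi2 = n
    res = lk.chisq_from_margins(100, 40, 40, 1.0)
    assert res["table"][0, 1] == 0 and res["table"][1, 0] == 0
    assert res["chi2"] == pytest.approx(100.0)
    # agreement at the independence expectation: chi2 ~ 0
    # margins 50/50 of n=100 -> independence agreement = (25 + 25)/100 = 0.5
    res0 = lk.chisq_from_margins(100, 50, 50, 0.5)
    assert res0["chi2"] == pytest.approx(0.0, abs=1e-9)


def test_chisq_from_margins_inconsistent():
    with pytest.raises(ValueError, match="inconsistent_margins"):
        lk.chisq_from_margins(10, 9, 9, 0.1)
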