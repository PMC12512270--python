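import numpy as np
import pandas as pd
import pytest
from scipy import stats

from orbisym.cohort_stats import (
    compare_many,
    compare_two,
    correlate,
    correlation_matrix,
    describe,
    normality_test,
)


# ---------------------------------------------------------------------------
# describe


def test_describe_closed_form():
    d = describe([1.0, 2.0, 3.0])
    assert d["min"] == 1 and d["max"] == 3 and d["mean"] == 2 and d["sd"] == 1


def test_describe_single_value_sd_missing():
    assert np.isnan(describe([5.0])["sd"])


def test_describe_empty_raises():
    with pytest.raises(ValueError):
        describe([])


def test_describe_matches_numpy_on_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(100):
        v = rng.normal(size=rng.integers(2, 50))
        d = describe(v)
        assert np.isclose(d["mean"], v.mean())
        assert np.isclose(d["sd"], v.std(ddof=1))
        assert d["min"] == v.min() and d["max"] == v.max()


# ---------------------------------------------------------------------------
# normality


def test_normality_matches_reference():
    rng = np.random.default_rng(42)
    sample = rng.normal(size=20)
    res = normality_test(sample)
    w, p = stats.shapiro(sample)
    assert abs(res.statistic - w) < 1e-6
    assert abs(res.p_value - p) < 1e-6


def test_normality_preconditions():
    with pytest.raises(ValueError):
        normality_test([1.0, 2.0])  # n < 3
    with pytest.raises(ValueError):
        normality_test(np.zeros(10))  # zero variance
    with pytest.raises(ValueError):
        normality_test(np.random.default_rng(0).normal(size=5001))


def test_normality_rejects_bimodal():
    rng = np.random.default_rng(1)
    sample = np.concatenate([rng.normal(-5, 1, 25), rng.normal(5, 1, 25)])
    assert normality_test(sample).p_value < 0.05


# ---------------------------------------------------------------------------
# two-group comparisons


def test_compare_two_identical_groups():
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    res = compare_two(a, a, parametric="t")
    assert abs(res.statistic) < 1e-12
    assert abs(res.p_value - 1.0) < 1e-12
    assert res.effect_direction == "equal"


def test_compare_two_matches_reference():
    rng = np.random.default_rng(7)
    a, b = rng.normal(0, 1, 30), rng.normal(0.4, 1.2, 35)
    res = compare_two(a, b, parametric="t")
    s_ref, p_ref = stats.ttest_ind(a, b)
    assert abs(res.statistic - s_ref) < 1e-6
    assert abs(res.p_value - p_ref) < 1e-6
    # independent implementation cross-check
    from statsmodels.stats.weightstats import ttest_ind as sm_ttest

    s_sm, p_sm, _ = sm_ttest(a, b, usevar="pooled")
    assert abs(res.statistic - s_sm) < 1e-6
    assert abs(res.p_value - p_sm) < 1e-6


def test_compare_two_paired_matches_reference():
    rng = np.random.default_rng(8)
    a = rng.normal(0, 1, 20)
    b = a + rng.normal(0.3, 0.5, 20)
    res = compare_two(a, b, paired=True, parametric="t")
    s_ref, p_ref = stats.ttest_rel(a, b)
    assert abs(res.statistic - s_ref) < 1e-12
    assert abs(res.p_value - p_ref) < 1e-12
    assert res.test_name == "paired_t"


def test_compare_two_wilcoxon_paths():
    rng = np.random.default_rng(9)
    a, b = rng.normal(0, 1, 25), rng.normal(1, 1, 25)
    res = compare_two(a, b, parametric="wilcoxon")
    s_ref, p_ref = stats.mannwhitneyu(a, b, alternative="two-sided")
    assert abs(res.statistic - s_ref) < 1e-12
    assert abs(res.p_value - p_ref) < 1e-12
    res_p = compare_two(a, b, paired=True, parametric="wilcoxon")
    s_ref, p_ref = stats.wilcoxon(a, b)
    assert abs(res_p.statistic - s_ref) < 1e-12
    assert abs(res_p.p_value - p_ref) < 1e-12


def test_compare_two_all_zero_paired_diff():
    a = np.array([1.0, 2.0, 3.0])
    res = compare_two(a, a, paired=True, parametric="wilcoxon")
    assert res.p_value == 1.0


def test_compare_two_detects_shift():
    rng = np.random.default_rng(10)
    a, b = rng.normal(0, 1, 50), rng.normal(1, 1, 50)
    assert compare_two(a, b).p_value < 0.05


def test_compare_two_auto_picks_nonparametric_for_skewed():
    rng = np.random.default_rng(11)
    a, b = rng.exponential(1, 40) ** 3, rng.exponential(1, 40) ** 3
    res = compare_two(a, b, parametric="auto")
    assert res.test_name == "wilcoxon_rank_sum"


def test_compare_two_preconditions():
    with pytest.raises(ValueError):
        compare_two([1.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        compare_two([1.0, 2.0], [1.0, 2.0, 3.0], paired=True)
    with pytest.raises(ValueError):
        compare_two([1.0, 2.0], [1.0, 2.0], parametric="bogus")


# ---------------------------------------------------------------------------
# multi-group comparisons


def test_compare_many_identical_groups():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    res = compare_many([a, a, a], parametric="anova")
    assert res.omnibus.p_value > 0.99
    assert (res.posthoc.p_adjusted > 0.99).all()


def test_compare_many_anova_matches_reference():
    rng = np.random.default_rng(12)
    groups = [rng.normal(m, 1, 15) for m in (0.0, 0.3, 1.5)]
    res = compare_many(groups, parametric="anova")
    f_ref, p_ref = stats.f_oneway(*groups)
    assert abs(res.omnibus.statistic - f_ref) < 1e-6
    assert abs(res.omnibus.p_value - p_ref) < 1e-6
    # Tukey HSD against the statsmodels implementation
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    data = np.concatenate(groups)
    labels = np.concatenate([[i] * len(g) for i, g in enumerate(groups)])
    sm = pairwise_tukeyhsd(data, labels)
    ours = res.posthoc.sort_values(["group1", "group2"]).p_adjusted.to_numpy()
    assert np.abs(ours - sm.pvalues).max() < 1e-6


def test_compare_many_flags_correct_pair():
    rng = np.random.default_rng(13)
    sd = 1.0
    groups = [rng.normal(0, sd, 20), rng.normal(0, sd, 20),
              rng.normal(2 * sd, sd, 20)]
    res = compare_many(groups, parametric="anova")
    assert res.omnibus.p_value < 0.05
    ph = res.posthoc.set_index(["group1", "group2"]).p_adjusted
    assert ph[(0, 2)] < 0.05 and ph[(1, 2)] < 0.05
    assert ph[(0, 1)] > 0.05


def test_compare_many_kruskal_path():
    rng = np.random.default_rng(14)
    groups = [rng.exponential(1, 20) ** 3 for _ in range(3)]
    res = compare_many(groups, parametric="kruskal")
    h_ref, p_ref = stats.kruskal(*groups)
    assert abs(res.omnibus.statistic - h_ref) < 1e-6
    assert abs(res.omnibus.p_value - p_ref) < 1e-6
    assert (res.posthoc.p_adjusted <= 1.0).all()
    assert (res.posthoc.method == "rank_sum_holm").all()


def test_holm_adjustment_order():
    # Holm-adjusted p-values are >= raw and monotone in the raw ordering
    rng = np.random.default_rng(15)
    groups = [rng.normal(m, 1, 12) for m in (0.0, 0.5, 2.0)]
    res = compare_many(groups, parametric="kruskal")
    raw = [
        stats.mannwhitneyu(groups[i], groups[j], alternative="two-sided")[1]
        for i, j in [(0, 1), (0, 2), (1, 2)]
    ]
    adj = res.posthoc.p_adjusted.to_numpy()
    assert (adj >= np.asarray(raw) - 1e-12).all()


def test_compare_many_preconditions():
    a = np.array([1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        compare_many([a, a])
    with pytest.raises(ValueError):
        compare_many([a, a, np.array([1.0])])


# ---------------------------------------------------------------------------
# correlations


def test_correlate_perfect_lines():
    x = np.arange(10.0)
    assert np.isclose(correlate(x, 2 * x + 1).statistic, 1.0)
    assert np.isclose(correlate(x, -x).statistic, -1.0)


def test_correlate_matches_reference():
    rng = np.random.default_rng(7)
    cov = [[1.0, 0.7], [0.7, 1.0]]
    xy = rng.multivariate_normal([0, 0], cov, size=30)
    res = correlate(xy[:, 0], xy[:, 1])
    r_ref, p_ref = stats.pearsonr(xy[:, 0], xy[:, 1])
    assert abs(res.statistic - r_ref) < 1e-9
    assert abs(res.p_value - p_ref) < 1e-9
    assert 0.4 < res.statistic < 0.9


def test_correlate_preconditions():
    with pytest.raises(ValueError):
        correlate([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_correlation_matrix_properties():
    rng = np.random.default_rng(16)
    table = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
    table.loc[3, "b"] = np.nan  # pairwise-complete handling
    r, p = correlation_matrix(table, ["a", "b", "c"])
    assert np.allclose(np.diag(r), 1.0)
    assert np.allclose(r.to_numpy(), r.to_numpy().T, atol=1e-12)
    assert np.allclose(p.to_numpy(), p.to_numpy().T, atol=1e-12)
    with pytest.raises(ValueError):
        correlation_matrix(table, ["a", "missing"])
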