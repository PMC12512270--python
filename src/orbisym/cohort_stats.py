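"""Cohort-level statistics over symmetry reports.

The analysis layer a symmetry study needs: descriptive statistics,
Shapiro-Wilk normality testing, two-group comparisons (t-test or the
Wilcoxon family, paired or unpaired, with an automatic parametric /
non-parametric switch), multi-group comparisons (one-way ANOVA with Tukey
HSD post-hoc, or Kruskal-Wallis), and Pearson correlation including full
correlation matrices with pairwise-complete missing handling.  All tests
are two-sided at alpha = 0.05 unless stated otherwise and delegate to
scipy.stats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    effect_direction: str = ""  # e.g. "group1 > group2" by means

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class MultiGroupResult:
    omnibus: TestResult
    posthoc: pd.DataFrame | None = None  # pairwise adjusted p-values


def _clean(values) -> np.ndarray:
    a = np.asarray(values, dtype=np.float64).ravel()
    return a[np.isfinite(a)]


def describe(values) -> dict:
    """Min, max, mean and SD (n-1 denominator); SD is NaN for n < 2."""
    a = _clean(values)
    if a.size == 0:
        raise ValueError("empty input")
    return {
        "min": float(a.min()),
        "max": float(a.max()),
        "mean": float(a.mean()),
        "sd": float(a.std(ddof=1)) if a.size > 1 else float("nan"),
        "n": int(a.size),
    }


def normality_test(values) -> TestResult:
    """Shapiro-Wilk normality test (3 <= n <= 5000)."""
    a = _clean(values)
    if not 3 <= a.size <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {a.size}")
    if np.ptp(a) == 0:
        raise ValueError("zero-variance sample")
    w, p = stats.shapiro(a)
    return TestResult("shapiro_wilk", float(w), float(p), (a.size,))


def compare_two(
    group1,
    group2,
    paired: bool = False,
    parametric: str = "auto",
) -> TestResult:
    """Two-group comparison, two-sided.

    ``parametric='auto'`` runs Shapiro-Wilk on each group (on the paired
    differences when ``paired``) and uses the t-test when normality is not
    rejected at alpha = 0.05, otherwise the Wilcoxon alternative
    (signed-rank when paired, rank-sum / Mann-Whitney otherwise).
    """
    a, b = _clean(group1), _clean(group2)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if paired and a.size != b.size:
        raise ValueError("paired comparison requires equal group sizes")
    if parametric not in ("auto", "t", "wilcoxon"):
        raise ValueError(f"unknown parametric mode {parametric!r}")

    choice = parametric
    if choice == "auto":
        try:
            if paired:
                normal = normality_test(a - b).p_value >= ALPHA
            else:
                normal = (
                    normality_test(a).p_value >= ALPHA
                    and normality_test(b).p_value >= ALPHA
                )
        except ValueError:  # zero variance / tiny n: rank test is safe
            normal = False
        choice = "t" if normal else "wilcoxon"

    direction = (
        "group1 > group2" if a.mean() > b.mean()
        else "group1 < group2" if a.mean() < b.mean() else "equal"
    )
    if choice == "t":
        if paired:
            s, p = stats.ttest_rel(a, b)
            name = "paired_t"
        else:
            s, p = stats.ttest_ind(a, b)
            name = "two_sample_t"
    else:
        if paired:
            diff = a - b
            if np.all(diff == 0):
                return TestResult("wilcoxon_signed_rank", 0.0, 1.0,
                                  (a.size, b.size), "equal")
            s, p = stats.wilcoxon(a, b)
            name = "wilcoxon_signed_rank"
        else:
            s, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            name = "wilcoxon_rank_sum"
    return TestResult(name, float(s), float(p), (a.size, b.size), direction)


def compare_many(groups, parametric: str = "auto") -> MultiGroupResult:
    """Omnibus comparison of >= 3 groups with post-hoc pairwise tests.

    ``anova`` runs one-way ANOVA followed by Tukey HSD; ``kruskal`` runs
    Kruskal-Wallis followed by pairwise rank-sum tests (Holm-adjusted).
    ``auto`` picks ANOVA when every group passes Shapiro-Wilk at
    alpha = 0.05.
    """
    cleaned = [_clean(g) for g in groups]
    if len(cleaned) < 3:
        raise ValueError("compare_many needs >= 3 groups (use compare_two)")
    if any(g.size < 2 for g in cleaned):
        raise ValueError("each group needs at least 2 values")
    if parametric not in ("auto", "anova", "kruskal"):
        raise ValueError(f"unknown parametric mode {parametric!r}")

    choice = parametric
    if choice == "auto":
        try:
            normal = all(normality_test(g).p_value >= ALPHA for g in cleaned)
        except ValueError:
            normal = False
        choice = "anova" if normal else "kruskal"

    ns = tuple(g.size for g in cleaned)
    rows = []
    if choice == "anova":
        f, p = stats.f_oneway(*cleaned)
        omnibus = TestResult("one_way_anova", float(f), float(p), ns)
        tukey = stats.tukey_hsd(*cleaned)
        for i in range(len(cleaned)):
            for j in range(i + 1, len(cleaned)):
                rows.append(
                    dict(group1=i, group2=j,
                         statistic=float(tukey.statistic[i, j]),
                         p_adjusted=float(tukey.pvalue[i, j]),
                         method="tukey_hsd")
                )
    else:
        h, p = stats.kruskal(*cleaned)
        omnibus = TestResult("kruskal_wallis", float(h), float(p), ns)
        raw = []
        for i in range(len(cleaned)):
            for j in range(i + 1, len(cleaned)):
                s, pij = stats.mannwhitneyu(
                    cleaned[i], cleaned[j], alternative="two-sided"
                )
                raw.append((i, j, float(s), float(pij)))
        # Holm step-down adjustment
        order = np.argsort([r[3] for r in raw])
        m = len(raw)
        adjusted = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * raw[idx][3])
            adjusted[idx] = min(1.0, running)
        for (i, j, s, pij), p_adj in zip(raw, adjusted):
            rows.append(dict(group1=i, group2=j, statistic=s,
                             p_adjusted=float(p_adj), method="rank_sum_holm"))
    return MultiGroupResult(omnibus=omnibus, posthoc=pd.DataFrame(rows))


def correlate(x, y) -> TestResult:
    """Pearson correlation with two-sided t-based p-value."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("correlation needs n >= 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    return TestResult("pearson", float(r), float(p), (x.size,))


def correlation_matrix(
    table: pd.DataFrame, variables: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlation matrix over table columns.

    Returns ``(r, p)`` DataFrames, symmetric with unit diagonal.
    """
    for v in variables:
        if v not in table.columns:
            raise ValueError(f"variable {v!r} not in table")
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = correlate(table[variables[i]], table[variables[j]])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.p_value
    return (
        pd.DataFrame(r, index=variables, columns=variables),
        pd.DataFrame(p, index=variables, columns=variables),
    )
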