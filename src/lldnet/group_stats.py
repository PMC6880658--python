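"""Group-difference statistics: Welch t (raw or from printed summaries),
paired t, and continuity-corrected two-proportion tests.

The proportion test is the chi-square test on the 2x2 table with the Yates
continuity correction, whose corrected statistic is exactly 0 (p = 1) when
the counts differ by less than the correction — the behavior needed to
reproduce published borderline results from rounded counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class StatsConfig:
    alpha: float = 0.05

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class GroupComparison:
    variable: str
    mean_sd_per_group: tuple
    statistic: float
    df: float
    p_value: float
    test_kind: str
    flagged: bool = False


def ttest_from_summary(mean1, sd1, n1, mean2, sd2, n2, variable: str = "") -> GroupComparison:
    """Welch two-sample t-test from summary statistics.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2), Satterthwaite df, two-tailed p.
    Zero variance in both groups with equal means yields p = 1, flagged.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0:
        return GroupComparison(variable, ((mean1, sd1, n1), (mean2, sd2, n2)),
                               0.0, float(n1 + n2 - 2), 1.0, "welch_t", flagged=True)
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return GroupComparison(variable, ((mean1, sd1, n1), (mean2, sd2, n2)),
                           float(t), float(df), float(p), "welch_t")


def welch_ttest(x, y, variable: str = "") -> GroupComparison:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return ttest_from_summary(x.mean(), x.std(ddof=1), len(x),
                              y.mean(), y.std(ddof=1), len(y), variable)


def two_proportion_test(k1: int, n1: int, k2: int, n2: int,
                        continuity: bool = True, variable: str = "") -> GroupComparison:
    """Chi-square test of two independent proportions on the 2x2 table,
    with Yates continuity correction when `continuity`."""
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n) or n < 1:
            raise ValueError("need 0 <= k <= n, n >= 1")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    summary = ((k1 / n1, np.nan, n1), (k2 / n2, np.nan, n2))
    if np.any(table.sum(axis=0) == 0):
        return GroupComparison(variable, summary, 0.0, 1.0, 1.0, "two_proportion_cc", flagged=True)
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=continuity)
    return GroupComparison(variable, summary, float(chi2), float(dof), float(p),
                           "two_proportion_cc" if continuity else "two_proportion")


def paired_ttest(x, y, variable: str = "") -> GroupComparison:
    """One-sample t on paired differences, two-tailed."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("paired vectors must have equal length >= 2")
    d = x - y
    sd = d.std(ddof=1)
    msd = ((x.mean(), x.std(ddof=1), len(x)), (y.mean(), y.std(ddof=1), len(y)))
    if sd == 0:
        return GroupComparison(variable, msd, 0.0, float(len(d) - 1),
                               1.0 if d.mean() == 0 else 0.0, "paired_t", flagged=True)
    t = d.mean() / (sd / np.sqrt(len(d)))
    p = 2.0 * stats.t.sf(abs(t), len(d) - 1)
    return GroupComparison(variable, msd, float(t), float(len(d) - 1), float(p), "paired_t")


def table2_report(low, high, matched=None, cohort=None):
    """Demographics/severity comparisons between anxiety groups.

    Welch t for continuous variables and a continuity-corrected proportion
    test for sex before matching; when a MatchResult (and the parent
    cohort) is given, paired t across matched pairs after matching.
    Returns a list of GroupComparison.
    """
    from .data_io import MADRS_COLS
    from .matching import matched_tables

    def cont(table, name):
        if name == "madrs_sum":
            return table.madrs_sum.to_numpy(dtype=float)
        if name == "bai_sum":
            return table.df["bai_sum"].to_numpy(dtype=float)
        return pd.to_numeric(table.df[name]).to_numpy(dtype=float)

    variables = ["age", "education_years", "madrs_sum", *MADRS_COLS, "bai_sum"]
    out = []
    for v in variables:
        out.append(welch_ttest(cont(low, v), cont(high, v), variable=f"{v}_before"))
    out.append(two_proportion_test(int((low.df["sex"] == "F").sum()), low.n,
                                   int((high.df["sex"] == "F").sum()), high.n,
                                   variable="sex_female_before"))

    if matched is not None:
        if cohort is None:
            raise ValueError("matched comparisons need the parent cohort")
        mlow, mhigh = matched_tables(cohort, matched)
        for v in variables:
            out.append(paired_ttest(cont(mlow, v), cont(mhigh, v), variable=f"{v}_after"))
        out.append(two_proportion_test(int((mlow.df["sex"] == "F").sum()), mlow.n,
                                       int((mhigh.df["sex"] == "F").sum()), mhigh.n,
                                       variable="sex_female_after"))
    return out
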