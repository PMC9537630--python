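"""Two-group comparison machinery for the clinical and P-wave tables.

Dispatch follows standard clinical-table practice: normally distributed
continuous variables get a pooled two-sample t-test (mean ± SD summaries),
skewed continuous variables a two-sided Mann–Whitney U (median [IQR]),
categorical variables a Pearson chi-square without continuity correction, or
Fisher's exact test when any expected cell count is below 5.  Normality is a
per-variable declaration, not an automatic test.

:func:`ttest_from_summary` reproduces the pooled t-test from published
n / mean / SD triplets alone — useful for auditing printed tables — and is
exactly equivalent to the raw-data test whenever the raw data have those
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ArgumentError, DegenerateVarianceError

__all__ = [
    "GroupComparison",
    "compare_groups",
    "ttest_from_summary",
    "comparison_table",
    "detection_summary",
]

VariableKind = str  # {"normal_continuous", "skewed_continuous", "categorical"}


@dataclass
class GroupComparison:
    """Result of one two-group comparison, Table-1 display style."""

    variable: str
    test: str                 # {"t", "mann_whitney", "chi2", "fisher"}
    n: tuple[int, int]
    summary: tuple[str, str]  # formatted per group
    statistic: float
    p_value: float


def _summaries(kind: VariableKind, g0: np.ndarray, g1: np.ndarray,
               ) -> tuple[str, str]:
    if kind == "normal_continuous":
        return tuple(f"{g.mean():.2f} ± {g.std(ddof=1):.2f}" for g in (g0, g1))
    if kind == "skewed_continuous":
        out = []
        for g in (g0, g1):
            q1, med, q3 = np.percentile(g, [25, 50, 75])
            out.append(f"{med:.1f} ({q1:.1f}, {q3:.1f})")
        return tuple(out)
    out = []
    for g in (g0, g1):
        k = int(np.sum(g == 1))
        out.append(f"{k} ({100.0 * k / g.size:.1f}%)")
    return tuple(out)


def compare_groups(table: pd.DataFrame, variable: str, kind: VariableKind,
                   group_col: str = "poaf") -> GroupComparison:
    """Compare one variable between the two outcome groups.

    ``kind`` selects the test: pooled t for ``normal_continuous``,
    Mann–Whitney U for ``skewed_continuous``, chi-square (Fisher when any
    expected count < 5 in a 2×2) for ``categorical``.  All tests two-tailed.
    """
    if kind not in ("normal_continuous", "skewed_continuous", "categorical"):
        raise ArgumentError(f"unknown variable kind: {kind!r}")
    sub = table[[variable, group_col]].dropna()
    g0 = sub.loc[sub[group_col] == 0, variable].to_numpy(dtype=float)
    g1 = sub.loc[sub[group_col] == 1, variable].to_numpy(dtype=float)
    if g0.size == 0 or g1.size == 0:
        raise ArgumentError("both groups must be non-empty")

    if kind == "normal_continuous":
        if np.ptp(np.concatenate([g0, g1])) == 0:
            raise DegenerateVarianceError(
                f"{variable}: all values identical in both groups")
        res = stats.ttest_ind(g0, g1, equal_var=True)
        test, stat, p = "t", float(res.statistic), float(res.pvalue)
    elif kind == "skewed_continuous":
        res = stats.mannwhitneyu(g0, g1, alternative="two-sided")
        test, stat, p = "mann_whitney", float(res.statistic), float(res.pvalue)
    else:
        tab = pd.crosstab(sub[group_col], sub[variable]).to_numpy()
        if min(tab.shape) < 2:
            # No variation in the variable: no association testable.
            test, stat, p = "fisher", np.nan, 1.0
        else:
            expected = stats.contingency.expected_freq(tab)
            if (expected < 5).any() and tab.shape == (2, 2):
                res = stats.fisher_exact(tab)
                test, stat, p = "fisher", float(res[0]), float(res[1])
            else:
                chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
                test, stat, p = "chi2", float(chi2), float(p)

    return GroupComparison(variable=variable, test=test,
                           n=(g0.size, g1.size),
                           summary=_summaries(kind, g0, g1),
                           statistic=stat, p_value=p)


def ttest_from_summary(n1: int, mean1: float, sd1: float,
                       n2: int, mean2: float, sd2: float,
                       ) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test from summary statistics.

    Returns (t, degrees of freedom, two-tailed p).  Agrees with the raw-data
    pooled t-test to machine precision whenever the raw samples have exactly
    these n / mean / SD.
    """
    if n1 < 2 or n2 < 2:
        raise ArgumentError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ArgumentError("SDs must be non-negative")
    if sd1 == 0 and sd2 == 0:
        raise DegenerateVarianceError("both group SDs are zero")
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                      equal_var=True)
    return float(t), int(n1 + n2 - 2), float(p)


def comparison_table(table: pd.DataFrame, kinds: Mapping[str, VariableKind],
                     group_col: str = "poaf") -> pd.DataFrame:
    """Run :func:`compare_groups` over many variables; one row each."""
    rows = []
    for var, kind in kinds.items():
        c = compare_groups(table, var, kind, group_col=group_col)
        rows.append({
            "variable": c.variable, "test": c.test,
            "group0_n": c.n[0], "group1_n": c.n[1],
            "group0_summary": c.summary[0], "group1_summary": c.summary[1],
            "statistic": c.statistic, "p_value": c.p_value,
        })
    return pd.DataFrame(rows)


def detection_summary(n_monitored: int = 105, n_excluded: int = 5,
                      n_poaf_longterm: int = 31, n_missed_routine: int = 12,
                      ) -> dict[str, float]:
    """Cohort bookkeeping and POAF detection rates.

    From the monitored cohort, patients excluded (e.g. paroxysmal AF found
    preoperatively) leave the included cohort; long-term monitoring detects
    ``n_poaf_longterm`` POAF cases of which routine ward/ICU monitoring
    misses ``n_missed_routine``.  Rates are percentages of the included
    cohort.
    """
    if n_excluded > n_monitored:
        raise ArgumentError("cannot exclude more patients than monitored")
    if n_missed_routine > n_poaf_longterm:
        raise ArgumentError("cannot miss more cases than were detected")
    n_included = n_monitored - n_excluded
    if n_poaf_longterm > n_included:
        raise ArgumentError("detected cases exceed included cohort")
    n_routine = n_poaf_longterm - n_missed_routine
    return {
        "n_monitored": n_monitored,
        "n_included": n_included,
        "n_poaf_longterm": n_poaf_longterm,
        "n_poaf_routine": n_routine,
        "longterm_rate_pct": 100.0 * n_poaf_longterm / n_included,
        "routine_rate_pct": 100.0 * n_routine / n_included,
    }
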