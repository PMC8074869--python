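"""Univariate cohort-comparison statistics.

Chi-square tests for categorical variables (Yates-corrected for 2x2 tables,
plain Pearson for larger tables) and one-way ANOVA F tests for continuous
variables — including reconstruction of the F statistic from printed
per-group summaries alone, under the population-SD (divisor n) convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GroupSummary:
    """One group's size, mean and population SD (divisor n)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if self.sd < 0:
            raise ValueError("SD must be >= 0")


def chi_square_test(table) -> dict[str, float]:
    """Pearson chi-square on an r x c contingency table.

    Yates continuity correction is applied iff the table is exactly 2x2.
    A zero row or column margin raises.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(t < 0) or t.sum() <= 0:
        raise ValueError("counts must be non-negative with positive total")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero row/column margin")
    correction = t.shape == (2, 2)
    res = stats.chi2_contingency(t, correction=correction)
    return {"statistic": float(res.statistic), "df": int(res.dof),
            "p_value": float(res.pvalue)}


def anova_f_from_summaries(groups: list[GroupSummary]) -> dict[str, float]:
    """One-way ANOVA F reconstructed from per-group (n, mean, SD) summaries.

    Between-group SS from the group means; within-group SS as sum of
    n_g * SD_g^2 (population-SD convention).  Zero within-group variance
    with unequal means yields F = inf, p = 0.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups], dtype=float)
    sds = np.array([g.sd for g in groups], dtype=float)
    N, k = ns.sum(), len(groups)
    if N <= k:
        raise ValueError("total n must exceed the number of groups")
    grand = (ns * means).sum() / N
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = (ns * sds**2).sum()
    df_b, df_w = k - 1, int(N - k)
    if ss_within == 0:
        F = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        F = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(F, df_b, df_w))
    return {"F": float(F), "df_between": df_b, "df_within": df_w, "p_value": p}


def anova_f_raw(groups: list) -> dict[str, float]:
    """Standard one-way ANOVA on raw per-group value vectors."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need >= 2 non-empty groups")
    if all(np.ptp(np.concatenate(arrays)) == 0 for _ in [0]):
        return {"F": 0.0,
                "df_between": len(arrays) - 1,
                "df_within": int(sum(a.size for a in arrays) - len(arrays)),
                "p_value": 1.0}
    res = stats.f_oneway(*arrays)
    return {"F": float(res.statistic),
            "df_between": len(arrays) - 1,
            "df_within": int(sum(a.size for a in arrays) - len(arrays)),
            "p_value": float(res.pvalue)}


def summaries_from_raw(groups: list) -> list[GroupSummary]:
    """Population-SD summaries of raw group vectors (for cross-checks)."""
    return [GroupSummary(n=len(g), mean=float(np.mean(g)),
                         sd=float(np.std(g, ddof=0))) for g in groups]


def characteristics_report(clinical: pd.DataFrame, labels,
                           categorical=None, continuous=None) -> pd.DataFrame:
    """Cohort characteristics table: per-variable test statistic and p value.

    Categorical columns are cross-tabulated against the outcome and tested
    by chi-square (Yates for 2x2); continuous columns by one-way ANOVA.
    """
    from .features import CLINICAL_CATEGORICAL, CLINICAL_CONTINUOUS

    categorical = categorical or [c for c in CLINICAL_CATEGORICAL
                                  if c in clinical.columns]
    continuous = continuous or [c for c in CLINICAL_CONTINUOUS
                                if c in clinical.columns]
    y = np.asarray(labels)
    rows = []
    for col in categorical:
        tab = pd.crosstab(clinical[col], y)
        if tab.shape[0] < 2:
            continue
        res = chi_square_test(tab.to_numpy())
        rows.append({"variable": col, "test": "chi_square",
                     "statistic": res["statistic"], "p_value": res["p_value"]})
    for col in continuous:
        vals = clinical[col].astype(float)
        groups = [vals[y == g].dropna().to_numpy() for g in np.unique(y)]
        res = anova_f_raw(groups)
        rows.append({"variable": col, "test": "anova_f",
                     "statistic": res["F"], "p_value": res["p_value"]})
    return pd.DataFrame(rows)
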