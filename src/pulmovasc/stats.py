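"""Group-comparison statistics for per-animal measurement tables.

One-way ANOVA with Tukey's HSD post hoc (all pairwise comparisons via the
studentized-range distribution), the pooled-variance two-sample Student's t
test, and Pearson's chi-square on positive/total proportions. Tests are
two-sided at alpha = 0.05; missing values are dropped listwise and the count
is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestReport",
    "one_way_anova_tukey",
    "two_sample_t",
    "chi2_proportions",
]

ALPHA = 0.05


@dataclass
class TestReport:
    test: str
    statistic: float
    df: tuple
    p_value: float
    alpha: float = ALPHA
    pairwise: list[tuple[str, str, float]] = field(default_factory=list)
    significant: dict = field(default_factory=dict)
    n_dropped: int = 0

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": list(self.df),
            "p_value": self.p_value,
            "alpha": self.alpha,
            "pairwise": [list(p) for p in self.pairwise],
            "significant": self.significant,
            "n_dropped": self.n_dropped,
        }


def _extract_groups(
    table: pd.DataFrame, value_col: str, group_col: str
) -> tuple[list[str], list[np.ndarray], int]:
    if group_col not in table or value_col not in table:
        raise ValueError(f"table needs columns {group_col!r} and {value_col!r}")
    clean = table[[group_col, value_col]].dropna()
    n_dropped = len(table) - len(clean)
    labels = list(pd.unique(clean[group_col]))
    groups = [clean.loc[clean[group_col] == g, value_col].to_numpy(float) for g in labels]
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for g, arr in zip(labels, groups):
        if len(arr) < 2:
            raise ValueError(f"group {g!r} has n < 2")
    return labels, groups, n_dropped


def one_way_anova_tukey(
    table: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
    posthoc: bool = True,
) -> TestReport:
    """One-way ANOVA (F with k-1, N-k df) followed by Tukey's HSD.

    Tukey-adjusted p-values come from the studentized-range distribution and
    are >= the corresponding unprotected pairwise t p-values. Two groups with
    identical values give F = 0, p = 1. ``posthoc=False`` skips the pairwise
    comparisons (useful in long calibration loops that only need the omnibus
    F test).
    """
    labels, groups, n_dropped = _extract_groups(table, value_col, group_col)
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    f_stat, p = sps.f_oneway(*groups)
    if np.isnan(f_stat):  # zero between- and within-group variance
        f_stat, p = 0.0, 1.0

    pairwise = []
    significant = {}
    if posthoc:
        tukey = sps.tukey_hsd(*groups)
        for i in range(k):
            for j in range(i + 1, k):
                p_adj = float(tukey.pvalue[i, j])
                pairwise.append((str(labels[i]), str(labels[j]), p_adj))
                significant[f"{labels[i]} vs {labels[j]}"] = bool(p_adj < ALPHA)
    return TestReport(
        test="anova_tukey",
        statistic=float(f_stat),
        df=(k - 1, n_total - k),
        p_value=float(p),
        pairwise=pairwise,
        significant=significant,
        n_dropped=n_dropped,
    )


def two_sample_t(
    table: pd.DataFrame, value_col: str = "value", group_col: str = "group"
) -> TestReport:
    """Two-sided Student's t test with pooled variance, df = n1 + n2 - 2."""
    labels, groups, n_dropped = _extract_groups(table, value_col, group_col)
    if len(groups) != 2:
        raise ValueError(f"two_sample_t needs exactly 2 groups, got {len(groups)}")
    a, b = groups
    t_stat, p = sps.ttest_ind(a, b, equal_var=True)
    if np.isnan(t_stat):  # identical constant groups
        t_stat, p = 0.0, 1.0
    return TestReport(
        test="student_t",
        statistic=float(t_stat),
        df=(len(a) + len(b) - 2,),
        p_value=float(p),
        significant={f"{labels[0]} vs {labels[1]}": bool(p < ALPHA)},
        n_dropped=n_dropped,
    )


def chi2_proportions(
    positives_a: int, total_a: int, positives_b: int, total_b: int,
    continuity_correction: bool = False,
) -> TestReport:
    """Pearson's chi-square on a 2x2 positives/negatives table, df = 1.

    No continuity correction by default (plain Pearson statistic); Yates'
    correction is available behind the flag.
    """
    for pos, tot in ((positives_a, total_a), (positives_b, total_b)):
        if tot <= 0:
            raise ValueError("totals must be positive")
        if not 0 <= pos <= tot:
            raise ValueError("need 0 <= positives <= total")
    obs = np.array(
        [
            [positives_a, total_a - positives_a],
            [positives_b, total_b - positives_b],
        ],
        dtype=float,
    )
    if positives_a == positives_b and total_a == total_b:
        # identical proportions: chi2 = 0 regardless of expected-count issues
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = sps.chi2_contingency(obs, correction=continuity_correction)
    return TestReport(
        test="pearson_chi2",
        statistic=float(chi2),
        df=(1,),
        p_value=float(p),
        significant={"a vs b": bool(p < ALPHA)},
    )
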