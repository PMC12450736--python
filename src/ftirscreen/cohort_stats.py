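"""Group-comparison statistics for cohort characteristics tables.

Categorical (yes/no by group) variables are tested with the Pearson
chi-square without continuity correction, switching to Fisher's exact
test (two-sided) whenever any expected cell count falls below 5 — the
standard small-sample rule.  Continuous variables pass through a
Shapiro-Wilk normality gate (alpha 0.05 per group): both groups normal
-> Welch's t-test; otherwise the Mann-Whitney U test with normal
approximation and tie correction.  Differences are flagged significant
at p < 0.05, matching the usual presentation of a demographics table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05
MIN_EXPECTED = 5.0


@dataclass(frozen=True)
class TwoByTwo:
    """Counts (group x yes/no): a, b = group-1 yes/no; c, d = group-2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be >= 0")

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def expected(self) -> np.ndarray:
        t = self.table
        return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()


@dataclass
class GroupComparison:
    variable: str
    test_used: str  # chi_square | fisher_exact | t_test | mann_whitney
    statistic: float
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")
        if self.significant != (self.p_value < ALPHA):
            raise ValueError("significance flag inconsistent with p-value")


def _comparison(variable, test, stat, p) -> GroupComparison:
    p = float(min(max(p, 0.0), 1.0))
    return GroupComparison(variable, test, float(stat), p, p < ALPHA)


def compare_categorical(t: TwoByTwo, variable: str = "") -> GroupComparison:
    """Pearson chi-square (no continuity correction); Fisher's exact when
    any expected count < 5."""
    tab = t.table
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("both margins must be positive")
    if (t.expected() < MIN_EXPECTED).any():
        stat, p = stats.fisher_exact(tab, alternative="two-sided")
        return _comparison(variable, "fisher_exact", stat, p)
    stat, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return _comparison(variable, "chi_square", stat, p)


def compare_continuous(x, y, variable: str = "") -> GroupComparison:
    """Shapiro-Wilk gate at alpha 0.05 per group; both normal -> Welch
    t-test, otherwise Mann-Whitney U (asymptotic, tie-corrected).
    Constant samples cannot be gated and take the rank path."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 values per group")

    def normal(v: np.ndarray) -> bool:
        if np.ptp(v) == 0.0:  # Shapiro undefined for constant input
            return False
        return stats.shapiro(v).pvalue >= ALPHA

    if normal(x) and normal(y):
        res = stats.ttest_ind(x, y, equal_var=False)
        return _comparison(variable, "t_test", res.statistic, res.pvalue)

    if np.ptp(np.concatenate([x, y])) == 0.0:
        # all observations identical: no evidence of shift
        return _comparison(variable, "mann_whitney", x.size * y.size / 2.0, 1.0)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return _comparison(variable, "mann_whitney", res.statistic, res.pvalue)


def table_one(covariates: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Demographics-style summary: per variable, per-group counts or
    mean +/- sd, the test applied, and its p-value.

    Columns with exactly the values {Yes, No} are treated as categorical;
    numeric columns as continuous.  Groups must be the two labels
    'negative' and 'positive'.
    """
    if group_col not in covariates.columns:
        raise ValueError(f"missing group column {group_col!r}")
    g0 = covariates[covariates[group_col] == "negative"]
    g1 = covariates[covariates[group_col] == "positive"]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("both groups must be present")

    rows = []
    for col in covariates.columns:
        if col in (group_col, "patient_id"):
            continue
        series = covariates[col]
        if pd.api.types.is_numeric_dtype(series):
            cmp = compare_continuous(g0[col].to_numpy(), g1[col].to_numpy(), col)
            rows.append({
                "variable": col,
                "negative": f"{g0[col].mean():.1f} ± {g0[col].std():.1f}",
                "positive": f"{g1[col].mean():.1f} ± {g1[col].std():.1f}",
                "test": cmp.test_used,
                "p_value": cmp.p_value,
                "significant": cmp.significant,
            })
        else:
            a = int((g0[col] == "Yes").sum())
            c = int((g1[col] == "Yes").sum())
            t = TwoByTwo(a, len(g0) - a, c, len(g1) - c)
            cmp = compare_categorical(t, col)
            rows.append({
                "variable": col,
                "negative": f"{a} ({100.0 * a / len(g0):.0f} %)",
                "positive": f"{c} ({100.0 * c / len(g1):.0f} %)",
                "test": cmp.test_used,
                "p_value": cmp.p_value,
                "significant": cmp.significant,
            })
    return pd.DataFrame(rows)
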