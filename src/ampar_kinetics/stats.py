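"""Group comparisons with the reporting shape of figure legends:
mean +/- SEM per group, classical two-sample t tests and one-way ANOVA.

No multiple-testing correction is applied anywhere (documented choice); the
Welch correction is off by default so the statistics match the classical
pooled-variance t test, but is available as a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["GroupSummary", "TestResult", "compare_groups", "anova_oneway"]


@dataclass
class GroupSummary:
    """Labelled sample with mean +/- SEM reporting."""

    label: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 2:
            raise ValueError(f"group {self.label!r} needs n >= 2")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sem(self) -> float:
        return float(self.values.std(ddof=1) / np.sqrt(self.n))

    def __str__(self) -> str:
        return f"{self.label}: {self.mean:.3g} ± {self.sem:.2g} (n = {self.n})"


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test: str
    df: float
    flags: list[str]


def compare_groups(
    a: GroupSummary,
    b: GroupSummary,
    test: str = "unpaired_t",
    welch: bool = False,
) -> TestResult:
    """Two-sided two-sample t test (unpaired pooled-variance, Welch, or paired)."""
    flags: list[str] = []
    if test == "unpaired_t":
        if np.array_equal(a.values, b.values):
            # degenerate but well-defined: no difference
            df = a.n + b.n - 2
            return TestResult(0.0, 1.0, test, df, ["identical-groups"])
        res = sps.ttest_ind(a.values, b.values, equal_var=not welch)
        df = float(res.df)
    elif test == "paired_t":
        if a.n != b.n:
            raise ValueError("paired test requires equal group sizes")
        diff = a.values - b.values
        if np.all(diff == 0):
            return TestResult(0.0, 1.0, test, a.n - 1, ["identical-groups"])
        res = sps.ttest_rel(a.values, b.values)
        df = float(a.n - 1)
    else:
        raise ValueError(f"unknown test {test!r}")
    stat, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(stat):
        flags.append("degenerate-variance")
        stat, p = 0.0, 1.0
    return TestResult(stat, p, ("welch_t" if welch and test == "unpaired_t" else test), df, flags)


def anova_oneway(groups: list[GroupSummary]) -> TestResult:
    """Classical one-way ANOVA (omnibus F, two groups give F = t^2)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    values = [g.values for g in groups]
    ns = np.array([v.size for v in values])
    grand = np.concatenate(values).mean()
    ss_between = float(sum(n * (v.mean() - grand) ** 2 for n, v in zip(ns, values)))
    ss_within = float(sum(((v - v.mean()) ** 2).sum() for v in values))
    df_between = len(groups) - 1
    df_within = int(ns.sum()) - len(groups)
    flags: list[str] = []
    if ss_within == 0:
        if ss_between == 0:
            return TestResult(0.0, 1.0, "anova_oneway", df_between, ["identical-groups"])
        flags.append("zero-within-variance")
        return TestResult(float("inf"), 0.0, "anova_oneway", df_between, flags)
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    if ss_between == 0:
        f, p = 0.0, 1.0
    return TestResult(float(f), p, "anova_oneway", df_between, flags)
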