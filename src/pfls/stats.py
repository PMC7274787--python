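"""Statistical comparisons used by the pipeline report.

All two-sample t tests use the pooled-variance (Student) form, so the
reported degrees of freedom are n1 + n2 - 2; no multiple-testing correction
is applied and raw p values are reported.  Proportion comparisons are run
as two-sample t tests on binary indicators, with a two-proportion z test
also emitted for reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    """Inadequate sample for the requested test."""


@dataclass
class TestResult:
    test: str
    statistic: float
    df: Optional[float]
    p: float
    n1: int
    n2: Optional[int] = None


def compare_groups(a, b=None, test: str = "t", popmean: float = 0.0) -> TestResult:
    """Run one of the supported tests and return (statistic, df, p).

    test: "t" (pooled two-sample, two-tailed), "one_sample_t", "paired_t",
    "ks" (two-sample Kolmogorov-Smirnov), or "chi2" (Pearson chi-square on a
    count table passed as ``a``).
    """
    a = np.asarray(a, dtype=float)
    if test == "t":
        b = np.asarray(b, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise StatsError("two-sample t needs >= 2 values per group")
        r = sps.ttest_ind(a, b, equal_var=True)
        return TestResult("t", float(r.statistic), float(len(a) + len(b) - 2),
                          float(r.pvalue), len(a), len(b))
    if test == "one_sample_t":
        if len(a) < 2:
            raise StatsError("one-sample t needs >= 2 values")
        r = sps.ttest_1samp(a, popmean)
        return TestResult("one_sample_t", float(r.statistic), float(len(a) - 1),
                          float(r.pvalue), len(a))
    if test == "paired_t":
        b = np.asarray(b, dtype=float)
        if len(a) != len(b) or len(a) < 2:
            raise StatsError("paired t needs equal-length groups of >= 2")
        r = sps.ttest_rel(a, b)
        return TestResult("paired_t", float(r.statistic), float(len(a) - 1),
                          float(r.pvalue), len(a), len(b))
    if test == "ks":
        b = np.asarray(b, dtype=float)
        r = sps.ks_2samp(a, b)
        return TestResult("ks", float(r.statistic), None, float(r.pvalue),
                          len(a), len(b))
    if test == "chi2":
        table = np.asarray(a, dtype=float)
        r = sps.chi2_contingency(table, correction=False)
        return TestResult("chi2", float(r.statistic), float(r.dof),
                          float(r.pvalue), int(table.sum()))
    raise StatsError(f"unknown test {test!r}")


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Two-proportion z test (pooled), reported alongside indicator t tests."""
    p1, p2 = k1 / n1, k2 / n2
    p = (k1 + k2) / (n1 + n2)
    se = np.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
    if se == 0:
        return TestResult("two_prop_z", 0.0, None, 1.0, n1, n2)
    z = (p1 - p2) / se
    return TestResult("two_prop_z", float(z), None,
                      float(2 * sps.norm.sf(abs(z))), n1, n2)
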