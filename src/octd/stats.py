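"""Two-group comparisons from summary statistics.

Published cohort results are printed as mean ± SD with group sizes, so the
unpaired t-test is reconstructed from those summaries: the pooled (Student)
variant by default, Welch as an alternative. ``compare_cohorts`` reduces raw
measurement lists to summaries first, and agrees exactly with a
direct-from-raw t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = ["GroupSummary", "TestResult", "summary_ttest", "compare_cohorts"]


@dataclass(frozen=True)
class GroupSummary:
    """Mean, sample SD and size of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("each group needs n >= 2")


@dataclass(frozen=True)
class TestResult:
    t_statistic: float
    df: float
    p_two_sided: float
    variant: str
    degenerate_variance: bool = False


def _two_sided_p(t: float, df: float) -> float:
    """P(|T_df| >= |t|) via the Student-t CDF (regularized incomplete beta)."""
    return float(2.0 * special.stdtr(df, -abs(t)))


def summary_ttest(
    a: GroupSummary, b: GroupSummary, variant: str = "pooled"
) -> TestResult:
    """Unpaired two-sample t-test from group summaries.

    ``pooled`` uses the pooled variance with df = n_a + n_b − 2; ``welch``
    uses the Welch–Satterthwaite degrees of freedom. Two zero-variance
    groups yield t = 0, p = 1 for equal means, and a flagged p below
    machine resolution for unequal means.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    diff = a.mean - b.mean
    if a.sd == 0 and b.sd == 0:
        if diff == 0:
            return TestResult(0.0, a.n + b.n - 2, 1.0, variant, degenerate_variance=True)
        return TestResult(
            float(np.copysign(np.inf, diff)), a.n + b.n - 2, 0.0, variant,
            degenerate_variance=True,
        )
    if variant == "pooled":
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
        se = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    t = diff / se
    return TestResult(float(t), float(df), _two_sided_p(t, df), variant)


def compare_cohorts(
    results_a: list[float], results_b: list[float], variant: str = "pooled"
) -> TestResult:
    """Unpaired t-test on two lists of raw measurements.

    Each list is reduced to a :class:`GroupSummary` (sample SD, ddof=1) and
    delegated to :func:`summary_ttest`; this matches a direct-from-raw
    t-test to machine precision.
    """
    xa = np.asarray(results_a, dtype=float)
    xb = np.asarray(results_b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each cohort needs at least 2 values")
    a = GroupSummary(float(xa.mean()), float(xa.std(ddof=1)), int(xa.size))
    b = GroupSummary(float(xb.mean()), float(xb.std(ddof=1)), int(xb.size))
    return summary_ttest(a, b, variant)
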