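"""Group comparisons: two-sample Student's t-test with significance stars.

Comparisons use the equal-variance (pooled) Student's t by default, two-sided, with
``df = n_a + n_b - 2``; a Welch variant is available behind a flag.  Significance is
annotated as ``*`` (p < 0.05), ``**`` (p < 0.01), ``***`` (p < 0.001), else ``ns``.
No multiple-testing correction is applied; comparisons are reported marginally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from rf3h.quantification import ConditionGroup


def stars_for_p(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class TestResult:
    group_a: str
    group_b: str
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    stars: str


def students_t_test(
    a, b, label_a: str = "a", label_b: str = "b", welch: bool = False
) -> TestResult:
    """Two-sided two-sample t-test between two groups of normalized values."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2 for a t-test")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    t = float(res.statistic)
    p = float(res.pvalue)
    if welch:
        df = float(res.df)
    else:
        df = float(a.size + b.size - 2)
    if math.isnan(t):  # zero pooled variance with equal means
        t, p = 0.0, 1.0
    return TestResult(
        group_a=label_a,
        group_b=label_b,
        t_statistic=t,
        degrees_of_freedom=df,
        p_value=p,
        stars=stars_for_p(p),
    )


def summarize_group(g: ConditionGroup) -> dict:
    """Arithmetic mean and sample SD (n-1); SD is NaN (flagged) for n = 1."""
    if g.n == 0:
        raise ValueError(f"group {g.label!r} is empty")
    return {"label": g.label, "n": g.n, "mean": g.mean, "sd": g.sd}


def pairwise_vs_control(groups: list[ConditionGroup], welch: bool = False) -> list[TestResult]:
    """Compare every non-control group against the designated control."""
    controls = [g for g in groups if g.is_control]
    if len(controls) != 1:
        raise ValueError("exactly one control group required")
    control = controls[0]
    return [
        students_t_test(control.values, g.values, control.label, g.label, welch=welch)
        for g in groups
        if not g.is_control
    ]
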