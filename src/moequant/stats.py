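"""Unpaired two-tailed t-test and the study's significance tiering.

The comparison of a labeled condition against its negative control uses
an unpaired two-tailed t-test; p-values are reported with a star tier:

    *** p <= 0.005,  ** p <= 0.01,  * p <= 0.05,  ns otherwise

(all boundaries inclusive).  The classical Student (equal-variance) test
is the default; Welch is available via ``variant="welch"`` and the
variant used is carried in the result so output tables are auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from ._exceptions import DegenerateVarianceError, ValidationError

VARIANTS = ("student", "welch")

#: inclusive upper bounds of each star tier, most significant first
STAR_TIERS = (("***", 0.005), ("**", 0.01), ("*", 0.05))


@dataclass(frozen=True)
class TestResult:
    t_stat: float
    df: float
    p_value: float
    label: str
    variant: str = "student"


def significance_label(p: float) -> str:
    """Star tier for a p-value; boundaries are inclusive."""
    if math.isnan(p) or not (0.0 <= p <= 1.0):
        raise ValidationError(f"p-value must lie in [0, 1], got {p}")
    for label, bound in STAR_TIERS:
        if p <= bound:
            return label
    return "ns"


def t_test_two_sample(a, b, variant: str = "student") -> TestResult:
    """Unpaired two-tailed t-test between two samples.

    ``student`` pools the variance with df = n_a + n_b - 2; ``welch``
    uses the Welch–Satterthwaite df.  Two samples with zero pooled
    variance raise :class:`DegenerateVarianceError` — the statistic is
    0/0 and no p-value exists.
    """
    if variant not in VARIANTS:
        raise ValidationError(f"variant must be one of {VARIANTS}")
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValidationError("both samples need at least two observations")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise DegenerateVarianceError(
            "zero variance in both samples; t statistic undefined"
        )
    res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    t = float(res.statistic)
    p = float(res.pvalue)
    df = float(res.df)
    if not math.isfinite(t):
        raise DegenerateVarianceError("t statistic is not finite")
    return TestResult(t_stat=t, df=df, p_value=p, label=significance_label(p), variant=variant)
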