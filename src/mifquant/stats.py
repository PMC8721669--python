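"""Statistical conventions used throughout the pipeline.

Two-sided Mann-Whitney U for distribution comparisons (exact permutation
null for small tie-free samples, tie-corrected normal approximation
otherwise), two-sided Fisher exact tests on 2×2 contingency tables
(probability-mass method), and Tukey-style boxplot summaries (linear-
interpolation hinges, whiskers at the most extreme point within 1.5·IQR of
the hinge). No multiple-comparison adjustment is applied anywhere; every
reported p-value is flagged unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InputError

#: Combined sample size at or below which the exact Mann-Whitney null is
#: enumerated (ties force the asymptotic method at any size).
EXACT_MW_MAX_N = 20


@dataclass
class GroupComparison:
    """One two-group Mann-Whitney comparison."""

    n1: int
    n2: int
    u: float
    p: float
    method: str  # exact | asymptotic


def mann_whitney_two_sided(x, y) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when n₁+n₂ ≤ 20 and the pooled sample has no ties;
    otherwise the tie-corrected normal approximation (no continuity
    correction — at moderate sample sizes this keeps the attained type-I
    rate closer to the nominal level). The U statistic reported is that of
    the first sample.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise InputError("Mann-Whitney groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # fully tied pooled sample carries no ordering evidence
        return GroupComparison(
            n1=len(x), n2=len(y), u=len(x) * len(y) / 2, p=1.0,
            method="asymptotic",
        )
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= EXACT_MW_MAX_N and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=False)
    return GroupComparison(
        n1=len(x), n2=len(y), u=float(res.statistic),
        p=float(min(res.pvalue, 1.0)), method=method,
    )


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2×2 table.

    Sums hypergeometric probabilities (margins fixed) of every table no more
    probable than the observed one — the probability-mass convention.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise InputError("Fisher test needs a 2x2 table")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if (t < 0).any() or not np.allclose(t, np.round(t)):
            raise InputError("table entries must be nonnegative integers")
        t = t.astype(int)
    if t.sum() == 0:
        raise InputError("all-zero contingency table")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def boxplot_summary(values) -> dict:
    """Median, hinges (25th/75th percentile, linear interpolation), whiskers
    at the most extreme data point within 1.5·IQR of the hinges, and the
    points beyond them."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise InputError("empty input")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_lo": float(inside.min()),
        "whisker_hi": float(inside.max()),
        "outliers": sorted(float(o) for o in v[(v < lo_fence) | (v > hi_fence)]),
    }
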