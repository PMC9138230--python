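"""Descriptive and effect-size statistics for group comparisons.

Cohen's d uses the n-weighted pooled standard deviation

    s_p = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)),
    d   = |m1 - m2| / s_p,

reported as a magnitude. Rank tests (Mann-Whitney U, Kruskal-Wallis,
Friedman, Cochran's Q) delegate to scipy/statsmodels; Bonferroni adjustment
is min(1, m*p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "describe",
    "values_from_order_stats",
    "cohens_d",
    "percent_change",
    "fold_change",
    "rank_tests",
    "bonferroni",
]


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: Optional[float]  # n-1 denominator; missing when n == 1
    median: float
    min: float
    max: float


def describe(values: Sequence[float]) -> GroupSummary:
    """Sample mean, SD (n-1), median and range of a non-empty sample."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    return GroupSummary(
        n=int(x.size),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if x.size > 1 else None,
        median=float(np.median(x)),
        min=float(x.min()),
        max=float(x.max()),
    )


def values_from_order_stats(n: int, median: float, min: float, max: float) -> list[float]:
    """Reconstruct a sample from its order statistics.

    Only n = 3 uniquely determines the sample: it is exactly
    {min, median, max}.
    """
    if n != 3:
        raise ValueError("not identifiable: only n = 3 is determined by (min, median, max)")
    if not (min <= median <= max):
        raise ValueError("order statistics must satisfy min <= median <= max")
    return [min, median, max]


def cohens_d(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Cohen's d (magnitude) with n-weighted pooled SD.

    Symmetric in group order; invariant under shifting both groups and under
    rescaling both groups by a common positive factor.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    sp = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    diff = abs(mean1 - mean2)
    if sp == 0:
        if diff == 0:
            return 0.0
        raise ValueError("degenerate: zero pooled SD with unequal means")
    return diff / sp


def percent_change(reference: float, value: float) -> float:
    """100 * (value - reference) / reference, sign preserved."""
    if reference == 0:
        raise ValueError("zero reference")
    return 100.0 * (value - reference) / reference


def fold_change(numerator: float, denominator: float) -> float:
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return numerator / denominator


def rank_tests(
    group1: Sequence[float],
    group2: Optional[Sequence[float]] = None,
    *,
    blocks: Optional[np.ndarray] = None,
    binary_blocks: Optional[np.ndarray] = None,
) -> dict[str, float]:
    """Two-sided p-values from the standard nonparametric tests.

    Exactly one comparison mode applies:

    * ``group1`` vs ``group2`` -> Mann-Whitney U (exact where possible) and
      Kruskal-Wallis;
    * ``blocks`` (subjects x conditions) -> Friedman;
    * ``binary_blocks`` (subjects x conditions, 0/1) -> Cochran's Q.

    These are support operations delegated to scipy / statsmodels.
    """
    out: dict[str, float] = {}
    if group2 is not None:
        g1 = np.asarray(group1, float)
        g2 = np.asarray(group2, float)
        if g1.size < 1 or g2.size < 1:
            raise ValueError("both groups must be non-empty")
        mwu = sps.mannwhitneyu(g1, g2, alternative="two-sided")
        out["mannwhitney_u"] = float(mwu.statistic)
        out["mannwhitney_p"] = float(mwu.pvalue)
        kw = sps.kruskal(g1, g2)
        out["kruskal_p"] = float(kw.pvalue)
    elif blocks is not None:
        b = np.asarray(blocks, float)
        if b.ndim != 2 or b.shape[1] < 3:
            raise ValueError("Friedman needs a subjects x (>=3) conditions block")
        fr = sps.friedmanchisquare(*b.T)
        out["friedman_p"] = float(fr.pvalue)
    elif binary_blocks is not None:
        from statsmodels.stats.contingency_tables import cochrans_q

        b = np.asarray(binary_blocks, float)
        if b.ndim != 2 or b.shape[1] < 2:
            raise ValueError("Cochran's Q needs a subjects x (>=2) conditions block")
        if np.all(b == b[:, [0]]):
            # identical conditions: no discordance, Q = 0 (statsmodels gives 0/0)
            out["cochran_q"] = 0.0
            out["cochran_q_p"] = 1.0
        else:
            res = cochrans_q(b, return_object=True)
            out["cochran_q"] = float(res.statistic)
            out["cochran_q_p"] = float(res.pvalue)
    else:
        raise ValueError("no comparison supplied")
    return out


def bonferroni(p_values: Sequence[float], m: int) -> list[float]:
    """min(1, m*p) per p-value; m is the number of tests in the family."""
    ps = list(p_values)
    if m < len(ps):
        raise ValueError("m must be at least the number of p-values")
    for p in ps:
        if not 0 <= p <= 1:
            raise ValueError(f"p-value {p} outside [0, 1]")
    return [min(1.0, m * p) for p in ps]
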