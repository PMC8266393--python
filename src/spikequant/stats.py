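"""Comparative statistics: Spearman correlation, Welch's t, hypergeometric
set overlap, and promoter-class composition tables.

Significance stars follow the conventional cutoffs:
p <= 0.0001 '****', <= 0.001 '***', <= 0.01 '**', <= 0.05 '*', else 'ns'.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    pass


STAR_CUTOFFS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def stars(p_value: float) -> str:
    """Map a p-value to significance stars ('ns' above 0.05)."""
    if np.isnan(p_value):
        return "ns"
    for cutoff, label in STAR_CUTOFFS:
        if p_value <= cutoff:
            return label
    return "ns"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    stars: str
    degrees_of_freedom: Optional[float] = None
    note: Optional[str] = None


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN (with no error) when either vector is constant, where the
    rank correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("spearman: inputs must be equal-length 1-D vectors")
    if x.size < 3:
        raise StatsError("spearman: need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r, _ = sps.spearmanr(x, y)
    return float(r)


def welch_t(x, y) -> TestResult:
    """Welch's unequal-variance two-sample t-test, two-sided.

    Degenerate zero-variance inputs with equal means report t=0, p=1 by
    convention rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise StatsError("welch_t: both samples need n >= 2")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x.mean() == y.mean():
            return TestResult(0.0, 1.0, "ns", degrees_of_freedom=float(x.size + y.size - 2),
                              note="zero variance, equal means")
        return TestResult(float("inf"), 0.0, "****",
                          degrees_of_freedom=float(x.size + y.size - 2),
                          note="zero variance, unequal means")
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        stars=stars(float(res.pvalue)),
        degrees_of_freedom=float(res.df),
    )


def hypergeom_overlap(set_a: Iterable, set_b: Iterable, universe: Iterable) -> TestResult:
    """One-sided over-representation test for the overlap of two gene sets.

    With X ~ Hypergeometric(|U|, |A|, |B|), reports P[X >= |A n B|]. Both
    sets must be subsets of the universe. The degenerate case where the
    overlap cannot be smaller than observed reports p = 1 with a note.
    """
    A, B, U = set(set_a), set(set_b), set(universe)
    if not A <= U or not B <= U:
        raise StatsError("hypergeom_overlap: sets must be subsets of the universe")
    k = len(A & B)
    # P[X >= k] via the survival function at k-1
    p = float(sps.hypergeom.sf(k - 1, len(U), len(A), len(B)))
    note = None
    min_overlap = max(0, len(A) + len(B) - len(U))
    if k == min_overlap:
        note = "degenerate: observed overlap is the minimum possible"
        p = 1.0
    return TestResult(statistic=float(k), p_value=p, stars=stars(p), note=note)


def class_composition(
    bound_sets: Mapping[str, Iterable],
    class_labels: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Percentage of promoters in each class bound by each factor.

    Rows are factors, columns classes; entry = 100 * |bound n class| / |class|.
    Empty classes are omitted.
    """
    labels = pd.Series(class_labels)
    classes = {
        cls: set(idx) for cls, idx in labels.groupby(labels).groups.items() if len(idx) > 0
    }
    rows = {}
    for factor, bound in bound_sets.items():
        bound = set(bound)
        rows[factor] = {
            cls: 100.0 * len(bound & members) / len(members)
            for cls, members in classes.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index")
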