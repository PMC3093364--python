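"""Statistical procedures used throughout the pipeline.

The per-cell intensity analysis uses single-pass 1.5*IQR outlier removal;
stage-positivity comparisons use the two-sided Fisher exact test (implemented
here by full hypergeometric enumeration, probability-mass definition); location
comparisons delegate to the standard scipy implementations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "iqr_filter",
    "fisher_exact_2x2",
    "t_test",
    "mann_whitney",
    "one_way_anova",
]

#: relative tolerance when comparing hypergeometric masses for the two-sided
#: Fisher p-value (tables whose mass ties the observed one, up to floating
#: error, are included in the tail)
FISHER_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of a 2x2 contingency table; rows are groups, columns outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("table counts must be nonnegative integers")

    @property
    def row_margins(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_margins(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def iqr_filter(values) -> tuple[np.ndarray, tuple[float, float]]:
    """Single-pass 1.5*IQR outlier removal.

    Quartiles use linear interpolation between order statistics (the "type 7"
    rule, numpy's default).  Values outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR] are
    dropped.  With fewer than 4 values the data pass through unchanged (with a
    warning) because quartiles are not meaningful.

    Returns
    -------
    retained : ndarray
        Values within the fences, in input order.
    bounds : (lo, hi)
        The fences actually applied.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < 4:
        warnings.warn(
            "fewer than 4 values: IQR filter is a passthrough", stacklevel=2
        )
        return x.copy(), (-np.inf, np.inf)
    q1, q3 = np.quantile(x, [0.25, 0.75])  # type-7 linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = (x >= lo) & (x <= hi)
    return x[keep], (float(lo), float(hi))


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact test p-value by full enumeration.

    Enumerates every table with the observed margins, computes each table's
    hypergeometric probability, and sums the probabilities of all tables whose
    mass does not exceed the observed table's mass (probability-mass
    definition of two-sidedness, with relative tolerance ``FISHER_REL_TOL`` on
    the comparison).  A zero margin makes the table degenerate; by convention
    p = 1 is returned with a warning.
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*np.ravel(table).tolist())
    r1, r2 = table.row_margins
    c1, _ = table.col_margins
    n = table.total
    if min(r1, r2, *table.col_margins) == 0:
        warnings.warn("zero margin: Fisher p set to 1 by convention", stacklevel=2)
        return 1.0
    # k = top-left count; feasible range given fixed margins
    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    ks = np.arange(k_min, k_max + 1)
    pmf = sps.hypergeom.pmf(ks, n, c1, r1)
    p_obs = sps.hypergeom.pmf(table.a, n, c1, r1)
    p = float(pmf[pmf <= p_obs * (1.0 + FISHER_REL_TOL)].sum())
    return min(p, 1.0)


def t_test(x, y, variant: str = "welch") -> tuple[float, float]:
    """Two-sample two-sided t-test; Welch (unequal variance) by default."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(x) == 0 and np.var(y) == 0:
        raise ValueError("degenerate (zero) variance in both groups")
    res = sps.ttest_ind(x, y, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with midrank ties.

    Exact enumeration for small samples (both n <= 20, no ties), normal
    approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 20 and y.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def one_way_anova(*groups) -> tuple[float, float]:
    """One-way ANOVA F-test across three or more groups."""
    if len(groups) < 3:
        raise ValueError("ANOVA here requires at least 3 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs at least 2 observations")
    if all(np.var(a) == 0 for a in arrs):
        raise ValueError("degenerate (zero) variance in every group")
    res = sps.f_oneway(*arrs)
    return float(res.statistic), float(res.pvalue)
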