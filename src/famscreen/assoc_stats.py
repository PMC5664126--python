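"""Count-table statistics: two-tailed Fisher exact test and Pearson chi-square.

The Fisher test uses the probability-mass (two-tailed) convention: with all
margins fixed, the p-value is the sum of hypergeometric point probabilities of
every admissible table whose probability does not exceed that of the observed
table.  Point masses are evaluated in log space (log-gamma based) so margins
in the thousands cannot overflow, and a relative tolerance of 1e-7 absorbs
floating-point ties between equally extreme tables.

The chi-square test is the plain Pearson statistic on an r x c table of
category counts with (r-1)(c-1) degrees of freedom and no continuity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import chi2, hypergeom

from .cohort_io import FamscreenError

__all__ = [
    "StatsError",
    "ContingencyTable2x2",
    "CategoryCountTable",
    "TestResult",
    "fisher_exact_two_tailed",
    "chi_square_pearson",
]


class StatsError(FamscreenError):
    pass


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 integer table: row 1 = (a, b), row 2 = (c, d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise StatsError(f"cells must be non-negative integers, got {cell!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass
class CategoryCountTable:
    """r x c table of category counts with row/column labels."""

    counts: np.ndarray
    row_labels: Optional[Sequence[str]] = None
    col_labels: Optional[Sequence[str]] = None

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise StatsError("category table must be at least 2x2")
        if np.any(arr < 0):
            raise StatsError("category counts must be non-negative")
        if np.any(arr.sum(axis=1) == 0) or np.any(arr.sum(axis=0) == 0):
            raise StatsError("category table must have no all-zero row or column")
        object.__setattr__(self, "counts", arr.astype(np.int64))


@dataclass(frozen=True)
class TestResult:
    """Outcome of a count-table test; statistic/df only for chi-square."""

    p_value: float
    statistic: Optional[float] = None
    df: Optional[int] = None

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise StatsError(f"p-value must lie in (0, 1], got {self.p_value}")


#: Relative slack when comparing point probabilities, absorbing float ties.
_TIE_RTOL = 1e-7


def fisher_exact_two_tailed(t: ContingencyTable2x2) -> TestResult:
    """Two-tailed Fisher exact test on a 2x2 table, probability-mass convention.

    All tables with the observed margins are enumerated through the
    hypergeometric support of the top-left cell; the p-value sums the point
    probabilities not exceeding the observed one (within a 1e-7 relative
    tolerance for ties).  Exact for any table size; log-space evaluation keeps
    margins in the thousands stable.
    """
    n = t.n
    if n < 1:
        raise StatsError("table total must be >= 1")
    r1 = t.a + t.b
    c1 = t.a + t.c
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logpmf = hypergeom.logpmf(support, n, r1, c1)
    log_obs = logpmf[t.a - lo]
    mask = logpmf <= log_obs + np.log1p(_TIE_RTOL)
    p = float(np.exp(logsumexp(logpmf[mask])))
    return TestResult(p_value=min(1.0, p))


def chi_square_pearson(t: CategoryCountTable) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    Expected counts come from the margin products over the grand total; the
    statistic is Sum (obs - exp)^2 / exp on (r-1)(c-1) degrees of freedom,
    without continuity correction.  Every expected count must be positive.
    """
    obs = t.counts.astype(float)
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    if np.any(expected <= 0):
        raise StatsError(
            "expected count of zero; merge sparse categories before testing"
        )
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(chi2.sf(stat, df))
    return TestResult(p_value=max(p, np.nextafter(0, 1)), statistic=stat, df=df)
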