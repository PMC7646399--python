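"""Association testing for 2x2 immunohistochemistry contingency tables.

The Pearson chi-square statistic without continuity correction,

    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)),   df = 1,

tests independence of two binary stainings (e.g. EGFR status vs AEBP1
status across tumors). Fisher's exact test is available as an optional
second output for small cells.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats


@dataclasses.dataclass(frozen=True)
class ContingencyTable2x2:
    """Four non-negative counts: rows are one marker (+/-), columns the other."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("counts must be non-negative integers")
        if self.n < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_totals(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_totals(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def chi_square_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Uncorrected Pearson chi-square (df = 1) and its p-value."""
    r1, r2 = table.row_totals
    c1, c2 = table.col_totals
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("degenerate table: a margin is zero")
    a, b, c, d = (float(v) for v in (table.a, table.b, table.c, table.d))
    statistic = table.n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p_value = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p_value


def fisher_exact_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher exact test (odds ratio, p) for small-cell tables."""
    odds, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    return float(odds), float(p)
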