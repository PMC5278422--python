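"""2x2 contingency-table tests for allele-bias and phenotype-frequency data.

Two tests cover the analyses this toolkit feeds: Pearson's chi-squared
test (edited/unedited x allele tables from deep-sequencing counts) and
Fisher's exact test (phenotype frequency tables with small counts or
zero margins).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows are outcome classes, columns groups."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be non-negative integers")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, col2) marginal totals."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    p_value: float
    df: int = 1


def chi_squared_2x2(table: ContingencyTable2x2, yates: bool = False) -> Chi2Result:
    """Pearson chi-squared test of independence on a 2x2 table (df=1).

    The statistic is sum((O-E)^2 / E) over the four cells; the p-value
    is the upper tail of the chi-squared distribution with one degree of
    freedom.  The Yates continuity correction is off by default.

    Raises ValueError on a zero row or column margin (expected counts of
    zero); use :func:`fisher_exact_2x2` there instead.
    """
    if table.total < 1:
        raise ValueError("table is empty")
    r1, r2, c1, c2 = table.margins()
    if 0 in (r1, r2, c1, c2):
        raise ValueError(
            "zero row/column margin: chi-squared undefined, use Fisher's exact test"
        )
    n = table.total
    observed = table.as_array().astype(float)
    expected = np.outer([r1, r2], [c1, c2]) / n
    dev = np.abs(observed - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    statistic = float(np.sum(dev**2 / expected))
    p = float(_sps.chi2.sf(statistic, df=1))
    return Chi2Result(statistic=statistic, p_value=p, df=1)


def fisher_exact_2x2(table: ContingencyTable2x2, sided: str = "two") -> float:
    """Fisher's exact test on a 2x2 table; returns the p-value.

    Conditioning on the margins, table probabilities are hypergeometric.
    The two-sided p-value sums the probabilities of all tables with the
    same margins whose probability does not exceed the observed table's
    (the "probability <= observed" convention).  The one-sided test is
    the upper tail for over-representation of the (row 1, column 1)
    cell.
    """
    if sided not in ("one", "two"):
        raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")
    if table.total < 1:
        raise ValueError("table is empty")
    alternative = "greater" if sided == "one" else "two-sided"
    result = _sps.fisher_exact(table.as_array(), alternative=alternative)
    return float(min(1.0, result.pvalue))
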