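"""Exact two-tailed Fisher test on 2x2 contingency tables.

Implemented from first principles with exact integer binomials and
rational arithmetic, so the p-value carries no floating-point error
before the final conversion. The two-sided convention is the small-p
one used by mainstream implementations: sum the hypergeometric
probabilities of every table with the observed margins whose point
probability does not exceed that of the observed table (a relative
tolerance of 1e-12 guards the comparison).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

__all__ = ["ContingencyTable2x2", "hypergeom_pmf", "fisher_exact_two_tailed"]

_REL_TOL = Fraction(1, 10**12)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; row 1 is the treated/evolved group."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if not isinstance(v, int) or v < 0:
                raise ValueError("table entries must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table must have at least one positive entry")

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, N)."""
        r1 = self.a + self.b
        r2 = self.c + self.d
        c1 = self.a + self.c
        return r1, r2, c1, r1 + r2


def hypergeom_pmf(x: int, r1: int, r2: int, c1: int) -> Fraction:
    """P(X = x) for X hypergeometric with margins (r1, r2, c1).

    Probability of a 2x2 table with top-left cell x given row sums
    (r1, r2) and first column sum c1: C(r1,x) C(r2,c1-x) / C(N,c1),
    computed with exact integers. Zero outside the support.
    """
    n = r1 + r2
    if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
        return Fraction(0)
    return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))


def fisher_exact_two_tailed(table: ContingencyTable2x2) -> float:
    """Two-tailed Fisher exact p-value, small-p convention.

    Degenerate tables (an all-zero row or column) carry no information
    and return p = 1.
    """
    r1, r2, c1, n = table.margins
    c2 = n - c1
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        return 1.0
    p_obs = hypergeom_pmf(table.a, r1, r2, c1)
    cutoff = p_obs * (1 + _REL_TOL)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p = Fraction(0)
    for x in range(lo, hi + 1):
        px = hypergeom_pmf(x, r1, r2, c1)
        if px <= cutoff:
            p += px
    return float(min(p, Fraction(1)))
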