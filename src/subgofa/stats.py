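"""Exact 2x2 association testing and FDR control.

The Fisher test here is the two-sided exact test on a 2x2 contingency
table: with both margins fixed, the cell count follows a hypergeometric
distribution, and the p-value sums the probabilities of every table whose
point probability does not exceed the observed one. The implementation is
exact integer arithmetic — hypergeometric numerators over a common binomial
denominator — so tied tables are resolved without floating-point fuzz.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb
from typing import NamedTuple, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests


class FisherResult(NamedTuple):
    p_value: float
    zero_margin: bool


def fisher_exact_2x2(table) -> FisherResult:
    """Two-sided Fisher exact p-value for a 2x2 table of counts.

    A zero row or column margin makes the test vacuous; those tables return
    p = 1 with ``zero_margin=True`` rather than failing.
    """
    (a, b), (c, d) = table
    cells = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in cells):
        raise ValueError(f"counts must be non-negative integers, got {cells}")
    a, b, c, d = (int(x) for x in cells)
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        return FisherResult(1.0, True)

    # P(k) = C(r1,k) C(r2,c1-k) / C(n,c1); compare numerators exactly
    lo, hi = max(0, c1 - r2), min(r1, c1)
    numerators = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    observed = comb(r1, a) * comb(r2, c)
    total = sum(num for num in numerators if num <= observed)
    p = float(Fraction(total, comb(n, c1)))
    return FisherResult(min(p, 1.0), False)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
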