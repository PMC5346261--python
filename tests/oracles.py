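"""Independent brute-force oracles used only by the tests.

These deliberately use exact rational arithmetic and naive enumeration;
they share no code with the implementation they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration with exact fractions.

    Sums hypergeometric point probabilities at most (1 + 1e-7) times the
    observed table's probability, margins fixed.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = comb(n, c1)
    probs = {
        x: Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        for x in range(max(0, c1 - r2), min(c1, r1) + 1)
    }
    cutoff = probs[a] * Fraction(10_000_001, 10_000_000)
    total = sum(p for p in probs.values() if p <= cutoff)
    return float(total)


def binom_two_sided_oracle(k: int, n: int) -> float:
    """Two-sided exact binomial p at p0 = 1/2 by enumeration."""
    probs = [Fraction(comb(n, i), 2 ** n) for i in range(n + 1)]
    cutoff = probs[k] * Fraction(10_000_001, 10_000_000)
    return float(sum(p for p in probs if p <= cutoff))


def git_table_oracle(m_high: int, u_high: int, m_low: int, u_low: int) -> float:
    """Selection-corrected one-sided p on one table by exact enumeration."""
    n_high, n_low = m_high + u_high, m_low + u_low
    n_meth = m_high + m_low
    n = n_high + n_low
    if n_high == 0 or n_low == 0 or n_meth == 0 or n_meth == n:
        return 1.0
    denom = comb(n, n_meth)
    p_e = Fraction(0)
    num = Fraction(0)
    for x in range(max(0, n_meth - n_low), min(n_meth, n_high) + 1):
        p = Fraction(comb(n_high, x) * comb(n_low, n_meth - x), denom)
        if Fraction(x, n_high) > Fraction(n_meth - x, n_low):
            p_e += p
            if x >= m_high:
                num += p
    if p_e == 0:
        return 1.0
    return float(min(Fraction(1), num / p_e))


def ols_oracle(x: np.ndarray, y: np.ndarray):
    """Closed-form simple linear regression via the textbook formulas."""
    from scipy.stats import t as t_dist

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - intercept - slope * x
    se = np.sqrt((resid @ resid) / (n - 2) / (sxx - sx * sx / n))
    p = 2 * t_dist.sf(abs(slope / se), n - 2)
    return slope, se, p


def ld_r2_counting_oracle(h1, h2) -> float:
    """r^2 from explicit 2x2 haplotype counting."""
    h1 = np.asarray(h1).ravel()
    h2 = np.asarray(h2).ravel()
    n = len(h1)
    n11 = int(((h1 == 1) & (h2 == 1)).sum())
    p1, p2 = h1.sum() / n, h2.sum() / n
    d = n11 / n - p1 * p2
    return d * d / (p1 * (1 - p1) * p2 * (1 - p2))


def pearson_oracle(x, y) -> float:
    """Textbook Pearson correlation coefficient."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    num = n * (x * y).sum() - x.sum() * y.sum()
    den = np.sqrt(n * (x * x).sum() - x.sum() ** 2) \
        * np.sqrt(n * (y * y).sum() - y.sum() ** 2)
    return num / den


def bh_oracle(p):
    """Step-up BH via the statsmodels reference implementation."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]
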