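"""Hand-coded statistical oracles, independent of scipy and of the package.

These are deliberately naive, textbook implementations used to cross-check
the production code paths:

- ``fisher_two_sided``: exhaustive hypergeometric enumeration in exact
  rational arithmetic (two-sided p = sum of probabilities of all tables
  with the observed margins that are at most as probable as the observed
  table).
- ``yates_chi2_p``: the classic 2x2 continuity-corrected chi-squared
  closed form ``N * (max(0, |ad - bc| - N/2))^2 / (r1 r2 c1 c2)`` with the
  1-df survival function written via ``math.erfc``.
- ``needs_fisher_bruteforce``: literal low-count rule (any observed or
  expected cell below five).
- ``kl_bits``: Kullback-Leibler divergence in bits.
- ``overlap_bruteforce``: all-pairs interval-overlap flags.
"""
from __future__ import annotations

import math
from fractions import Fraction


def _comb(n: int, k: int) -> int:
    return math.comb(n, k) if 0 <= k <= n else 0


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p by exhaustive enumeration.

    The support of the upper-left cell x given fixed margins is
    ``max(0, n - (c + d)) <= x <= min(n, a + c)`` with ``n = a + b``; each
    table's probability is hypergeometric.  Computed with exact Fractions
    so that ties are exact.
    """
    n1, n2 = a + b, c + d  # row sums
    m1 = a + c             # first-column sum
    total = n1 + n2
    denom = _comb(total, m1)
    if denom == 0:  # empty table
        return 1.0
    lo, hi = max(0, m1 - n2), min(n1, m1)
    p_obs = Fraction(_comb(n1, a) * _comb(n2, m1 - a), denom)
    acc = Fraction(0)
    for x in range(lo, hi + 1):
        p_x = Fraction(_comb(n1, x) * _comb(n2, m1 - x), denom)
        if p_x <= p_obs:
            acc += p_x
    return min(1.0, float(acc))


def yates_chi2_p(a: int, b: int, c: int, d: int) -> float:
    """Yates continuity-corrected chi-squared p-value (1 df) for a 2x2 table."""
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if 0 in (r1, r2, c1, c2):
        raise ValueError("zero margin")
    num = max(0.0, abs(a * d - b * c) - n / 2.0)
    chi2 = n * num * num / (r1 * r2 * c1 * c2)
    # P(Chi2_1 > x) = erfc(sqrt(x / 2))
    return math.erfc(math.sqrt(chi2 / 2.0))


def needs_fisher_bruteforce(a: int, b: int, c: int, d: int) -> bool:
    """Low-count routing rule, checked cell by cell."""
    n = a + b + c + d
    obs = [a, b, c, d]
    exp = [
        (a + b) * (a + c) / n, (a + b) * (b + d) / n,
        (c + d) * (a + c) / n, (c + d) * (b + d) / n,
    ]
    return any(x < 5 for x in obs) or any(x < 5 for x in exp)


def kl_bits(p, q) -> float:
    """KL(p || q) in bits for two discrete distributions."""
    return float(sum(pi * math.log2(pi / qi) for pi, qi in zip(p, q) if pi > 0))


def overlap_bruteforce(set_a, set_b) -> float:
    """Overlap coefficient by all-pairs comparison.

    ``set_a``/``set_b`` are lists of ``(chrom, start, end, strand)``; the
    smaller set's peaks are counted (first argument on a tie).
    """
    small, large = (set_a, set_b) if len(set_a) <= len(set_b) else (set_b, set_a)
    n_hit = 0
    for (ca, sa, ea, ta) in small:
        for (cb, sb, eb, tb) in large:
            if ca == cb and ta == tb and sa < eb and sb < ea:
                n_hit += 1
                break
    return n_hit / len(small)


def dedup_bruteforce(reads) -> int:
    """Exact-mode molecule count: distinct (rbp, chrom, strand, truncation, umi)."""
    return len({(r.rbp, r.chrom, r.strand, r.truncation, r.umi) for r in reads})
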