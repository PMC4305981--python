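"""Independent exact-arithmetic oracles used to freeze expected values.

These deliberately avoid the package's log-space code path: everything is
big-integer / Fraction arithmetic or brute-force enumeration.
"""

from fractions import Fraction
from itertools import combinations
from math import comb


def hyper_tail_exact(n1: int, n2: int, m: int, total: int) -> Fraction:
    """P(X >= m) for X ~ Hypergeometric(total, n1, n2), exact."""
    denom = comb(total, n2)
    num = 0
    for i in range(m, min(n1, n2) + 1):
        if 0 <= n2 - i <= total - n1:
            num += comb(n1, i) * comb(total - n1, n2 - i)
    return Fraction(num, denom)


def overlap_tail_by_enumeration(n1: int, n2: int, m: int, total: int) -> Fraction:
    """Same tail by enumerating every placement of the second target set."""
    first = set(range(n1))
    hits = 0
    count = 0
    for second in combinations(range(total), n2):
        count += 1
        if len(first & set(second)) >= m:
            hits += 1
    return Fraction(hits, count)


def fisher_tail_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """One-sided tail P(cell_a >= a) over all tables with the same margins."""
    n = a + b + c + d
    if n == 0:
        return Fraction(1)
    r1, c1 = a + b, a + c
    denom = comb(n, c1)
    num = 0
    for i in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        if i >= a:
            num += comb(r1, i) * comb(n - r1, c1 - i)
    return Fraction(num, denom)


def fisher_tables_with_margins(a: int, b: int, c: int, d: int):
    """All (a', b', c', d') sharing the margins of the given table."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    for i in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        yield i, r1 - i, c1 - i, n - r1 - (c1 - i)
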