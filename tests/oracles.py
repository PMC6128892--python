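"""Independent brute-force oracles shared by the test modules.

Deliberately naive implementations — explicit loops and exact rational
arithmetic — kept separate from the library code paths they check.
"""

import math
from fractions import Fraction
from math import comb


def naive_ranks(values):
    """Average ranks computed by literal counting."""
    out = []
    for vi in values:
        less = sum(1 for u in values if u < vi)
        equal = sum(1 for u in values if u == vi)
        out.append(1 + less + (equal - 1) / 2)
    return out


def naive_spearman_rho(x, y):
    """Textbook Pearson correlation of average ranks."""
    rx, ry = naive_ranks(list(x)), naive_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def exact_hypergeom_upper_tails(N, K, n):
    """Exact rational P(X >= k) for every k in 0..min(K, n), as floats."""
    m = min(K, n)
    pmf = [Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n)) for i in range(m + 1)]
    tails = [Fraction(0)] * (m + 1)
    acc = Fraction(0)
    for k in range(m, -1, -1):
        acc += pmf[k]
        tails[k] = acc
    return [float(t) for t in tails]


def exact_hypergeom_upper(N, K, n, k):
    return exact_hypergeom_upper_tails(N, K, n)[k]
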