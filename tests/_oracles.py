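"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library paths they are checking: plain loops,
exact integer arithmetic, textbook formulas.
"""

from fractions import Fraction
from math import comb, dist

import numpy as np

#: same fixed order the classifier documents
ORACLE_CATEGORIES = (
    "balanced",
    "A_dominant",
    "B_dominant",
    "D_dominant",
    "A_suppressed",
    "B_suppressed",
    "D_suppressed",
)
ORACLE_PROFILES = (
    (1 / 3, 1 / 3, 1 / 3),
    (1.0, 0.0, 0.0),
    (0.0, 1.0, 0.0),
    (0.0, 0.0, 1.0),
    (0.0, 0.5, 0.5),
    (0.5, 0.0, 0.5),
    (0.5, 0.5, 0.0),
)


def bh_step_up_brute(pvalues):
    """Textbook BH: sort ascending, p(i) * m / i, enforce monotonicity from
    the top rank down, cap at 1, return in input order."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        adjusted[idx] = min(running_min, 1.0)
    return adjusted


def binom_two_sided_exact(k, n, tie_tol_num=0):
    """Exact two-sided binomial p at p0 = 1/2 by full enumeration.

    Sums P(X = i) over every i whose probability does not exceed P(X = k);
    exact integer comparison of binomial coefficients, so no floating-point
    tie ambiguity."""
    ck = comb(n, k)
    num = sum(comb(n, i) for i in range(n + 1) if comb(n, i) <= ck + tie_tol_num)
    return float(Fraction(num, 2**n))


def hypergeom_upper_brute(N, K, n, k):
    """Exact upper tail P(X >= k) of hypergeometric(N, K, n) as a ratio of
    integer sums of binomial coefficients."""
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return float(Fraction(num, comb(N, n)))


def nearest_profile_brute(rel):
    """Exhaustive minimum-distance category lookup, first winner on ties."""
    best, best_d = None, float("inf")
    for name, prof in zip(ORACLE_CATEGORIES, ORACLE_PROFILES):
        d = dist(rel, prof)
        if d < best_d:
            best, best_d = name, d
    return best
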