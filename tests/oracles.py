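"""Independent brute-force oracles used to cross-check the package.

These implementations deliberately avoid the vectorized code paths in
the package: exact rational arithmetic for the hypergeometric tail, an
explicit quadratic-time step-up loop for BH, and a full running-sum walk
for the KS enrichment statistic.
"""

from fractions import Fraction
from math import comb


def hypergeom_tail_exact(x: int, K: int, M: int, n: int) -> Fraction:
    """P(X >= x) by direct enumeration of the tail, exact rationals."""
    upper = min(K, n)
    total = sum(comb(K, k) * comb(M - K, n - k) for k in range(x, upper + 1))
    return Fraction(total, comb(M, n))


def bh_brute(p_values) -> list[float]:
    """Benjamini-Hochberg step-up by the definition, O(m^2)."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    for position, index in enumerate(order):
        best = min(m * p[order[t]] / (t + 1) for t in range(position, m))
        adjusted[index] = min(1.0, best)
    return adjusted


def ks_brute(member_ranks, n_total: int) -> float:
    """KS enrichment by walking the full ranked list.

    a = max over positions i of (fraction of members at rank <= i) - i/N;
    b = max over positions i of i/N - (fraction of members at rank < i).
    """
    members = set(member_ranks)
    n = len(members)
    a = float("-inf")
    b = float("-inf")
    hits = 0
    for i in range(1, n_total + 1):
        before = hits / n
        if i in members:
            hits += 1
        a = max(a, hits / n - i / n_total)
        b = max(b, i / n_total - before)
    return a if a > b else -b
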