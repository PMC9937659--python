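"""Independent brute-force oracles used only by the test suite.

Each oracle is a direct enumeration or closed form, deliberately sharing no
code with the package implementation it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction


def fisher_enumeration(a: int, b: int, c: int, d: int,
                       sidedness: str = "two-sided") -> float:
    """Fisher exact p by full enumeration of the hypergeometric support,
    with exact rational point probabilities (so ties are decided exactly)."""
    r1, r2 = a + b, c + d
    col1 = a + c
    n = r1 + r2
    lo, hi = max(0, col1 - r2), min(r1, col1)
    denom = math.comb(n, col1)
    probs = {x: Fraction(math.comb(r1, x) * math.comb(r2, col1 - x), denom)
             for x in range(lo, hi + 1)}
    if sidedness == "greater":
        return float(sum(p for x, p in probs.items() if x >= a))
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def prevalence_ratio(a: int, b: int, c: int, d: int) -> float:
    """(a/(a+b)) / (c/(c+d)) with the same sentinel conventions."""
    if c == 0:
        return math.nan if a == 0 else math.inf
    return (a / (a + b)) / (c / (c + d))


def hypergeom_upper_tail(x: int, N: int, K: int, n: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, K, n), by summation."""
    denom = math.comb(N, n)
    total = Fraction(0)
    for k in range(x, min(K, n) + 1):
        if n - k <= N - K:
            total += Fraction(math.comb(K, k) * math.comb(N - K, n - k), denom)
    return float(min(total, Fraction(1)))


def bh_stepup(p_values) -> list[float]:
    """Benjamini-Hochberg step-up by its textbook definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        adjusted[i] = running
    return adjusted
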