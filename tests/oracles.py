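"""Independent brute-force oracles used only by the tests."""

from fractions import Fraction
from math import comb


def exact_fisher_two_sided(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by exhaustive enumeration with exact rational
    arithmetic: sum the probabilities of every table sharing the observed
    margins whose probability is <= that of the observed table."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = comb(n, c1)

    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(n - r1, c1 - x), denom)

    p_obs = prob(a)
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs)


def stepup_bh(pvals):
    """Benjamini–Hochberg step-up, written independently (direct formula)."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvals[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def stepup_by(pvals):
    m = len(pvals)
    c_m = sum(1.0 / i for i in range(1, m + 1))
    return [min(1.0, v) for v in stepup_bh([min(p * c_m, 1.0) for p in pvals])]
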