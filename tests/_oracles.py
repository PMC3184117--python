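"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately written the slow, obvious way (exhaustive
enumeration, exact rational arithmetic) and shares no code with the package
paths it validates.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb


def sliding_alignment_oracle(a: str, b: str):
    """Best ungapped local alignment by exhaustive offset/window search.

    Scoring: +1 match, -1 mismatch.  Ties broken by fewest mismatches then
    largest window, matching the implementation's documented tie-break.
    Returns (score, mismatches, total_overhang, window_length); the empty
    alignment gives (0, 0, 2*max(len a, len b), 0).
    """
    n, m = len(a), len(b)
    best = (0, 0, 0)  # (score, -mismatches, window length)
    best_loc = None
    for s in range(-(m - 1), n):  # b[j] pairs with a[j + s]
        jlo = max(0, -s)
        jhi = min(m, n - s)
        if jlo >= jhi:
            continue
        mis_flags = [a[j + s] != b[j] or a[j + s] == "N" for j in range(jlo, jhi)]
        cum = [0]
        for f in mis_flags:
            cum.append(cum[-1] + f)
        for u in range(jlo, jhi):
            for v in range(u, jhi):
                mis = cum[v + 1 - jlo] - cum[u - jlo]
                L = v - u + 1
                cand = (L - 2 * mis, -mis, L)
                if cand > best:
                    best = cand
                    best_loc = (s, u, v)
    if best_loc is None:
        return 0, 0, 2 * max(n, m), 0
    s, u, v = best_loc
    score, neg_mis, L = best
    start_a, start_b = u + s, u
    end_a, end_b = v + s + 1, v + 1
    overhang = (start_a + start_b) + (n - end_a) + (m - end_b)
    return score, -neg_mis, overhang, L


def fisher_twosided_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact two-sided Fisher p by rational hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    total = comb(n, c1)

    def pmf(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), total)

    p_obs = pmf(a)
    p = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if pmf(x) <= p_obs:
            p += pmf(x)
    return p


def mann_whitney_twosided_oracle(x, y) -> Fraction:
    """Exact two-sided Mann-Whitney p by full enumeration (no ties allowed)."""
    n, m = len(x), len(y)
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == n + m, "oracle requires distinct values"
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for idx in itertools.combinations(range(n + m), n):
        chosen = set(idx)
        u = sum(
            1
            for i in chosen
            for j in range(n + m)
            if j not in chosen and pooled[i] > pooled[j]
        )
        us.append(u)
    total = len(us)
    p_low = Fraction(sum(1 for u in us if u <= u_obs), total)
    p_high = Fraction(sum(1 for u in us if u >= u_obs), total)
    return min(2 * min(p_low, p_high), Fraction(1))


def binomial_upper_tail_oracle(k: int, n: int, p: Fraction) -> Fraction:
    """Exact P(X >= k) for X ~ Binomial(n, p), rational arithmetic."""
    return sum(
        Fraction(comb(n, i)) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
    )


def hypergeom_detection_oracle(d1: int, d2: int, n_total: int) -> Fraction:
    """Two-sided Fisher p for a detection-count comparison, via the
    rational enumeration oracle."""
    return fisher_twosided_oracle(d1, n_total - d1, d2, n_total - d2)
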