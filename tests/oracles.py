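"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive (exact rational arithmetic,
exhaustive enumeration, transitive closure) and shares no code with
the implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def hypergeom_cdf_exact(N: int, m: int, n: int, x: int) -> Fraction:
    """P(X <= x) by exact rational summation of the hypergeometric PMF."""
    denom = comb(N, n)
    return sum(
        Fraction(comb(m, i) * comb(N - m, n - i), denom) for i in range(x + 1)
    )


def upper_tail_exact(N: int, K: int, n: int, k: int) -> Fraction:
    """One-sided (greater) Fisher p-value P(X >= k) by enumerating every
    2x2 table with the fixed margins, weighted by the hypergeometric PMF."""
    denom = comb(N, n)
    return sum(
        Fraction(comb(K, i) * comb(N - K, n - i), denom)
        for i in range(k, min(K, n) + 1)
    )


def pearson_exact(xs, ys) -> Fraction:
    """PCC numerator/denominator**2 as exact rationals; returns the squared
    correlation with its sign, avoiding irrational square roots."""
    n = len(xs)
    xs = [Fraction(v) for v in xs]
    ys = [Fraction(v) for v in ys]
    mx = sum(xs) / n
    my = sum(ys) / n
    num = sum((a - mx) * (b - my) for a, b in zip(xs, ys))
    den = sum((a - mx) ** 2 for a in xs) * sum((b - my) ** 2 for b in ys)
    sign = 1 if num >= 0 else -1
    return sign * (num * num / den) if den else None


def connected_components_bruteforce(nodes, edges):
    """Components via repeated transitive closure over the edge list."""
    parent = {v: {v} for v in nodes}
    groups = [set([v]) for v in nodes]
    for a, b in edges:
        ga = next(g for g in groups if a in g)
        gb = next(g for g in groups if b in g)
        if ga is not gb:
            ga |= gb
            groups.remove(gb)
    return [frozenset(g) for g in groups]


def complete_linkage_bruteforce(points):
    """Exhaustive agglomeration under complete linkage on Euclidean
    distance. Returns the merge heights in order and the sequence of
    merged member-index frozensets."""
    import math

    def dist(p, q):
        return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))

    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(len(points))]
    heights = []
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(
                    dist(points[a], points[b])
                    for a in clusters[i]
                    for b in clusters[j]
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merged = clusters[i] | clusters[j]
        heights.append(d)
        merges.append(merged)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return heights, merges
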