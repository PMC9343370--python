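"""Independent brute-force oracles used by the test suite.

Everything here is written for transparency, not speed: exact rational
arithmetic, exhaustive enumeration and quadratic scans, independent of the
library code paths they check.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


# --- Fisher: exact rational hypergeometric enumeration ----------------------


def fisher_pvalues_by_margins(r1: int, r2: int, c1: int) -> dict[int, Fraction]:
    """Two-sided p (probability-mass definition) for every feasible top-left
    cell a given margins, as exact rationals."""
    n = r1 + r2
    ks = range(max(0, c1 - r2), min(r1, c1) + 1)
    denom = comb(n, c1)
    probs = {k: Fraction(comb(r1, k) * comb(r2, c1 - k), denom) for k in ks}
    return {a: sum(p for p in probs.values() if p <= probs[a]) for a in ks}


def fisher_p_rational(a: int, b: int, c: int, d: int) -> Fraction:
    return fisher_pvalues_by_margins(a + b, c + d, a + c)[a]


# --- d-score rules in exact rational arithmetic ------------------------------


def dscore_rational(xi: int, xa: int, min_reads: int = 10):
    """(analyzable, d as Fraction or None)."""
    if xi + xa < min_reads:
        return False, None
    return True, Fraction(xi, xi + xa) - Fraction(1, 2)


def escape_rational(xi: int, xa: int, ratio=Fraction(1, 20)) -> bool:
    # xi/xa >= ratio with xa = 0 treated as unbounded ratio (escape iff xi > 0;
    # xi = xa = 0 cannot be analyzable under any positive min_reads)
    if xa == 0:
        return xi > 0
    return Fraction(xi, xa) >= ratio


def dependent_rational(xi1, xa1, xi2, xa2, delta=Fraction(3, 100)) -> bool:
    d1 = Fraction(xi1, xi1 + xa1) - Fraction(1, 2)
    d2 = Fraction(xi2, xi2 + xa2) - Fraction(1, 2)
    return d2 - d1 >= delta


# --- two-sample KS permutation enumeration -----------------------------------


def _ks_D_scaled(x, y) -> int:
    """sup|F_x - F_y| * n * m as an integer."""
    n, m = len(x), len(y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    best = 0
    for t in np.unique(np.concatenate([x, y])):
        best = max(best, abs(int((x <= t).sum()) * m - int((y <= t).sum()) * n))
    return best


def ks_permutation_p(x, y) -> Fraction:
    """P(D >= D_obs) over all C(n+m, n) label assignments of the pooled
    sample, with D compared on the integer scale (no float ties)."""
    n, m = len(x), len(y)
    pooled = list(x) + list(y)
    d_obs = _ks_D_scaled(x, y)
    hits = tot = 0
    idx = set(range(n + m))
    for chosen in combinations(range(n + m), n):
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in idx - set(chosen)]
        tot += 1
        if _ks_D_scaled(xs, ys) >= d_obs:
            hits += 1
    return Fraction(hits, tot)


# --- quadratic interval oracles ----------------------------------------------


def overlap_naive(a, b) -> bool:
    """a, b: (chrom, start, end) half-open; >= 1 shared bp."""
    return a[0] == b[0] and min(a[2], b[2]) - max(a[1], b[1]) >= 1


def merge_naive(intervals, max_gap: int):
    """Transitive closure union-find over the gap <= max_gap relation."""
    items = list(intervals)
    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            ci, si, ei = items[i]
            cj, sj, ej = items[j]
            if ci == cj and max(si, sj) - min(ei, ej) <= max_gap:
                parent[find(i)] = find(j)
    groups: dict[int, list] = {}
    for i in range(len(items)):
        groups.setdefault(find(i), []).append(items[i])
    out = []
    for members in groups.values():
        chrom = members[0][0]
        out.append((chrom, min(s for _, s, _ in members), max(e for _, _, e in members)))
    return sorted(out)


def consensus_naive(peak_sets, min_fraction: Fraction):
    """Pooled intervals supported by >= min_fraction of sets, unioned."""
    n = len(peak_sets)
    pooled = [iv for s in peak_sets for iv in s]
    kept = []
    for iv in pooled:
        support = sum(1 for s in peak_sets if any(overlap_naive(iv, o) for o in s))
        if Fraction(support, n) >= min_fraction:
            kept.append(iv)
    return merge_naive(kept, max_gap=-1) if kept else []


def partition_naive(peaks, tss_list, window: int):
    """'proximal'/'distal' per peak; tss_list is [(chrom, tss_bp)]."""
    out = []
    for chrom, s, e in peaks:
        prox = any(
            overlap_naive((chrom, s, e), (c, max(t - window, 0), t + window))
            for c, t in tss_list
        )
        out.append("proximal" if prox else "distal")
    return out


def enhancer_naive(peaks, h3k27ac, tss_list, window: int, enhancer_max: int):
    """promoter/enhancer/other per peak, promoter tested first."""
    out = []
    for p in peaks:
        chrom, s, e = p
        prom = any(
            overlap_naive(p, (c, max(t - window, 0), t + window)) for c, t in tss_list
        )
        if prom:
            out.append("promoter")
            continue
        near = any(
            overlap_naive(p, (c, max(t - enhancer_max, 0), t + enhancer_max))
            for c, t in tss_list
        )
        has_ac = any(overlap_naive(p, a) for a in h3k27ac)
        out.append("enhancer" if (near and has_ac) else "other")
    return out
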