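"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration, exact
integer arithmetic, O(n*m) membership checks — and shares no code with
the package internals it is used to verify.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def exact_binomial_tails(n: int, p: float) -> np.ndarray:
    """All upper tails P(X >= k), k = 0..n, X ~ Binomial(n, p), exact.

    Writes p as the exact binary rational a / c (c a power of two), forms
    the pmf numerators C(n, j) * a^j * (c - a)^(n - j) as big integers,
    suffix-sums them, and divides by c^n with Python's correctly rounded
    integer true division. No floating-point intermediate anywhere.
    """
    a, c = p.as_integer_ratio()
    b = c - a
    bpow = [1] * (n + 1)
    for j in range(1, n + 1):
        bpow[j] = bpow[j - 1] * b
    numer = [0] * (n + 1)
    coef = 1
    apow = 1
    for j in range(n + 1):
        numer[j] = coef * apow * bpow[n - j]
        coef = coef * (n - j) // (j + 1)
        apow *= a
    den = c**n
    tails = np.empty(n + 1)
    suffix = 0
    for k in range(n, -1, -1):
        suffix += numer[k]
        tails[k] = suffix / den
    return tails


def brute_dedupe(records) -> dict[str, object]:
    """Group-by-minimum reference for probeset deduplication.

    Returns {gene_id: best ProbesetStat} scanning every probeset of every
    gene and keeping the (min p, max |t|, min probeset_id) winner.
    """
    by_gene: dict[str, list] = {}
    for rec in records:
        if rec.gene_id:
            by_gene.setdefault(rec.gene_id, []).append(rec)
    out = {}
    for gene, recs in by_gene.items():
        best = recs[0]
        for r in recs[1:]:
            if (r.p_value, -abs(r.t_stat), r.probeset_id) < (
                best.p_value,
                -abs(best.t_stat),
                best.probeset_id,
            ):
                best = r
        out[gene] = best
    return out


def brute_window_members(
    rep_points: np.ndarray, center: int, radius: int
) -> np.ndarray:
    """Boolean membership mask: center - radius <= x < center + radius."""
    return (rep_points >= center - radius) & (rep_points < center + radius)


def brute_perm_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided permutation p for the mean-difference statistic."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    obs = abs(x.mean() - y.mean())
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), nx):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(idx)] = True
        stat = pooled[sel].mean() - pooled[~sel].mean()
        count += abs(stat) >= obs
        total += 1
    assert total == math.comb(len(pooled), nx)
    return count / total


def brute_merge_intervals(
    intervals: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Union of half-open intervals on one chromosome (sort and sweep)."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]
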