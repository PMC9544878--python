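"""Independent reference implementations used only to check the package.

Everything here is deliberately written from first principles (textbook
formulas, exact rational arithmetic, brute-force scans) and never calls
into :mod:`msea`.
"""

from __future__ import annotations

import math
from fractions import Fraction


def bh_step_up(pvals):
    """Benjamini-Hochberg adjusted p-values, textbook step-up form:
    p~_(i) = min_{j >= i} ( m/j * p_(j) ), clipped at 1."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvals[i] * m / rank)
        adjusted[i] = min(1.0, running_min)
    return adjusted


def holm_step_down(pvals):
    """Bonferroni-Holm adjusted p-values, textbook step-down form:
    p~_(i) = max_{j <= i} ( (m-j+1) * p_(j) ), clipped at 1."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_max = 0.0
    for rank, i in enumerate(order, start=1):
        running_max = max(running_max, pvals[i] * (m - rank + 1))
        adjusted[i] = min(1.0, running_max)
    return adjusted


def fisher_tail_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact-rational one-sided Fisher p: hypergeometric upper tail
    P(X >= a) with the table's margins."""
    n_tot = a + b + c + d
    K = a + c
    n = a + b
    hi = min(K, n)
    denom = math.comb(n_tot, n)
    total = Fraction(0)
    for k in range(a, hi + 1):
        total += Fraction(math.comb(K, k) * math.comb(n_tot - K, n - k), denom)
    return total


def hypergeom_tails_exact(n_tot: int, K: int, n: int) -> dict[int, Fraction]:
    """P(X >= a) for every feasible a, via exact suffix sums."""
    lo, hi = max(0, K + n - n_tot), min(K, n)
    denom = math.comb(n_tot, n)
    pmf = [Fraction(math.comb(K, k) * math.comb(n_tot - K, n - k), denom) for k in range(lo, hi + 1)]
    tails: dict[int, Fraction] = {}
    acc = Fraction(0)
    for k in range(hi, lo - 1, -1):
        acc += pmf[k - lo]
        tails[k] = acc
    return tails


def components_bruteforce(sets: dict[str, frozenset], mode: str) -> set[frozenset]:
    """Connected components of the 100%-overlap link graph via pairwise
    scan + union-find."""
    ids = sorted(sets)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for i in ids:
        for j in ids:
            if i >= j:
                continue
            si, sj = sets[i], sets[j]
            linked = si == sj if mode == "exact" else (si <= sj or sj <= si)
            if linked:
                union(i, j)
    groups: dict[str, set[str]] = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def auc_from_u(labels, scores) -> float:
    """ROC AUC via the Mann-Whitney identity AUC = U / (n1*n0), with the
    half-credit tie convention, computed by a direct pairwise scan."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    u = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                u += 1.0
            elif p == q:
                u += 0.5
    return u / (len(pos) * len(neg))
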