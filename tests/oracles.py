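"""Independent reference implementations used only to check the package.

Each oracle deliberately avoids the code path it validates: r² by
explicit 2x2 haplotype counting, the Fisher one-sided p by direct
hypergeometric tail summation, BH q-values via statsmodels, LD blocks
via a hand-rolled union-find, and tag covers by exhaustive subset
search.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def r2_by_counting(x, y) -> float:
    """r² from the 2x2 haplotype count table, one haplotype at a time."""
    n11 = n10 = n01 = n00 = 0
    for a, b in zip(x, y):
        if a == 1 and b == 1:
            n11 += 1
        elif a == 1:
            n10 += 1
        elif b == 1:
            n01 += 1
        else:
            n00 += 1
    n = n11 + n10 + n01 + n00
    pa = (n11 + n10) / n
    pb = (n11 + n01) / n
    d = n11 / n - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))


def dprime_by_counting(x, y) -> float:
    n = len(x)
    pa = sum(x) / n
    pb = sum(y) / n
    pab = sum(1 for a, b in zip(x, y) if a == 1 and b == 1) / n
    d = pab - pa * pb
    if d > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    elif d < 0:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    else:
        return 0.0
    return abs(d) / dmax


def fisher_greater_by_summation(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher exact p by summing the hypergeometric
    tail directly with exact integer arithmetic."""
    a, b, c, d = int(a), int(b), int(c), int(d)
    row1 = a + b
    col1 = a + c
    n = a + b + c + d
    lo = a
    hi = min(row1, col1)
    total = 0
    for k in range(lo, hi + 1):
        total += math.comb(col1, k) * math.comb(n - col1, row1 - k)
    return total / math.comb(n, row1)


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values via statsmodels."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y):
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


def blocks_by_union_find(ids, edge_fn) -> dict:
    """Connected components via union-find; labels ordered to match the
    package convention (leftmost member by (chrom, pos))."""
    uf = UnionFind(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if edge_fn(a, b):
                uf.union(a, b)
    comps: dict = {}
    for s in ids:
        comps.setdefault(uf.find(s), set()).add(s)
    return comps


def minimum_tag_cover(snps, covers) -> int:
    """Smallest number of tags covering all candidates, by exhaustive
    subset search. ``covers[s]`` is the set covered by s (incl. itself)."""
    snps = list(snps)
    for size in range(1, len(snps) + 1):
        for subset in itertools.combinations(snps, size):
            covered = set()
            for s in subset:
                covered |= covers[s]
            if covered >= set(snps):
                return size
    raise AssertionError("full set always covers")
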