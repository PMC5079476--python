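"""Independent brute-force oracles the test suite checks the package against.

Everything here is deliberately naive (quadratic loops, per-base boolean
arrays, recursive cluster-distance recomputation) and shares no code with
the implementation.
"""

from __future__ import annotations

import numpy as np


def pearson_two_pass(x, y):
    """Textbook two-pass product-moment correlation (explicit loops)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sxx = syy = 0.0
    for xi, yi in zip(x, y):
        sxy += (xi - mx) * (yi - my)
        sxx += (xi - mx) ** 2
        syy += (yi - my) ** 2
    if sxx == 0.0 or syy == 0.0:
        return None
    return sxy / (sxx * syy) ** 0.5


def merge_intervals_quadratic(intervals):
    """Union-merge of (chrom, start, end) tuples by repeated pairwise passes.

    Two intervals merge when they overlap or are bookended. O(n^2) per pass,
    repeated until a fixed point.
    """
    regions = [tuple(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        out: list[tuple] = []
        for iv in regions:
            merged = False
            for k, other in enumerate(out):
                if iv[0] == other[0] and iv[1] <= other[2] and other[1] <= iv[2]:
                    out[k] = (iv[0], min(iv[1], other[1]), max(iv[2], other[2]))
                    merged = True
                    changed = True
                    break
            if not merged:
                out.append(iv)
        regions = out
    return sorted(regions)


def coverage_per_base(intervals, chrom_len):
    """Per-chromosome boolean coverage arrays of a set of intervals."""
    cov = {}
    for chrom, start, end in intervals:
        arr = cov.setdefault(chrom, np.zeros(chrom_len, dtype=bool))
        arr[start:end] = True
    return cov


def binarize_all_pairs(sample_intervals, universe_intervals):
    """O(n*m) overlap oracle: entry r = 1 iff any sample interval overlaps
    universe region r by >= 1 bp under half-open semantics."""
    vec = np.zeros(len(universe_intervals))
    for r, (uc, us, ue) in enumerate(universe_intervals):
        for sc, ss, se in sample_intervals:
            if sc == uc and max(ss, us) < min(se, ue):
                vec[r] = 1.0
                break
    return vec


def naive_agglomerative_leaf_order(corr, method):
    """O(n^3) agglomerative clustering on d = 1 - r, recomputing inter-cluster
    distances from the original matrix at every step.

    Ties merge the pair whose clusters hold the lowest original indices; the
    cluster containing the lower original index goes left. Returns the
    left-to-right leaf order.
    """
    d0 = 1.0 - np.asarray(corr, dtype=float)
    n = d0.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    # for ward, track recursively updated distances keyed by member frozensets
    dist: dict[frozenset, float] = {
        frozenset((i, j)): d0[i, j] for i in range(n) for j in range(i + 1, n)
    }

    def cluster_distance(a: list[int], b: list[int]) -> float:
        if method == "single":
            return min(d0[i, j] for i in a for j in b)
        if method == "complete":
            return max(d0[i, j] for i in a for j in b)
        if method == "average":
            return sum(d0[i, j] for i in a for j in b) / (len(a) * len(b))
        return dist[frozenset((min(a), min(b)))]  # ward: recursion below

    while len(clusters) > 1:
        best = None
        for ai in range(len(clusters)):
            for bi in range(ai + 1, len(clusters)):
                a, b = clusters[ai], clusters[bi]
                key = (cluster_distance(a, b), min(min(a), min(b)), max(min(a), min(b)))
                if best is None or key < best[0]:
                    best = (key, ai, bi)
        (h, _, _), ai, bi = best
        a, b = clusters[ai], clusters[bi]
        left, right = (a, b) if min(a) < min(b) else (b, a)
        merged = left + right
        if method == "ward":
            na, nb = len(a), len(b)
            for c in clusters:
                if c is a or c is b:
                    continue
                nc = len(c)
                dac = dist[frozenset((min(a), min(c)))]
                dbc = dist[frozenset((min(b), min(c)))]
                dist[frozenset((min(merged), min(c)))] = (
                    ((na + nc) * dac**2 + (nb + nc) * dbc**2 - nc * h**2) / (na + nb + nc)
                ) ** 0.5
        clusters = [c for c in clusters if c is not a and c is not b]
        clusters.append(merged)
    return clusters[0]
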