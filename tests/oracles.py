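"""Independent brute-force oracles used by unit and acceptance tests.

Each function re-derives a quantity by the most transparent possible
route (naive scans, direct summation, exhaustive agglomeration) and is
kept free of any code path it is used to check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def naive_ccgg_positions(seq: str) -> list[int]:
    """O(L*4) sliding-window motif scan; 1-based positions."""
    seq = seq.upper()
    return [i + 1 for i in range(len(seq) - 3) if seq[i:i + 4] == "CCGG"]


def stepup_bh(p: list[float]) -> list[float]:
    """Benjamini-Hochberg by direct evaluation of the step-up formula:
    q_i = min over all j with p_(j) >= p_i of m * p_(j) / j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for i in range(m):
        cands = [m * p[order[j]] / (j + 1)
                 for j in range(m) if p[order[j]] >= p[i]]
        q[i] = min(1.0, min(cands))
    return q


def hypergeom_upper_tail(k: int, n_on: int, n_sig: int, n_total: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N=n_total, K=n_sig, n=n_on), by exact
    integer-arithmetic summation of the pmf."""
    denom = math.comb(n_total, n_on)
    total = 0
    hi = min(n_on, n_sig)
    for x in range(k, hi + 1):
        total += math.comb(n_sig, x) * math.comb(n_total - n_sig, n_on - x)
    return total / denom


def quadratic_containment(sites: list[tuple[str, int]],
                          intervals: list[tuple[str, int, int, str]]) -> dict:
    """site -> sorted feature names, by scanning every (site, interval)
    pair; intervals 0-based half-open, sites 1-based positions."""
    out = {}
    for chrom, pos in sites:
        hits = [name for (ic, s, e, name) in intervals
                if ic == chrom and s <= pos - 1 < e]
        out[(chrom, pos)] = sorted(hits)
    return out


def quadratic_bin_means(rows: list[tuple[str, int, float]],
                        width: int) -> dict[tuple[str, int], float]:
    """(chrom, bin) -> mean logfc, by explicit accumulation."""
    acc: dict[tuple[str, int], list[float]] = {}
    for chrom, pos, lfc in rows:
        acc.setdefault((chrom, (pos - 1) // width), []).append(lfc)
    return {k: sum(v) / len(v) for k, v in acc.items()}


def complete_linkage_merges(points: np.ndarray) -> list[float]:
    """Merge heights of exhaustive complete-linkage agglomeration on the
    rows of ``points`` (Euclidean), smallest cluster pair first."""
    clusters = [[i] for i in range(len(points))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            d = max(np.linalg.norm(points[i] - points[j])
                    for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return heights
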