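"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive (quadratic scans, exhaustive
enumeration, explicit formulas) and shares no code with the package, so
each oracle pins the semantics of the operation it mirrors.
"""

from __future__ import annotations

import math
from itertools import permutations


def greedy_center_clusters(centers: list[int], window: int) -> list[list[int]]:
    """Left-to-right maximal center groups with span <= window (indices)."""
    order = sorted(range(len(centers)), key=lambda i: centers[i])
    clusters: list[list[int]] = []
    current: list[int] = []
    for i in order:
        if current and centers[i] - centers[current[0]] > window:
            clusters.append(current)
            current = []
        current.append(i)
    if current:
        clusters.append(current)
    return clusters


def transitive_stitch(intervals: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    """O(n^2) transitive merge: intervals closer than gap end up together."""
    merged = [list(iv) for iv in sorted(intervals)]
    changed = True
    while changed:
        changed = False
        out: list[list[int]] = []
        for iv in merged:
            placed = False
            for o in out:
                if iv[0] - o[1] <= gap and o[0] - iv[1] <= gap:
                    o[0], o[1] = min(o[0], iv[0]), max(o[1], iv[1])
                    placed = True
                    changed = True
                    break
            if not placed:
                out.append(iv)
        merged = out
    return sorted((a, b) for a, b in merged)


def feature_of_center(center: int, transcripts, promoter_halfwidth: int = 2000) -> str:
    """Hierarchy promoter > intron > exon > intergenic for a point.

    ``transcripts`` is a list of (tss, tx_start, tx_end, exons) tuples on
    the point's chromosome.
    """
    classes = set()
    for tss, tx_start, tx_end, exons in transcripts:
        if abs(center - tss) <= promoter_halfwidth:
            classes.add("promoter")
        if tx_start <= center < tx_end:
            if any(s <= center < e for s, e in exons):
                classes.add("exon")
            else:
                classes.add("intron")
    for c in ("promoter", "intron", "exon"):
        if c in classes:
            return c
    return "intergenic"


def rank_curve_cutoff(scores: list[float]) -> float:
    """Evaluate every candidate rank point; maximize the gap below y=x."""
    s = sorted(scores)
    n = len(s)
    lo, hi = s[0], s[-1]
    if hi == lo:
        return hi
    best_i, best_gap = None, None
    for i in range(n):
        y = (s[i] - lo) / (hi - lo)
        x = i / (n - 1)
        gap = y - x
        if best_gap is None or gap <= best_gap:  # <=: prefer the later point
            best_i, best_gap = i, gap
    return s[best_i]


def motif_counts_exhaustive(edges: set[tuple[str, str]], tfs: set[str]):
    """(autoregulation, feedforward, interconnected) by full enumeration."""
    auto = sum(1 for t in tfs if (t, t) in edges)
    nodes = {n for e in edges for n in e} | tfs
    inter = 0
    tf_list = sorted(tfs)
    for i, a in enumerate(tf_list):
        for b in tf_list[i + 1 :]:
            if (a, b) in edges and (b, a) in edges:
                inter += 1
    ffl = 0
    for a, b in permutations(tf_list, 2):
        for c in nodes:
            if c in (a, b):
                continue
            if (a, b) in edges and (a, c) in edges and (b, c) in edges:
                ffl += 1
    return auto, ffl, inter


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by explicit binomial-coefficient summation."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total


def pearson_binary(set_a: set, set_b: set, universe: list) -> float | None:
    """Pearson correlation of membership indicator vectors (None if undefined)."""
    xs = [1.0 if g in set_a else 0.0 for g in universe]
    ys = [1.0 if g in set_b else 0.0 for g in universe]
    n = len(universe)
    mx, my = sum(xs) / n, sum(ys) / n
    vx = sum((x - mx) ** 2 for x in xs)
    vy = sum((y - my) ** 2 for y in ys)
    if vx == 0 or vy == 0:
        return None
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    return cov / math.sqrt(vx * vy)
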