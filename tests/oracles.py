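"""Independent brute-force reference implementations used only by tests.

Each oracle re-derives its quantity from first principles, sharing no code
path with the package implementation it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp_naive(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def spearman_brute(x, y) -> float:
    """Average-rank Spearman via the Pearson formula, from scratch."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r
    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx)
                    * sum((b - my) ** 2 for b in ry))
    return num / den if den else float("nan")


def fisher_brute(table) -> float:
    """Two-sided Fisher p by exact hypergeometric enumeration in integer
    arithmetic (sum of outcomes no more likely than the observed one)."""
    (a, b), (c, d) = [list(map(int, row)) for row in table]
    r1, r2, c1 = a + b, c + d, a + c

    def weight(k):
        if k < max(0, c1 - r2) or k > min(r1, c1):
            return 0
        return math.comb(r1, k) * math.comb(r2, c1 - k)

    w_obs = weight(a)
    total = sum(weight(k) for k in range(min(r1, c1) + 1))
    acc = sum(w for k in range(min(r1, c1) + 1)
              if (w := weight(k)) <= w_obs)
    return acc / total


def rank_sum_brute(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating every assignment of the
    pooled observations to the first group."""
    pooled = list(x) + list(y)
    n = len(x)

    def ranks(values):
        sorted_vals = sorted(values)
        return [(sorted_vals.index(v) + 1 +
                 (sorted_vals.index(v) + sorted_vals.count(v))) / 2.0
                for v in values]

    r = ranks(pooled)
    w_obs = sum(r[:n])
    ws = [sum(r[i] for i in idx)
          for idx in combinations(range(len(pooled)), n)]
    lo = sum(1 for w in ws if w <= w_obs + 1e-9) / len(ws)
    hi = sum(1 for w in ws if w >= w_obs - 1e-9) / len(ws)
    return min(1.0, 2.0 * min(lo, hi))


def spacer_scan_brute(spacer: str, target: str, min_len: int,
                      max_mismatch: int, min_coverage: float) -> int | None:
    """Sliding-window Hamming scan over both strands and every spacer
    substring longer than ``min_coverage`` of the spacer; returns the
    minimum mismatch count or None.  Early exit keeps it tractable."""
    L = len(spacer)
    if L < min_len:
        return None
    best = None
    limit = max_mismatch
    for probe0 in (spacer, revcomp_naive(spacer)):
        for w in range(L, 0, -1):
            if w / L <= min_coverage:
                break
            for off in range(0, L - w + 1):
                probe = probe0[off:off + w]
                for pos in range(0, len(target) - w + 1):
                    mism = 0
                    for i in range(w):
                        if probe[i] != target[pos + i]:
                            mism += 1
                            if mism > limit:
                                break
                    else:
                        if best is None or mism < best:
                            best = mism
    return best


def coverage_brute(intervals, length: int) -> float:
    """Breadth of coverage by position marking."""
    covered = [False] * length
    for s, e in intervals:
        for i in range(max(s, 0), min(e, length)):
            covered[i] = True
    return sum(covered) / length


def transitive_closure_clusters(similar_pairs, element_ids):
    """Clusters as the transitive closure of a similarity relation,
    computed by repeated sweeps over a membership map."""
    cluster_of = {e: e for e in element_ids}
    changed = True
    while changed:
        changed = False
        for a, b in similar_pairs:
            ra, rb = cluster_of[a], cluster_of[b]
            if ra != rb:
                target = min(ra, rb)
                for e, r in cluster_of.items():
                    if r in (ra, rb):
                        cluster_of[e] = target
                changed = True
    groups = {}
    for e, r in cluster_of.items():
        groups.setdefault(r, set()).add(e)
    return {frozenset(g) for g in groups.values()}
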