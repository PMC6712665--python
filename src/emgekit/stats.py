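"""Statistical primitives used by host prediction and quantification.

Spearman and Fisher tests are delegated to scipy; q-values come from
statsmodels (Benjamini-Hochberg) or a Storey-style estimate.  The rank-sum
test enumerates the exact permutation null for small samples (handling ties
by average ranks, as R's ``wilcox.test`` does in spirit) and falls back to
the tie-corrected normal approximation with continuity correction.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho = sps.spearmanr(x, y).statistic
    return float(rho)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p (minimum-likelihood definition)."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def qvalues(pvals, method: str = "bh") -> np.ndarray:
    """FDR q-values: Benjamini-Hochberg (default) or a Storey-style
    variant with pi0 estimated at lambda = 0.5."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    q = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return q
    if method == "storey":
        pi0 = min(1.0, float(np.mean(p > 0.5)) / 0.5) if p.size else 1.0
        if pi0 <= 0:
            pi0 = 1.0 / p.size
        return np.minimum(q * pi0, 1.0)
    raise ValueError(f"unknown q-value method {method!r}")


def _average_ranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _exact_rank_sum_p(ranks: np.ndarray, n_x: int, w_obs: float) -> float:
    """Exact two-sided p for the rank-sum W of the first group: enumerate
    the distribution of sums of ``n_x`` ranks by dynamic programming over
    the rank multiset (ranks doubled to stay integral with .5 ties)."""
    r2 = np.round(ranks * 2).astype(int)
    total = int(r2.sum())
    # dp[k][s] = number of k-subsets with doubled-rank sum s
    dp = np.zeros((n_x + 1, total + 1), dtype=float)
    dp[0][0] = 1.0
    for r in r2:
        for k in range(min(n_x, 1_000_000), 0, -1):
            dp[k][r:] += dp[k - 1][: total + 1 - r]
    dist = dp[n_x]
    n_total = dist.sum()
    w2 = int(round(w_obs * 2))
    lo = dist[: w2 + 1].sum() / n_total
    hi = dist[w2:].sum() / n_total
    return float(min(1.0, 2.0 * min(lo, hi)))


def rank_sum_test(x, y, exact_limit: int = 200_000) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact permutation null when C(n+m, n) <= ``exact_limit``; otherwise
    normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _average_ranks(pooled)
    w = float(ranks[: len(x)].sum())
    if math.comb(len(pooled), len(x)) <= exact_limit:
        return _exact_rank_sum_p(ranks, len(x), w)
    n, m = len(x), len(y)
    mu = n * (n + m + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / ((n + m) * (n + m - 1.0))
    sigma2 = n * m / 12.0 * ((n + m + 1) - tie_term)
    if sigma2 <= 0:
        return 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(sigma2)
    return float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))


def pearson(x, y) -> float:
    """Pearson correlation; NaN for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
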