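"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: enumeration instead
of convolution, explicit loops instead of vectorized formulas.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def signed_rank_enumeration(diffs, alternative: str = "greater") -> float:
    """Exact signed-rank p by full enumeration of all 2^n sign patterns."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product((0, 1), repeat=d.size):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    p_greater = float((ws >= w_obs - 1e-9).mean())
    if alternative == "greater":
        return p_greater
    p_less = float((ws <= w_obs + 1e-9).mean())
    return min(1.0, 2.0 * min(p_greater, p_less))


def bh_step_up(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the literal step-up formula."""
    p = np.asarray(p, dtype=float)
    m = p.size
    q = np.empty(m)
    for i in range(m):
        candidates = [m * pj / (np.sum(p <= pj)) for pj in p if pj >= p[i]]
        q[i] = min(1.0, min(candidates))
    return q


def average_linkage(dist: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Naive agglomerative average-linkage: list of (left, right, height)."""
    n = dist.shape[0]
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            h = np.mean([dist[i, j] for i in a for j in b])
            if best is None or h < best[2]:
                best = (a, b, h)
        a, b, h = best
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
        merges.append((a, b, h))
    return merges


def dl_formulas(y, se):
    """DerSimonian-Laird by direct transcription of the textbook formulas."""
    y = np.asarray(y, dtype=float)
    se = np.asarray(se, dtype=float)
    w = 1.0 / se ** 2
    ybar = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - ybar) ** 2))
    k = y.size
    tau2 = max(0.0, (q - (k - 1)) / (np.sum(w) - np.sum(w ** 2) / np.sum(w)))
    wr = 1.0 / (se ** 2 + tau2)
    mu = float(np.sum(wr * y) / np.sum(wr))
    se_mu = float(np.sum(wr) ** -0.5)
    return mu, se_mu, tau2, q


def shared_null_expectation(n_genes: int, n_strains: int, alpha: float, k: int) -> float:
    """Analytic binomial-direction expectation of concordant counts at exactly k.

    Independent response indicators per strain (probability alpha) with
    symmetric directions: the k responding strains agree in sign with
    probability (1/2)^(k-1).
    """
    from math import comb
    return (n_genes * comb(n_strains, k) * alpha ** k
            * (1 - alpha) ** (n_strains - k) * 0.5 ** (k - 1))
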