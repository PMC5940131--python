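"""Cross-strain shared CR responses, permutation null, signature scores and
quadrant-proportion tests.

A gene "responds similarly" in a set of strains when its raw per-strain
p-value falls below alpha *and* the log2 fold-changes of all responding
strains share one sign.  Observed counts of genes responding in exactly k
strains are compared against a permutation null in which each strain's
per-gene (p, direction) pairs are shuffled independently across the gene
universe — i.e. CR responses are randomly associated among strains while
each strain's marginal response distribution is preserved exactly.
"""

from __future__ import annotations

import logging
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SharedResponseTable",
    "shared_counts",
    "shared_null",
    "signature_score",
    "quadrant_proportion_test",
]

log = logging.getLogger(__name__)


@dataclass
class SharedResponseTable:
    """Observed (and optionally null) counts of concordant multi-strain responses.

    ``table`` is indexed by k = 1..n_strains with columns ``observed`` (genes
    responding concordantly in exactly k strains) and ``observed_at_least``;
    after :func:`shared_null` it gains ``null_mean``, ``null_sd`` and
    ``p_perm`` (empirical upper-tail p).  ``discordant`` counts genes whose
    responding strains disagree in direction.
    """

    alpha: float
    n_strains: int
    n_genes: int
    table: pd.DataFrame
    discordant: int
    n_permutations: int | None = None
    seed: int | None = None


def _aligned_arrays(fit_tables: dict[str, pd.DataFrame]) -> tuple[pd.Index, np.ndarray, np.ndarray]:
    strains = list(fit_tables)
    universe = fit_tables[strains[0]].index
    for s in strains[1:]:
        universe = universe.intersection(fit_tables[s].index)
    if not len(universe):
        raise ValueError("gene universes of the fit tables are disjoint")
    P = np.column_stack([fit_tables[s].loc[universe, "p"].to_numpy() for s in strains])
    D = np.column_stack([np.sign(fit_tables[s].loc[universe, "log2fc"].to_numpy())
                         for s in strains])
    return universe, P, D


def _count_exact(P: np.ndarray, D: np.ndarray, alpha: float) -> tuple[np.ndarray, int]:
    """Counts of concordant genes per exact k, plus the discordant count."""
    resp = (P < alpha) & (D != 0)
    up = (resp & (D > 0)).sum(axis=1)
    down = (resp & (D < 0)).sum(axis=1)
    k = up + down
    concordant = (up == 0) | (down == 0)
    S = P.shape[1]
    counts = np.bincount(k[concordant & (k > 0)], minlength=S + 1)[1:]
    discordant = int((~concordant).sum())
    return counts, discordant


def shared_counts(fit_tables: dict[str, pd.DataFrame],
                  alpha: float = 0.05) -> SharedResponseTable:
    """Observed counts of genes responding concordantly in exactly k strains."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    universe, P, D = _aligned_arrays(fit_tables)
    counts, discordant = _count_exact(P, D, alpha)
    S = P.shape[1]
    table = pd.DataFrame({
        "observed": counts,
        "observed_at_least": counts[::-1].cumsum()[::-1],
    }, index=pd.RangeIndex(1, S + 1, name="k"))
    return SharedResponseTable(alpha, S, len(universe), table, discordant)


def shared_null(fit_tables: dict[str, pd.DataFrame], alpha: float = 0.05,
                B: int = 1000, seed: int = 0) -> SharedResponseTable:
    """Permutation null for the shared-response counts.

    Each of ``B`` permutations shuffles every strain's (p, direction) pairs
    jointly across genes (independent permutations per strain, preserving
    within-strain dependence between significance and direction), then
    recounts concordant genes.  The empirical p for each k is
    (1 + #{permutations with count >= observed}) / (B + 1), computed on the
    "at least k" cumulative counts.
    """
    if B < 100:
        raise ValueError("at least 100 permutations are required")
    observed = shared_counts(fit_tables, alpha)
    universe, P, D = _aligned_arrays(fit_tables)
    S = P.shape[1]
    N = len(universe)
    rng = np.random.default_rng(seed)

    null_exact = np.empty((B, S), dtype=np.int64)
    for b in range(B):
        Pb = np.empty_like(P)
        Db = np.empty_like(D)
        for j in range(S):
            perm = rng.permutation(N)
            Pb[:, j] = P[perm, j]
            Db[:, j] = D[perm, j]
        null_exact[b], _ = _count_exact(Pb, Db, alpha)

    null_at_least = null_exact[:, ::-1].cumsum(axis=1)[:, ::-1]
    obs_at_least = observed.table["observed_at_least"].to_numpy()
    obs_exact = observed.table["observed"].to_numpy()
    p_perm = (1 + (null_at_least >= obs_at_least).sum(axis=0)) / (B + 1)
    p_perm_exact = (1 + (null_exact >= obs_exact).sum(axis=0)) / (B + 1)

    table = observed.table.copy()
    table["null_mean"] = null_exact.mean(axis=0)
    table["null_sd"] = null_exact.std(axis=0, ddof=1)
    table["null_mean_at_least"] = null_at_least.mean(axis=0)
    table["p_perm"] = p_perm
    table["p_perm_exact"] = p_perm_exact
    return SharedResponseTable(alpha, S, N, table, observed.discordant, B, seed)


SignatureScore = namedtuple("SignatureScore",
                            ["up_score", "down_score", "n_up", "n_down"])


def signature_score(fit_table: pd.DataFrame, up_genes, down_genes) -> SignatureScore:
    """Average linear FC over the members of an up- and a down-regulated set.

    Only list members present in the fit table contribute; the matched
    counts are reported alongside the scores.
    """
    up = fit_table.index.intersection(pd.Index(up_genes))
    down = fit_table.index.intersection(pd.Index(down_genes))
    if not len(up) or not len(down):
        raise ValueError("signature gene lists do not overlap the fit table")
    return SignatureScore(float(fit_table.loc[up, "fc"].mean()),
                          float(fit_table.loc[down, "fc"].mean()),
                          len(up), len(down))


QUADRANTS = ("up_up", "up_down", "down_up", "down_down")


def quadrant_proportion_test(fc_pairs, expected: float = 0.25,
                             alpha: float = 0.05) -> pd.DataFrame:
    """Quadrant occupancy of paired linear fold-changes versus a 25% expectation.

    Pairs with either FC equal to 1 (zero log2FC) are excluded; quadrants are
    defined by the signs of the two log2 fold-changes (first axis first, e.g.
    ``up_down`` = up on axis a, down on axis b).  Each quadrant gets a
    one-cell goodness-of-fit chi-square (df = 1, no continuity correction)
    against the expected proportion; only quadrants *exceeding* the
    expectation at p < alpha are flagged.
    """
    arr = np.asarray(fc_pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("fc_pairs must be an (n, 2) array of linear fold-changes")
    if (arr <= 0).any():
        raise ValueError("linear fold-changes must be positive")
    la, lb = np.log2(arr[:, 0]), np.log2(arr[:, 1])
    usable = (la != 0) & (lb != 0)
    n = int(usable.sum())
    if n < 20:
        raise ValueError(f"need at least 20 usable pairs, got {n}")
    la, lb = la[usable], lb[usable]

    counts = {
        "up_up": int(((la > 0) & (lb > 0)).sum()),
        "up_down": int(((la > 0) & (lb < 0)).sum()),
        "down_up": int(((la < 0) & (lb > 0)).sum()),
        "down_down": int(((la < 0) & (lb < 0)).sum()),
    }
    rows = []
    for quad in QUADRANTS:
        o = counts[quad]
        e = expected * n
        chi2 = (o - e) ** 2 / e + ((n - o) - (n - e)) ** 2 / (n - e)
        p = float(stats.chi2.sf(chi2, 1))
        prop = o / n
        rows.append({"quadrant": quad, "count": o, "proportion": prop,
                     "chi2": chi2, "p": p,
                     "flagged": bool(prop > expected and p < alpha)})
    return pd.DataFrame(rows).set_index("quadrant")
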