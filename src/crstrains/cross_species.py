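"""Ortholog-mapped mouse-human concordance of CR responses.

Mouse per-strain fold-change tables are aligned to human per-experiment
fold-changes through an explicit one-to-one ortholog symbol map; concordance
is summarized as a strains x experiments grid of Spearman rank correlations,
a cumulative-overlap enrichment of each strain's top genes inside the
human meta-ranking, and directional median-FC tests of mouse-defined gene
sets in the human data.

The enrichment statistic is a Kolmogorov-style running-overlap deviation:
with O(i) the overlap of the gene set with the top-i genes of the ranking
and E(i) = m*i/H its uniform expectation, D+ = max(O - E), D- = max(E - O),
and the statistic is (D+ - D-)/m, signed toward the larger deviation, with
a permutation p-value over random same-size sets.  This running-overlap
definition is this package's own; outputs label it accordingly.
"""

from __future__ import annotations

import logging
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import signed_rank_pvalue

__all__ = [
    "ConcordanceGrid",
    "map_orthologs",
    "species_correlations",
    "top_n_genes",
    "cumulative_overlap_gsea",
    "median_fc_test",
]

log = logging.getLogger(__name__)


@dataclass
class ConcordanceGrid:
    """Strains x experiments rank-correlation grid with per-strain summaries."""

    rho: pd.DataFrame               # strains x experiments Spearman
    strain_summary: pd.DataFrame    # per strain: median, q25, q75
    meta_rho: pd.Series | None = None   # correlation against the meta-signature
    enrichment: pd.DataFrame | None = None


def _validate_map(ortholog_map: pd.DataFrame) -> pd.DataFrame:
    required = {"mouse_symbol", "human_symbol"}
    if not required.issubset(ortholog_map.columns):
        raise ValueError(f"ortholog map needs columns {sorted(required)}")
    for col in required:
        if ortholog_map[col].duplicated().any():
            dups = ortholog_map.loc[ortholog_map[col].duplicated(), col].tolist()
            raise ValueError(f"ortholog map has duplicated {col} entries: {dups[:5]}")
    return ortholog_map


def map_orthologs(mouse_fit: pd.DataFrame, human_table,
                  ortholog_map: pd.DataFrame) -> pd.DataFrame:
    """Inner-join mouse and human log2 fold-changes through the ortholog map.

    ``human_table`` may be a Series of log2 fold-changes indexed by human
    symbol or a DataFrame with a ``log2fc`` (or ``meta_log2fc``) column.
    Unmapped genes are dropped with counts logged.
    """
    _validate_map(ortholog_map)
    if isinstance(human_table, pd.Series):
        human_fc = human_table
    else:
        col = "log2fc" if "log2fc" in human_table.columns else "meta_log2fc"
        human_fc = human_table[col]
    mapped = ortholog_map.set_index("mouse_symbol")["human_symbol"]
    common_mouse = mouse_fit.index.intersection(mapped.index)
    human_names = mapped.loc[common_mouse]
    present = human_names.isin(human_fc.index)
    joined = pd.DataFrame({
        "human_symbol": human_names[present],
        "mouse_log2fc": mouse_fit.loc[common_mouse[present], "log2fc"],
        "human_log2fc": human_fc.loc[human_names[present]].to_numpy(),
    })
    log.info("ortholog join: %d of %d mouse genes matched", len(joined),
             len(mouse_fit))
    if joined.empty:
        log.warning("ortholog join is empty")
    return joined


def species_correlations(mouse_fits: dict[str, pd.DataFrame],
                         human_fcs: dict[str, pd.Series],
                         ortholog_map: pd.DataFrame,
                         meta_fc: pd.Series | None = None) -> ConcordanceGrid:
    """Spearman rank correlation per (strain, experiment) on complete pairs.

    Cells with fewer than three joined genes are left missing and logged.
    When ``meta_fc`` (the meta-signature average response) is supplied, a
    per-strain correlation against it is reported as well.
    """
    strains = list(mouse_fits)
    experiments = list(human_fcs)
    rho = pd.DataFrame(np.nan, index=strains, columns=experiments)
    for s in strains:
        for e in experiments:
            joined = map_orthologs(mouse_fits[s], human_fcs[e], ortholog_map)
            if len(joined) < 3:
                log.warning("cell (%s, %s) undefined (<3 joined genes)", s, e)
                continue
            rho.loc[s, e] = stats.spearmanr(joined["mouse_log2fc"],
                                            joined["human_log2fc"]).statistic
    summary = pd.DataFrame({
        "median": rho.median(axis=1),
        "q25": rho.quantile(0.25, axis=1),
        "q75": rho.quantile(0.75, axis=1),
        "mean": rho.mean(axis=1),
    })
    meta_rho = None
    if meta_fc is not None:
        vals = {}
        for s in strains:
            joined = map_orthologs(mouse_fits[s], meta_fc, ortholog_map)
            vals[s] = (stats.spearmanr(joined["mouse_log2fc"],
                                       joined["human_log2fc"]).statistic
                       if len(joined) >= 3 else np.nan)
        meta_rho = pd.Series(vals, name="rho_vs_meta")
    return ConcordanceGrid(rho, summary, meta_rho)


def top_n_genes(fit: pd.DataFrame, n: int = 100, direction: str = "up") -> list[str]:
    """Top-n genes by log2 fold-change (descending for up, ascending for down).

    Ties break by smaller p, then by gene symbol.  If fewer than n genes are
    available all are returned (logged).
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if len(fit) < n:
        log.warning("top_n_genes: only %d genes available for n=%d", len(fit), n)
    ordered = (fit.assign(_gene=fit.index)
               .sort_values(["log2fc", "p", "_gene"],
                            ascending=[direction == "down", True, True]))
    return ordered.index[:n].tolist()


GseaResult = namedtuple("GseaResult", ["statistic", "p", "d_plus", "d_minus"])


def cumulative_overlap_gsea(ranking, gene_set, B: int = 10000,
                            seed: int = 0) -> GseaResult:
    """Running-overlap enrichment of a gene set within an ordered ranking.

    ``ranking`` is the full gene universe ordered by descending human
    meta-fold-change; the statistic is positive when the set concentrates at
    the top of the ranking (genes increased in human) and negative when it
    concentrates at the bottom.  The permutation p draws ``B`` random
    same-size sets from the universe.
    """
    ranking = pd.Index(ranking)
    if ranking.has_duplicates:
        raise ValueError("ranking contains duplicate genes")
    gene_set = pd.Index(gene_set)
    missing = gene_set.difference(ranking)
    if len(missing):
        raise ValueError(f"gene set members absent from ranking: {list(missing)[:5]}")
    m = len(gene_set)
    if m < 5:
        raise ValueError("gene set must contain at least 5 genes")
    H = len(ranking)
    positions = np.sort(ranking.get_indexer(gene_set)) + 1  # 1-based ranks

    def deviations(pos: np.ndarray) -> tuple[float, float]:
        j = np.arange(1, m + 1)
        d_plus = max(0.0, float((j - m * pos / H).max()))
        d_minus = max(0.0, float((m * (pos - 1) / H - (j - 1)).max()))
        return d_plus, d_minus

    d_plus, d_minus = deviations(positions)
    statistic = (d_plus - d_minus) / m

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(B):
        pos = np.sort(rng.choice(H, size=m, replace=False)) + 1
        dp, dm = deviations(pos)
        if abs((dp - dm) / m) >= abs(statistic) - 1e-12:
            count += 1
    p = (1 + count) / (B + 1)
    return GseaResult(float(statistic), float(p), d_plus, d_minus)


MedianFcResult = namedtuple("MedianFcResult", ["median_fc", "p", "q25", "q75", "n"])


def median_fc_test(human_fcs) -> MedianFcResult:
    """Signed-rank test of a gene set's human linear FCs against 1.00.

    Two-sided one-sample Wilcoxon signed-rank on log2(FC) against zero,
    exact for small sets; reports the median linear FC with the middle-50%
    interval.  All FCs equal to 1 is degenerate and yields p = 1.
    """
    fc = np.asarray(human_fcs, dtype=float)
    if fc.size < 5:
        raise ValueError("need at least 5 genes")
    if (fc <= 0).any():
        raise ValueError("linear fold-changes must be positive")
    l2 = np.log2(fc)
    p = signed_rank_pvalue(l2, alternative="two-sided")
    return MedianFcResult(float(np.median(fc)), float(p),
                          float(np.quantile(fc, 0.25)),
                          float(np.quantile(fc, 0.75)), fc.size)
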