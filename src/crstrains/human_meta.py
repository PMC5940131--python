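"""Random-effects meta-signature of human adipose CR responses.

Each paired experiment contributes a per-gene mean log2 difference
(post - baseline, positive = increased by CR) with its standard error.
Experiments sharing a baseline sample set are statistically dependent, so
only the member with the lowest average standard error is retained per
baseline set; genes measured in too few retained experiments are excluded;
the surviving per-experiment effects are synthesized per gene with the
DerSimonian-Laird random-effects estimator (inverse-variance weights with
the moment estimate of the between-experiment variance tau^2) and the meta
p-values are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PairedExperiment
from .diffexpr import bh_adjust, moderate_variances, moderated_t_test

__all__ = [
    "ExperimentSummary",
    "MetaGeneResult",
    "MetaSignature",
    "paired_log2_differences",
    "low_expression_filter",
    "experiment_summary",
    "independence_filter",
    "gene_inclusion_filter",
    "dersimonian_laird",
    "meta_signature",
]

log = logging.getLogger(__name__)


@dataclass
class ExperimentSummary:
    """Per-gene paired statistics for one experiment.

    ``table`` columns: ``mean`` (log2 difference), ``se`` (sd/sqrt(n)),
    ``t``/``p`` (moderated one-sample test), ``degenerate`` (zero raw
    variance).  ``average_se`` is the mean of ``se`` over the retained genes
    and ranks experiments in the independence filter.
    """

    experiment_id: str
    baseline_set_id: str
    n_subjects: int
    table: pd.DataFrame
    average_se: float


@dataclass(frozen=True)
class MetaGeneResult:
    """DerSimonian-Laird synthesis for one gene."""

    mu: float           # meta log2FC
    se: float           # standard error of mu
    tau2: float         # between-experiment variance
    q_cochran: float
    z: float
    p: float
    k: int              # contributing experiments


def paired_log2_differences(exp: PairedExperiment) -> pd.DataFrame:
    """Per-gene, per-subject log2 differences post - baseline."""
    if not (exp.baseline.index.equals(exp.post.index)
            and exp.baseline.columns.equals(exp.post.columns)):
        raise ValueError("baseline and post matrices are misaligned")
    return exp.post - exp.baseline


def low_expression_filter(exp: PairedExperiment, fraction: float = 0.15) -> pd.Index:
    """Drop the lowest-expressed ``fraction`` of genes (floor convention).

    Genes are ranked by mean log2 expression over all baseline and post
    samples; ties break toward removing the lexicographically smallest gene
    symbol first.  Returns the retained genes in their original order.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    means = pd.concat([exp.baseline, exp.post], axis=1).mean(axis=1)
    order = np.lexsort((means.index.to_numpy(), means.to_numpy()))
    n_remove = math.floor(fraction * len(means))
    removed = means.index[order[:n_remove]]
    return exp.genes.difference(removed, sort=False)


def experiment_summary(differences: pd.DataFrame, experiment_id: str = "",
                       baseline_set_id: str = "") -> ExperimentSummary:
    """Per-gene mean, SE and moderated one-sample test of paired differences.

    The per-gene variance of the differences (df = n - 1) is moderated
    across genes before testing the mean against zero.
    """
    n = differences.shape[1]
    if n < 2:
        raise ValueError("at least two subjects are required")
    mean = differences.mean(axis=1)
    s2 = differences.var(axis=1, ddof=1)
    se = np.sqrt(s2 / n)
    prior, s2_post = moderate_variances(s2, n - 1)
    t, p = moderated_t_test(mean, 1.0 / math.sqrt(n), s2_post, n - 1,
                            prior.df_prior)
    table = pd.DataFrame({
        "mean": mean, "se": se, "t": t, "p": p,
        "degenerate": s2.to_numpy() == 0.0,
    })
    return ExperimentSummary(experiment_id, baseline_set_id, n, table,
                             float(se.mean()))


def independence_filter(summaries: list[ExperimentSummary]) -> list[ExperimentSummary]:
    """Keep one experiment per baseline set: the lowest average SE.

    Ties break toward the lexicographically smallest experiment id (logged).
    Output preserves the input order of the retained experiments.
    """
    best: dict[str, ExperimentSummary] = {}
    for s in summaries:
        cur = best.get(s.baseline_set_id)
        if cur is None:
            best[s.baseline_set_id] = s
        elif (s.average_se, s.experiment_id) < (cur.average_se, cur.experiment_id):
            if s.average_se == cur.average_se:
                log.info("average-SE tie in baseline set %s broken toward %s",
                         s.baseline_set_id, s.experiment_id)
            best[s.baseline_set_id] = s
    kept_ids = {s.experiment_id for s in best.values()}
    retained = [s for s in summaries if s.experiment_id in kept_ids]
    log.info("independence filter: %d of %d experiments retained (%d baseline sets)",
             len(retained), len(summaries), len(best))
    return retained


def gene_inclusion_filter(presence: pd.DataFrame, min_experiments: int = 6) -> pd.Index:
    """Genes measured in at least ``min_experiments`` retained experiments."""
    if min_experiments < 1:
        raise ValueError("min_experiments must be positive")
    counts = presence.astype(bool).sum(axis=1)
    return presence.index[counts >= min_experiments]


def dersimonian_laird(y, se) -> MetaGeneResult:
    """DerSimonian-Laird random-effects synthesis for one gene.

    Fixed weights w_i = 1/se_i^2 give Cochran's Q; the moment estimate
    tau^2 = max(0, (Q - (k-1)) / (sum(w) - sum(w^2)/sum(w))) feeds the
    random-effects weights w*_i = 1/(se_i^2 + tau^2); the synthesis is
    mu = sum(w* y)/sum(w*) with se(mu) = sum(w*)^(-1/2) and a two-sided
    normal p for z = mu/se(mu).
    """
    y = np.asarray(y, dtype=float)
    se = np.asarray(se, dtype=float)
    if y.shape != se.shape or y.ndim != 1:
        raise ValueError("y and se must be aligned 1-d arrays")
    k = y.size
    if k < 2:
        raise ValueError("at least two contributing experiments are required")
    if (se <= 0).any():
        raise ValueError("standard errors must be positive (floor degenerate "
                         "values upstream)")
    w = 1.0 / se ** 2
    ybar = (w * y).sum() / w.sum()
    q = (w * (y - ybar) ** 2).sum()
    denom = w.sum() - (w ** 2).sum() / w.sum()
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    wr = 1.0 / (se ** 2 + tau2)
    mu = (wr * y).sum() / wr.sum()
    se_mu = wr.sum() ** -0.5
    z = mu / se_mu
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return MetaGeneResult(float(mu), float(se_mu), float(tau2), float(q),
                          float(z), min(1.0, p), k)


@dataclass
class MetaSignature:
    """Gene-level meta-analysis results plus provenance counts."""

    table: pd.DataFrame                 # per gene: meta_log2fc, meta_fc, se, tau2, ...
    retained_experiments: list[str]
    n_input_experiments: int
    n_genes_union: int
    n_genes_included: int


def meta_signature(experiments: list[PairedExperiment],
                   low_expr_fraction: float = 0.15,
                   min_experiments: int = 6,
                   se_floor_quantile: float = 0.01) -> MetaSignature:
    """Full human meta-analysis composition.

    Per experiment: drop the lowest-expressed genes, form paired log2
    differences and summarize.  Across experiments: keep one per baseline
    set (lowest average SE), keep genes measured in at least
    ``min_experiments`` retained experiments, synthesize each with
    DerSimonian-Laird, and BH-adjust the meta p-values once over the final
    gene set.  Zero standard errors are floored at the ``se_floor_quantile``
    quantile of that experiment's positive SEs.
    """
    if len(experiments) < 2:
        raise ValueError("at least two experiments are required")
    summaries = []
    for exp in experiments:
        keep = low_expression_filter(exp, low_expr_fraction)
        diffs = paired_log2_differences(exp).loc[keep]
        summaries.append(experiment_summary(diffs, exp.experiment_id,
                                            exp.baseline_set_id))
    retained = independence_filter(summaries)
    if len(retained) < 2:
        raise ValueError("fewer than two independent experiments remain; "
                         "meta-analysis is undefined")

    union = retained[0].table.index
    for s in retained[1:]:
        union = union.union(s.table.index)
    union = union.sort_values()

    Y = np.full((len(union), len(retained)), np.nan)
    SE = np.full_like(Y, np.nan)
    for j, s in enumerate(retained):
        tab = s.table
        pos = tab["se"].to_numpy()
        positive = pos[pos > 0]
        floor = (np.quantile(positive, se_floor_quantile)
                 if positive.size else 1e-8)
        if (pos == 0).any():
            log.info("experiment %s: %d zero SEs floored at %.3g",
                     s.experiment_id, int((pos == 0).sum()), floor)
        se_vals = np.where(pos > 0, pos, floor)
        loc = union.get_indexer(tab.index)
        Y[loc, j] = tab["mean"].to_numpy()
        SE[loc, j] = se_vals

    presence = pd.DataFrame(~np.isnan(Y), index=union,
                            columns=[s.experiment_id for s in retained])
    included = gene_inclusion_filter(presence, min_experiments)

    rows = []
    for gene in included:
        i = union.get_loc(gene)
        mask = ~np.isnan(Y[i])
        res = dersimonian_laird(Y[i, mask], SE[i, mask])
        rows.append({"gene": gene, "meta_log2fc": res.mu,
                     "meta_fc": 2.0 ** res.mu, "se": res.se,
                     "tau2": res.tau2, "q_cochran": res.q_cochran,
                     "z": res.z, "p": res.p, "k_experiments": res.k})
    columns = ["gene", "meta_log2fc", "meta_fc", "se", "tau2", "q_cochran",
               "z", "p", "k_experiments"]
    table = pd.DataFrame(rows, columns=columns).set_index("gene")
    if len(table):
        table["fdr"] = bh_adjust(table["p"])
    else:
        log.warning("no gene measured in >= %d retained experiments", min_experiments)
        table["fdr"] = np.nan
    return MetaSignature(table, [s.experiment_id for s in retained],
                         len(experiments), len(union), len(included))
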