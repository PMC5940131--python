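"""Global transcriptome structure: factor dominance, PC response vectors,
fold-change correlation matrices and strain clustering.

Per-gene *factor dominance* asks whether strain or diet explains more
expression variation: nested Gaussian linear models are compared with
likelihood-ratio tests (statistic n*ln(RSS_reduced/RSS_full), chi-square
reference with df = parameters dropped) and the factor with the larger
-log10 p (Log10P) is called dominant.  *Response vectors* summarize each
strain's CR shift in the first two principal components of the
gene-centered expression matrix: arrows run from the bivariate mean of CTL
samples to the bivariate mean of CR samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "DominanceResult",
    "ResponseVectorSet",
    "ClusterResult",
    "factor_dominance",
    "pc_response_vectors",
    "fc_correlation_matrix",
    "strain_cluster",
]

log = logging.getLogger(__name__)

LN10 = math.log(10.0)


@dataclass
class DominanceResult:
    """Per-gene Log10P for diet and strain plus the dominant-factor summary."""

    per_gene: pd.DataFrame          # log10p_diet, log10p_strain, dominant
    percent_strain_dominant: float
    percent_diet_dominant: float


@dataclass
class ResponseVectorSet:
    """Per-strain CR response arrows in PC1/PC2 space."""

    scores: pd.DataFrame            # samples x (PC1, PC2)
    arrows: pd.DataFrame            # per strain: ctl/cr endpoints, length, angle
    explained_variance: np.ndarray  # fraction per component (all components)
    loadings: pd.DataFrame          # genes x (PC1, PC2)


@dataclass
class ClusterResult:
    """Agglomerative strain clustering on 1 - Spearman distance."""

    labels: list[str]
    linkage: np.ndarray             # scipy linkage matrix
    newick: str

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def _rss(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta
    return (resid ** 2).sum(axis=0)


def _log10_sf_chi2(lrt: np.ndarray, df: int) -> np.ndarray:
    # -log10 p via the log survival function for numerical range
    return -stats.chi2.logsf(lrt, df) / LN10


def factor_dominance(matrix: pd.DataFrame, strain_labels, diet_labels) -> DominanceResult:
    """Likelihood-ratio dominance of strain versus diet, per gene.

    Fits the full model (intercept + strain + diet) and the two reduced
    models dropping each factor; the factor whose removal degrades the fit
    more (larger Log10P) is dominant.  Ties break toward strain.
    """
    strains = pd.Series(list(strain_labels), index=matrix.columns)
    diets = pd.Series(list(diet_labels), index=matrix.columns)
    strain_levels = sorted(strains.unique())
    if len(strain_levels) < 2:
        raise ValueError("factor dominance requires at least two strains")
    if diets.nunique() != 2:
        raise ValueError("both diets must be present")

    n = matrix.shape[1]
    strain_dummies = pd.get_dummies(strains, drop_first=True).astype(float)
    diet_col = (diets == diets.unique()[1]).astype(float).rename("diet")
    intercept = pd.Series(1.0, index=matrix.columns, name="intercept")

    X_full = pd.concat([intercept, strain_dummies, diet_col], axis=1).to_numpy()
    X_no_diet = pd.concat([intercept, strain_dummies], axis=1).to_numpy()
    X_no_strain = pd.concat([intercept, diet_col], axis=1).to_numpy()

    Y = matrix.to_numpy(dtype=float)
    rss_full = _rss(Y, X_full)
    rss_full = np.maximum(rss_full, np.finfo(float).tiny)
    lrt_diet = n * np.log(np.maximum(_rss(Y, X_no_diet) / rss_full, 1.0))
    lrt_strain = n * np.log(np.maximum(_rss(Y, X_no_strain) / rss_full, 1.0))

    log10p_diet = _log10_sf_chi2(lrt_diet, 1)
    log10p_strain = _log10_sf_chi2(lrt_strain, len(strain_levels) - 1)
    dominant = np.where(log10p_strain >= log10p_diet, "strain", "diet")

    per_gene = pd.DataFrame({
        "log10p_diet": log10p_diet,
        "log10p_strain": log10p_strain,
        "dominant": dominant,
    }, index=matrix.index)
    pct_strain = 100.0 * (dominant == "strain").mean()
    return DominanceResult(per_gene, pct_strain, 100.0 - pct_strain)


def pc_response_vectors(matrix: pd.DataFrame, strain_labels, diet_labels,
                        ctl_label: str = "CTL", cr_label: str = "CR",
                        ) -> ResponseVectorSet:
    """Project samples onto PC1/PC2 and draw per-strain CTL -> CR arrows.

    PCA is computed on the gene-centered (not standardized) matrix via SVD;
    the sign convention makes each component's gene loadings sum positive.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples for a PC decomposition")
    strains = pd.Series(list(strain_labels), index=matrix.columns)
    diets = pd.Series(list(diet_labels), index=matrix.columns)

    centered = matrix.sub(matrix.mean(axis=1), axis=0)
    A = centered.to_numpy(dtype=float).T       # samples x genes
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    flip = np.where(Vt.sum(axis=1) < 0, -1.0, 1.0)
    scores_all = U * S * flip
    with np.errstate(invalid="ignore", divide="ignore"):
        explained = (S ** 2) / (S ** 2).sum() if S.size else S

    scores = pd.DataFrame(scores_all[:, :2], index=matrix.columns,
                          columns=["PC1", "PC2"])
    loadings = pd.DataFrame((Vt[:2].T * flip[:2]), index=matrix.index,
                            columns=["PC1", "PC2"])

    rows = []
    for strain in sorted(strains.unique()):
        ctl = scores[(strains == strain) & (diets == ctl_label)].mean()
        cr = scores[(strains == strain) & (diets == cr_label)].mean()
        dx, dy = cr["PC1"] - ctl["PC1"], cr["PC2"] - ctl["PC2"]
        rows.append({
            "strain": strain,
            "ctl_pc1": ctl["PC1"], "ctl_pc2": ctl["PC2"],
            "cr_pc1": cr["PC1"], "cr_pc2": cr["PC2"],
            "length": math.hypot(dx, dy),
            "angle_deg": math.degrees(math.atan2(dy, dx)),
        })
    arrows = pd.DataFrame(rows).set_index("strain")
    return ResponseVectorSet(scores, arrows, explained, loadings)


def fc_correlation_matrix(fit_tables: dict[str, pd.DataFrame],
                          gene_universe=None) -> pd.DataFrame:
    """Strain-by-strain Spearman correlation of log2 fold-change vectors.

    Each pairwise correlation uses the genes present (non-missing) in both
    tables (complete pairs); entries with fewer than three shared genes are
    set to NaN and logged.  The diagonal is exactly 1.
    """
    strains = list(fit_tables)
    fcs = pd.DataFrame({s: fit_tables[s]["log2fc"] for s in strains})
    if gene_universe is not None:
        fcs = fcs.loc[fcs.index.intersection(pd.Index(gene_universe))]
    out = pd.DataFrame(np.eye(len(strains)), index=strains, columns=strains)
    for i, a in enumerate(strains):
        for b in strains[i + 1:]:
            pair = fcs[[a, b]].dropna()
            if len(pair) < 3:
                log.warning("correlation %s vs %s undefined (<3 shared genes)", a, b)
                rho = np.nan
            else:
                rho = stats.spearmanr(pair[a], pair[b]).statistic
            out.loc[a, b] = out.loc[b, a] = rho
    return out


def strain_cluster(correlation_matrix: pd.DataFrame) -> ClusterResult:
    """Average-linkage agglomerative clustering of strains at distance 1 - rho.

    The merge order is deterministic (scipy's nearest-neighbor chain with
    index-order tie-breaking); the dendrogram is also rendered as a Newick
    string with branch lengths as height differences.
    """
    M = correlation_matrix.to_numpy(dtype=float)
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, equal_nan=True):
        raise ValueError("correlation matrix must be square and symmetric")
    if np.isnan(M).any():
        raise ValueError("correlation matrix contains undefined entries")
    dist = 1.0 - M
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    labels = [str(x) for x in correlation_matrix.index]
    tree = hierarchy.to_tree(Z)

    def to_newick(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{labels[node.id]}:{length:.10g}"
        left = to_newick(node.left, node.dist)
        right = to_newick(node.right, node.dist)
        return f"({left},{right}):{parent_height - node.dist:.10g}"

    newick = f"({to_newick(tree.left, tree.dist)},{to_newick(tree.right, tree.dist)});"
    return ClusterResult(labels, Z, newick)
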