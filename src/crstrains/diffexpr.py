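"""Per-gene linear models with empirical-Bayes variance moderation.

Each gene is fit by ordinary least squares against a shared design matrix;
per-gene residual variances are then shrunk toward a global prior estimated
across genes by the closed-form moment estimator on log variances, and
t-statistics for a coefficient of interest are referenced to a
t-distribution with augmented degrees of freedom d_g + d0.  This is the
standard moderated-t construction for microarray differential expression.

A gene is a "DEG" when its Benjamini-Hochberg FDR is below ``q_max`` and its
linear fold-change (FC = 2^log2FC) is above ``fc_up`` or below ``fc_down``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LinearFit",
    "ModerationPrior",
    "fit_gene_linear_models",
    "moderate_variances",
    "moderated_t_test",
    "bh_adjust",
    "call_degs",
    "cr_contrast",
    "interaction_scan",
]

log = logging.getLogger(__name__)


@dataclass
class LinearFit:
    """OLS results for all genes against one design matrix."""

    coefficients: pd.DataFrame      # genes x terms
    sigma2: pd.Series               # residual variance s2_g per gene
    df_residual: int                # n - rank(design), common to all genes
    stdev_unscaled: pd.Series       # per-term sqrt of diag((X'X)^-1)


@dataclass(frozen=True)
class ModerationPrior:
    """Empirical-Bayes variance prior: d0 may be infinite."""

    df_prior: float
    s2_prior: float

    def __post_init__(self) -> None:
        if not (self.df_prior > 0):
            raise ValueError("prior degrees of freedom must be > 0")
        if not (self.s2_prior > 0):
            raise ValueError("prior variance must be > 0")


def _check_full_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    collinear = [
        str(col) for i, col in enumerate(design.columns)
        if np.linalg.matrix_rank(np.delete(X, i, axis=1)) == rank
    ]
    raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")


def fit_gene_linear_models(matrix: pd.DataFrame, design: pd.DataFrame) -> LinearFit:
    """Ordinary least squares per gene against a shared design.

    Parameters
    ----------
    matrix
        genes x samples log2 expression.
    design
        samples x terms design matrix (full rank; rows aligned with the
        matrix columns).
    """
    if not matrix.columns.equals(design.index):
        raise ValueError("design rows must align with matrix columns")
    n, p = design.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} samples for {p} parameters, got {n}")
    _check_full_rank(design)

    X = design.to_numpy(dtype=float)
    Y = matrix.to_numpy(dtype=float)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ xtx_inv                      # genes x p
    resid = Y - beta @ X.T
    df_residual = n - p
    sigma2 = (resid ** 2).sum(axis=1) / df_residual
    return LinearFit(
        coefficients=pd.DataFrame(beta, index=matrix.index, columns=design.columns),
        sigma2=pd.Series(sigma2, index=matrix.index, name="sigma2"),
        df_residual=df_residual,
        stdev_unscaled=pd.Series(np.sqrt(np.diag(xtx_inv)), index=design.columns),
    )


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y by monotone Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < tol:
            break
    return x


def moderate_variances(s2, d) -> tuple[ModerationPrior, pd.Series]:
    """Estimate the variance prior and return posterior (moderated) variances.

    The prior (d0, s0^2) is fit by moment matching on
    e_g = log s2_g - digamma(d_g/2) + log(d_g/2): the excess of the sample
    variance of e over the expected trigamma dispersion determines d0 via
    the trigamma inverse, and s0^2 follows from the mean of e.  Genes with
    zero sample variance are excluded from prior estimation but are still
    moderated.  If the excess dispersion is <= 0, d0 = infinity and every
    posterior variance equals s0^2.
    """
    s2 = pd.Series(s2, dtype=float)
    if (s2 < 0).any():
        raise ValueError("sample variances must be >= 0")
    d_arr = np.broadcast_to(np.asarray(d, dtype=float), s2.shape)
    if (d_arr <= 0).any():
        raise ValueError("residual degrees of freedom must be > 0")
    ok = s2.to_numpy() > 0
    if ok.sum() < 10:
        raise ValueError("need at least 10 genes with positive variance to "
                         "estimate the prior")
    s2_ok = s2.to_numpy()[ok]
    d_ok = d_arr[ok]
    e = np.log(s2_ok) - special.digamma(d_ok / 2.0) + np.log(d_ok / 2.0)
    emean = e.mean()
    n_ok = e.size
    evar = ((e - emean) ** 2).sum() / (n_ok - 1) - np.mean(special.polygamma(1, d_ok / 2.0))
    if evar > 0:
        df_prior = 2.0 * _trigamma_inverse(float(evar))
        s2_prior = float(np.exp(emean + special.digamma(df_prior / 2.0)
                                - np.log(df_prior / 2.0)))
    else:
        df_prior = np.inf
        s2_prior = float(np.exp(emean))
    prior = ModerationPrior(df_prior, s2_prior)

    if np.isinf(df_prior):
        post = np.full(s2.shape, s2_prior)
    else:
        post = (df_prior * s2_prior + d_arr * s2.to_numpy()) / (df_prior + d_arr)
    return prior, pd.Series(post, index=s2.index, name="s2_post")


def moderated_t_test(beta, stdev_unscaled, s2_post, df_residual,
                     df_prior) -> tuple[pd.Series, pd.Series]:
    """Moderated t and two-sided p for one coefficient across genes.

    t = beta / (u * s_post); the reference distribution is t with
    df_residual + df_prior degrees of freedom (standard normal when the
    prior degrees of freedom are infinite).  Genes with zero posterior
    variance get NaN p-values (degenerate; flagged upstream).
    """
    beta = pd.Series(beta, dtype=float)
    s2_post = np.broadcast_to(np.asarray(s2_post, dtype=float), beta.shape)
    u = np.broadcast_to(np.asarray(stdev_unscaled, dtype=float), beta.shape)
    denom = u * np.sqrt(s2_post)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, beta.to_numpy() / denom, np.nan)
    df_total = df_residual + df_prior
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # beta == 0 must give p exactly 1 even when the variance is degenerate
    p = np.where(beta.to_numpy() == 0.0, np.where(denom > 0, p, 1.0), p)
    return (pd.Series(t, index=beta.index, name="t"),
            pd.Series(np.minimum(p, 1.0), index=beta.index, name="p"))


def bh_adjust(p) -> pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = pd.Series(p, dtype=float)
    arr = p.to_numpy()
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1] with no missing values")
    q = multipletests(arr, method="fdr_bh")[1]
    return pd.Series(q, index=p.index, name="fdr")


def call_degs(fit: pd.DataFrame, q_max: float = 0.10, fc_up: float = 1.50,
              fc_down: float = 0.67) -> pd.DataFrame:
    """Differentially expressed genes: q < q_max and FC outside [fc_down, fc_up].

    Returns a table indexed by gene with a ``direction`` column (up/down).
    """
    if not {"fdr", "fc"}.issubset(fit.columns):
        raise ValueError("fit table needs 'fdr' and 'fc' columns")
    sig = (fit["fdr"] < q_max) & ((fit["fc"] > fc_up) | (fit["fc"] < fc_down))
    out = fit.loc[sig, ["fc", "fdr"]].copy()
    out["direction"] = np.where(out["fc"] > 1.0, "up", "down")
    return out


def _finalize_fit(genes: pd.Index, beta: pd.Series, u: float, fit: LinearFit,
                  prior: ModerationPrior, s2_post: pd.Series,
                  q_max: float, fc_up: float, fc_down: float) -> pd.DataFrame:
    t, p = moderated_t_test(beta, u, s2_post, fit.df_residual, prior.df_prior)
    table = pd.DataFrame({
        "log2fc": beta,
        "fc": np.exp2(beta),
        "s2": fit.sigma2,
        "s2_post": s2_post,
        "t": t,
        "p": p,
        "fdr": bh_adjust(p.fillna(1.0)),
        "df_residual": fit.df_residual,
        "df_total": fit.df_residual + prior.df_prior,
    }, index=genes)
    degs = call_degs(table, q_max, fc_up, fc_down)
    table["deg"] = table.index.isin(degs.index)
    table["direction"] = "none"
    table.loc[degs.index, "direction"] = degs["direction"]
    return table


def cr_contrast(matrix: pd.DataFrame, diet_labels, q_max: float = 0.10,
                fc_up: float = 1.50, fc_down: float = 0.67,
                cr_label: str = "CR") -> pd.DataFrame:
    """CR-vs-CTL two-group moderated-t contrast for one strain/tissue cell.

    ``diet_labels`` aligns with the matrix columns; the diet coefficient is
    the mean log2 difference CR - CTL, i.e. the log2 fold-change.  Returns a
    gene fit table with columns log2fc, fc, t, p, fdr, deg, direction.
    """
    diets = pd.Series(list(diet_labels), index=matrix.columns)
    if diets.nunique() != 2:
        raise ValueError("exactly two diet groups are required")
    design = pd.DataFrame({
        "intercept": 1.0,
        "diet": (diets == cr_label).astype(float),
    }, index=matrix.columns)
    fit = fit_gene_linear_models(matrix, design)
    prior, s2_post = moderate_variances(fit.sigma2, fit.df_residual)
    return _finalize_fit(matrix.index, fit.coefficients["diet"],
                         fit.stdev_unscaled["diet"], fit, prior, s2_post,
                         q_max, fc_up, fc_down)


def interaction_scan(matrix: pd.DataFrame, strain_labels, diet_labels,
                     focal_strain: str, q_max: float = 0.10,
                     fc_up: float = 1.50, fc_down: float = 0.67,
                     cr_label: str = "CR") -> pd.DataFrame:
    """Strain-by-diet interaction scan for one focal strain.

    Fits Expression = Diet + Strain + Diet*Strain per gene, where Diet is a
    0/1 CR indicator and Strain is 1 for the focal strain and 0 for the
    pooled remaining strains; tests the interaction coefficient (the excess
    CR response of the focal strain) with the moderated t, BH-adjusted
    within the scan.
    """
    strains = pd.Series(list(strain_labels), index=matrix.columns)
    diets = pd.Series(list(diet_labels), index=matrix.columns)
    if strains.nunique() < 2:
        raise ValueError("interaction scan requires at least two strains")
    if focal_strain not in set(strains):
        raise ValueError(f"focal strain {focal_strain!r} absent from data")
    focal = (strains == focal_strain).astype(float)
    diet = (diets == cr_label).astype(float)
    for name, grp in (("focal strain", focal == 1), ("other strains", focal == 0)):
        if diets[grp].nunique() != 2:
            raise ValueError(f"{name} must include both diets")
    design = pd.DataFrame({
        "intercept": 1.0,
        "diet": diet,
        "strain": focal,
        "interaction": diet * focal,
    }, index=matrix.columns)
    fit = fit_gene_linear_models(matrix, design)
    prior, s2_post = moderate_variances(fit.sigma2, fit.df_residual)
    return _finalize_fit(matrix.index, fit.coefficients["interaction"],
                         fit.stdev_unscaled["interaction"], fit, prior, s2_post,
                         q_max, fc_up, fc_down)
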