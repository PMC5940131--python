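"""Detection calling, probe collapsing, expression filtering and QC exclusion.

Above-background detection follows the perfect-match / mismatch (PM/MM)
convention of early oligonucleotide arrays: a probe set is called detected
when a one-sided Wilcoxon signed-rank test supports PM > MM, and a gene is
detectable in a sample when at least half of its probe sets are detected at
P < 0.05.  Downstream testing is restricted to genes detectable in at least
a third of the samples entering a given CR-vs-CTL comparison.
"""

from __future__ import annotations

import logging
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionStudy

__all__ = [
    "signed_rank_pvalue",
    "detection_call",
    "gene_detectable",
    "expression_filter",
    "collapse_probes",
    "exclude_flagged_samples",
]

log = logging.getLogger(__name__)

EXACT_MAX_N = 25  # exact signed-rank null up to this many nonzero pairs


def _exact_sf(ranks: np.ndarray, w_obs: float) -> float:
    """P(W >= w_obs) under sign flips of the observed (mid)ranks.

    Uses a generating-function convolution over doubled ranks (midranks of
    tied |differences| are half-integers, so doubling makes them integers).
    This equals brute-force enumeration of all 2^n sign patterns and is
    exact in the presence of ties.
    """
    doubled = np.rint(2 * ranks).astype(np.int64)
    total = int(doubled.sum())
    # counts[w] = number of sign patterns with doubled positive-rank sum w
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        counts[r:] += counts[: total + 1 - r].copy()
    threshold = int(np.ceil(2 * w_obs - 1e-9))
    return float(counts[threshold:].sum() / 2.0 ** len(ranks))


def signed_rank_pvalue(diffs: np.ndarray, alternative: str = "greater") -> float:
    """Wilcoxon signed-rank p-value with exact small-sample null.

    Zero differences are dropped before ranking (standard convention); tied
    absolute differences receive midranks.  For <= 25 nonzero pairs the null
    distribution is computed exactly by sign-flip enumeration (conditional on
    the observed midranks); above that a normal approximation with tie and
    continuity corrections is used.

    Parameters
    ----------
    diffs
        Paired differences.
    alternative
        ``"greater"`` (positive shift) or ``"two-sided"``.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    n = d.size
    if n <= EXACT_MAX_N:
        p_greater = _exact_sf(ranks, w_pos)
        if alternative == "greater":
            return min(1.0, p_greater)
        w_total = n * (n + 1) / 2.0
        p_less = _exact_sf(ranks, w_total - w_pos)  # P(W <= w_pos) by symmetry
        return min(1.0, 2.0 * min(p_greater, p_less))
    # normal approximation with tie-corrected variance and continuity correction
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts ** 3 - tie_counts).sum()) / 48.0
    if var <= 0:
        return 1.0
    z = (w_pos - mean - 0.5) / np.sqrt(var)
    if alternative == "greater":
        return float(stats.norm.sf(z))
    z2 = (abs(w_pos - mean) - 0.5) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(z2)))


def detection_call(probe_pairs) -> float:
    """One-sided (PM > MM) signed-rank p-value for a probe set.

    ``probe_pairs`` is a sequence of (PM, MM) intensity pairs; at least five
    pairs of positive intensities are required.  All PM equal to MM yields
    p = 1.0 (undetected).
    """
    pairs = np.asarray(probe_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("probe_pairs must be a sequence of (PM, MM) pairs")
    if pairs.shape[0] < 5:
        raise ValueError(f"at least 5 probe pairs required, got {pairs.shape[0]}")
    if (pairs <= 0).any():
        raise ValueError("probe intensities must be positive")
    return signed_rank_pvalue(pairs[:, 0] - pairs[:, 1], alternative="greater")


def gene_detectable(probeset_pvalues, alpha: float = 0.05,
                    min_fraction: float = 0.5) -> bool:
    """True iff at least half of the probe-set p-values fall below alpha."""
    p = np.asarray(probeset_pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("probeset_pvalues must be nonempty")
    return bool((p < alpha).sum() * 1.0 >= min_fraction * p.size)


def expression_filter(detection: pd.DataFrame, comparison_samples,
                      min_fraction: Fraction | float = Fraction(1, 3)) -> pd.Index:
    """Genes detectable in at least ``min_fraction`` of the comparison samples.

    The threshold is an exact fraction (default 1/3), evaluated with integer
    arithmetic so that e.g. 5/15 samples sits exactly on the boundary and is
    retained.
    """
    if detection.size == 0:
        raise ValueError("detection matrix is empty")
    ids = pd.Index(comparison_samples)
    if not len(ids):
        raise ValueError("comparison_samples must be nonempty")
    unknown = ids.difference(detection.columns)
    if len(unknown):
        raise KeyError(f"samples missing from detection matrix: {list(unknown)[:5]}")
    frac = Fraction(min_fraction).limit_denominator(10 ** 6)
    counts = detection[ids].sum(axis=1).to_numpy()
    keep = counts * frac.denominator >= frac.numerator * len(ids)
    return detection.index[keep]


def collapse_probes(probe_matrix: pd.DataFrame, probe_map: pd.DataFrame) -> pd.DataFrame:
    """Collapse a probe-level matrix to one representative probe per gene.

    ``probe_map`` has columns ``probe_id`` and ``gene_symbol`` (many probes
    to one gene).  For multi-probe genes the probe with the highest average
    expression across all samples represents the gene; ties break toward the
    lexicographically smallest probe id.
    """
    required = {"probe_id", "gene_symbol"}
    if not required.issubset(probe_map.columns):
        raise ValueError(f"probe_map needs columns {sorted(required)}")
    if probe_map["probe_id"].duplicated().any():
        raise ValueError("probe_map maps some probe to more than one gene")
    unmapped = probe_matrix.index.difference(pd.Index(probe_map["probe_id"]))
    if len(unmapped):
        raise ValueError(f"unmapped probes: {list(unmapped)[:5]}")

    means = probe_matrix.mean(axis=1)
    choice = (probe_map.set_index("probe_id")
              .assign(avg=means)
              .dropna(subset=["avg"])
              .sort_values(["gene_symbol", "avg", "probe_id"],
                           ascending=[True, False, True])
              .groupby("gene_symbol", sort=True).head(1))
    out = probe_matrix.loc[choice.index]
    out.index = pd.Index(choice["gene_symbol"], name="gene")
    if out.index.has_duplicates:
        dups = out.index[out.index.duplicated()].unique().tolist()
        raise ValueError(f"collapse produced duplicate gene symbols: {dups[:5]}")
    return out


def exclude_flagged_samples(study: ExpressionStudy,
                            flagged_ids=None) -> ExpressionStudy:
    """Drop QC-failed samples from the matrix and metadata.

    By default samples with ``qc_flag == 'fail'`` are removed; an explicit
    list of sample ids may be supplied instead (unknown ids are an error).
    """
    if flagged_ids is not None:
        flagged = pd.Index(flagged_ids)
        unknown = flagged.difference(study.samples.index)
        if len(unknown):
            raise KeyError(f"flagged ids not present in study: {list(unknown)}")
    else:
        flagged = study.samples.index[study.samples["qc_flag"] == "fail"]
    keep = study.samples.index.difference(flagged, sort=False)
    if not len(keep):
        raise ValueError("all samples flagged; nothing left to analyze")
    log.info("QC exclusion: %d of %d samples removed, %d retained",
             len(flagged), study.n_samples, len(keep))
    out = study.subset_samples(keep)
    out.samples.loc[:, "qc_flag"] = "pass"
    return out
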