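"""Synthetic study generator with known ground truth.

Emulates the statistical structure of a multi-strain mouse caloric-restriction
(CR) study — a full factorial of strains x tissues x diets (CTL, CR) with a
fixed number of replicate animals per cell — together with a collection of
paired human subcutaneous-WAT experiments (baseline / post-intervention
matrices, some experiments sharing a baseline sample set).

Planted structure, all on the log2 scale:

* a fraction of genes carries a *shared* CR effect (same in every strain),
* a disjoint fraction carries a *strain-specific* CR effect confined to one
  focal strain (these genes are the true strain-by-diet interactions),
* every gene has diet-independent per-strain offsets and a gene-specific
  residual variance drawn from a scaled inverse-chi-square prior, so that
  empirical-Bayes variance moderation has a correctly specified target,
* true human CR effects are tied to the mouse shared effects through a
  configurable correlation (``concordance_rho``), allowing cross-species
  concordance recovery to be checked against ground truth.

All randomness flows from one explicit integer seed; identical inputs
reproduce identical outputs bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionStudy, PairedExperiment, TruthTable

__all__ = [
    "StudyDesign",
    "MouseEffectModel",
    "HumanMetaConfig",
    "DEFAULT_STRAINS",
    "DEFAULT_TISSUES",
    "simulate_mouse_study",
    "simulate_human_experiments",
    "simulate_probe_level",
    "simulate_ortholog_map",
]

# The deposited multi-strain CR study design: 7 strains x 4 tissues x 2 diets
# x 8 replicate mice = 448 arrays.
DEFAULT_STRAINS = ("B6", "BALBc", "C3H", "129", "CBA", "DBA", "F1")
DEFAULT_TISSUES = ("eWAT", "muscle", "heart", "cortex")


@dataclass(frozen=True)
class StudyDesign:
    """Full-factorial mouse study layout."""

    strains: tuple[str, ...] = DEFAULT_STRAINS
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    diets: tuple[str, str] = ("CTL", "CR")
    replicates_per_cell: int = 8
    n_genes: int = 2000

    def __post_init__(self) -> None:
        for name, labels in (("strains", self.strains), ("tissues", self.tissues),
                             ("diets", self.diets)):
            if len(set(labels)) != len(labels):
                raise ValueError(f"{name} labels must be unique: {labels}")
        if len(self.diets) != 2:
            raise ValueError("exactly two diets (CTL, CR) are required")
        if self.replicates_per_cell < 1:
            raise ValueError("replicates_per_cell must be a positive integer")
        if self.n_genes < 1:
            raise ValueError("n_genes must be a positive integer")

    @property
    def n_samples(self) -> int:
        return (len(self.strains) * len(self.tissues) * len(self.diets)
                * self.replicates_per_cell)


@dataclass(frozen=True)
class MouseEffectModel:
    """Planted effect structure for the mouse simulation (log2 units).

    ``fraction_shared`` of genes receive a CR effect common to all strains,
    drawn N(0, shared_effect_sd); a disjoint ``fraction_strain_specific``
    receive a CR effect in a single focal strain drawn from
    ``interaction_strains`` (default: every strain eligible).  Residual
    variances are gene-specific, s2_g ~ s0^2 * var_prior_df / chi2(var_prior_df)
    with s0 = residual_sd.
    """

    shared_effect_sd: float = 0.6
    strain_specific_effect_sd: float = 0.8
    fraction_shared: float = 0.10
    fraction_strain_specific: float = 0.05
    interaction_strains: tuple[str, ...] | None = None
    residual_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_mean_sd: float = 1.5
    strain_offset_sd: float = 0.5
    var_prior_df: float = 4.0
    n_qc_fail: int = 12
    detect_threshold: float = 6.0

    def __post_init__(self) -> None:
        sds = {
            "shared_effect_sd": self.shared_effect_sd,
            "strain_specific_effect_sd": self.strain_specific_effect_sd,
            "residual_sd": self.residual_sd,
            "baseline_mean_sd": self.baseline_mean_sd,
            "strain_offset_sd": self.strain_offset_sd,
        }
        for name, value in sds.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        for name, frac in (("fraction_shared", self.fraction_shared),
                           ("fraction_strain_specific", self.fraction_strain_specific)):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {frac}")
        if self.fraction_shared + self.fraction_strain_specific > 1.0:
            raise ValueError("fraction_shared + fraction_strain_specific must be <= 1")
        if self.var_prior_df <= 0:
            raise ValueError("var_prior_df must be > 0")
        if self.n_qc_fail < 0:
            raise ValueError("n_qc_fail must be >= 0")


@dataclass(frozen=True)
class HumanMetaConfig:
    """Layout and effect structure for the paired human experiments.

    Defaults emulate the human scWAT meta-analysis setting: 28 experiments
    over 18 distinct baseline sample sets, 3-40 subjects each.  ``tau2`` is
    the between-experiment variance of the true per-gene effect (random
    effects heterogeneity); ``concordance_rho`` links true human effects to
    the standardized mouse shared effects.
    """

    n_experiments: int = 28
    subjects_range: tuple[int, int] = (3, 40)
    n_baseline_sets: int = 18
    concordance_rho: float = -0.3
    missing_gene_fraction: float = 0.10
    residual_sd: float = 0.5
    tau2: float = 0.02
    effect_sd: float = 0.4
    baseline_mean: float = 8.0
    baseline_mean_sd: float = 1.5
    baseline_set_sizes: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be positive")
        if self.n_baseline_sets > self.n_experiments:
            raise ValueError("n_baseline_sets must be <= n_experiments")
        if self.n_baseline_sets < 1:
            raise ValueError("n_baseline_sets must be positive")
        lo, hi = self.subjects_range
        if lo < 2 or hi < lo:
            raise ValueError("subjects_range must be an integer interval with lower bound >= 2")
        if not -1.0 <= self.concordance_rho <= 1.0:
            raise ValueError("concordance_rho must lie in [-1, 1]")
        if not 0.0 <= self.missing_gene_fraction <= 1.0:
            raise ValueError("missing_gene_fraction must lie in [0, 1]")
        if self.residual_sd < 0 or self.effect_sd < 0 or self.tau2 < 0:
            raise ValueError("residual_sd, effect_sd and tau2 must be >= 0")
        if self.baseline_set_sizes is not None:
            sizes = tuple(self.baseline_set_sizes)
            if len(sizes) != self.n_baseline_sets:
                raise ValueError("baseline_set_sizes must have n_baseline_sets entries")
            if any(s < 1 for s in sizes):
                raise ValueError("baseline_set_sizes entries must be positive")
            if sum(sizes) != self.n_experiments:
                raise ValueError("baseline_set_sizes must sum to n_experiments")


def _gene_symbols(n: int) -> pd.Index:
    return pd.Index([f"Gene{i:05d}" for i in range(n)], name="gene")


def simulate_mouse_study(design: StudyDesign = StudyDesign(),
                         effects: MouseEffectModel = MouseEffectModel(),
                         seed: int = 0) -> tuple[ExpressionStudy, TruthTable]:
    """Simulate a full-factorial multi-strain CR study.

    Expression for gene g in sample (tissue t, strain s, diet d, replicate r):

        y = baseline_g + offset_{g,s,t} + 1[d = CR] * effect_{g,s,t} + eps,
        eps ~ N(0, sigma_g)

    Returns the study (with per-sample QC flags and a detection matrix) and
    the ground-truth table of planted effects and flags.
    """
    rng = np.random.default_rng(seed)
    genes = _gene_symbols(design.n_genes)
    G = design.n_genes
    focal_pool = effects.interaction_strains or design.strains
    unknown = set(focal_pool) - set(design.strains)
    if unknown:
        raise ValueError(f"interaction_strains not in design: {sorted(unknown)}")

    baseline = effects.baseline_mean + rng.normal(0.0, effects.baseline_mean_sd, G)
    # gene-specific residual variances from a scaled inverse-chi-square prior
    d0 = effects.var_prior_df
    sigma2 = effects.residual_sd ** 2 * d0 / rng.chisquare(d0, G)
    sigma = np.sqrt(sigma2)

    n_shared = int(round(effects.fraction_shared * G))
    n_specific = int(round(effects.fraction_strain_specific * G))

    truth_rows: list[pd.DataFrame] = []
    columns: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []

    for tissue in design.tissues:
        chosen = rng.choice(G, size=n_shared + n_specific, replace=False)
        shared_idx = chosen[:n_shared]
        specific_idx = chosen[n_shared:]
        shared = np.zeros(G)
        shared[shared_idx] = rng.normal(0.0, effects.shared_effect_sd, n_shared)
        focal = rng.choice(len(focal_pool), size=n_specific)

        offsets = rng.normal(0.0, effects.strain_offset_sd,
                             (G, len(design.strains)))
        effect = np.tile(shared[:, None], (1, len(design.strains)))
        for j, s in enumerate(design.strains):
            mask = np.array([focal_pool[f] == s for f in focal], dtype=bool)
            idx = specific_idx[mask]
            effect[idx, j] += rng.normal(0.0, effects.strain_specific_effect_sd,
                                         mask.sum())

        flags_shared = np.zeros(G, bool)
        flags_shared[shared_idx] = True
        flags_specific = np.zeros(G, bool)
        flags_specific[specific_idx] = True

        for j, strain in enumerate(design.strains):
            for diet in design.diets:
                is_cr = float(diet == design.diets[1])
                noise = rng.normal(0.0, 1.0, (G, design.replicates_per_cell)) * sigma[:, None]
                vals = (baseline[:, None] + offsets[:, [j]]
                        + is_cr * effect[:, [j]] + noise)
                for r in range(design.replicates_per_cell):
                    sid = f"{tissue}_{strain}_{diet}_{r + 1:02d}"
                    columns[sid] = vals[:, r]
                    meta_rows.append({"sample_id": sid, "strain": strain,
                                      "diet": diet, "tissue": tissue,
                                      "qc_flag": "pass"})

        for j, strain in enumerate(design.strains):
            truth_rows.append(pd.DataFrame({
                "gene": genes, "tissue": tissue, "strain": strain,
                "true_log2fc": effect[:, j],
                "shared": flags_shared,
                # only truly interaction genes: specific effect present in this strain
                "strain_specific": flags_specific,
                "interaction": flags_specific,
            }))

    matrix = pd.DataFrame(columns, index=genes)
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    if effects.n_qc_fail:
        if effects.n_qc_fail >= len(samples):
            raise ValueError("n_qc_fail must be smaller than the sample count")
        fail = rng.choice(len(samples), size=effects.n_qc_fail, replace=False)
        samples.iloc[fail, samples.columns.get_loc("qc_flag")] = "fail"
    detection = matrix > effects.detect_threshold

    # truth.human starts at zero; simulate_human_experiments fills it in
    truth = TruthTable(
        mouse=pd.concat(truth_rows, ignore_index=True),
        human=pd.Series(np.zeros(G), index=genes, name="true_log2fc"),
    )
    study = ExpressionStudy(matrix, samples, detection, seed=seed)
    return study, truth


def _mouse_shared_vector(truth: TruthTable, tissue: str) -> pd.Series:
    """Mean true CR effect across strains in the reference tissue."""
    eff = truth.effects(tissue)
    return eff.mean(axis=1)


def simulate_human_experiments(config: HumanMetaConfig,
                               truth: TruthTable,
                               seed: int,
                               reference_tissue: str | None = None,
                               ortholog_map: pd.DataFrame | None = None,
                               ) -> list[PairedExperiment]:
    """Simulate paired human experiments tied to the mouse ground truth.

    True human effects are built as
    ``rho * z(mouse shared effect) + sqrt(1 - rho^2) * eps`` with ``eps``
    standard normal, rescaled to ``config.effect_sd``; the result is stored
    back into ``truth.human``.  Experiments in the same baseline set reuse
    identical baseline samples (and gene coverage); per-experiment true
    effects deviate from the gene-level mean with variance ``tau2``.

    If ``ortholog_map`` is given (columns ``mouse_symbol``/``human_symbol``),
    human matrices are indexed by human symbols of mapped genes only.
    """
    rng = np.random.default_rng(seed)
    tissues = truth.mouse["tissue"].unique()
    tissue = reference_tissue or tissues[0]
    m = _mouse_shared_vector(truth, tissue)
    z = (m - m.mean()) / (m.std(ddof=0) or 1.0)
    rho = config.concordance_rho
    eps = rng.normal(0.0, 1.0, len(z))
    h = rho * z.to_numpy() + math.sqrt(max(0.0, 1.0 - rho ** 2)) * eps
    human_effect = pd.Series(h * config.effect_sd, index=m.index, name="true_log2fc")
    truth.human = human_effect

    if ortholog_map is not None:
        mapped = ortholog_map.set_index("mouse_symbol")["human_symbol"]
        keep = human_effect.index.intersection(mapped.index)
        gene_effect = human_effect.loc[keep]
        gene_names = pd.Index(mapped.loc[keep], name="gene")
    else:
        gene_effect = human_effect
        gene_names = human_effect.index

    sizes = (tuple(config.baseline_set_sizes)
             if config.baseline_set_sizes is not None
             else _round_robin_sizes(config.n_experiments, config.n_baseline_sets))

    G = len(gene_effect)
    lo, hi = config.subjects_range
    experiments: list[PairedExperiment] = []
    exp_counter = 0
    sexes = np.array(["male", "female", "unknown"])
    # observed mix in the emulated meta-analysis: 10 male, 15 female, 3 unknown of 28
    sex_p = np.array([10, 15, 3]) / 28.0

    for set_idx, size in enumerate(sizes):
        set_id = f"BS{set_idx + 1:02d}"
        n_subj = int(rng.integers(lo, hi + 1))
        present = rng.random(G) >= config.missing_gene_fraction
        idx = gene_names[present]
        base_mean = config.baseline_mean + rng.normal(
            0.0, config.baseline_mean_sd, present.sum())
        baseline = pd.DataFrame(
            base_mean[:, None] + rng.normal(0.0, config.residual_sd,
                                            (present.sum(), n_subj)),
            index=idx,
            columns=[f"{set_id}_S{j + 1:02d}" for j in range(n_subj)],
        )
        for _ in range(size):
            exp_counter += 1
            eid = f"EXP{exp_counter:02d}"
            per_exp = gene_effect.to_numpy()[present]
            if config.tau2 > 0:
                per_exp = per_exp + rng.normal(0.0, math.sqrt(config.tau2),
                                               present.sum())
            post = baseline + per_exp[:, None] + rng.normal(
                0.0, config.residual_sd, baseline.shape)
            experiments.append(PairedExperiment(
                experiment_id=eid,
                baseline=baseline.copy(),
                post=post,
                baseline_set_id=set_id,
                sex=str(rng.choice(sexes, p=sex_p)),
                duration_weeks=int(rng.integers(4, 53)),
            ))
    return experiments


def _round_robin_sizes(n_experiments: int, n_sets: int) -> tuple[int, ...]:
    sizes = [1] * n_sets
    for i in range(n_experiments - n_sets):
        sizes[i % n_sets] += 1
    return tuple(sizes)


def simulate_probe_level(truth: TruthTable, probes_per_gene: int = 11,
                         detect_fraction: float = 0.9, seed: int = 0,
                         shift: float = 1.0, n_probesets: int | None = None,
                         ) -> pd.DataFrame:
    """Emit perfect-match / mismatch probe intensity pairs per probe set.

    A ``detect_fraction`` of probe sets have PM intensities stochastically
    dominating MM (log2 shift of ``shift``); the rest draw PM and MM from
    the same background distribution.  Returns a long table with columns
    ``probeset_id``, ``gene``, ``probe``, ``pm``, ``mm``, ``detected_truth``.
    """
    if probes_per_gene < 5:
        raise ValueError("probes_per_gene must be >= 5")
    if not 0.0 <= detect_fraction <= 1.0:
        raise ValueError("detect_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = truth.human.index if n_probesets is None else truth.human.index[:n_probesets]
    n_detect = int(round(detect_fraction * len(genes)))
    detected = np.zeros(len(genes), bool)
    detected[rng.choice(len(genes), size=n_detect, replace=False)] = True

    rows = []
    for gi, gene in enumerate(genes):
        mm_log = rng.normal(6.0, 0.8, probes_per_gene)
        if detected[gi]:
            pm_log = mm_log + shift + rng.normal(0.0, 0.3, probes_per_gene)
        else:
            pm_log = rng.normal(6.0, 0.8, probes_per_gene)
        for p in range(probes_per_gene):
            rows.append({"probeset_id": f"{gene}_at", "gene": gene, "probe": p + 1,
                         "pm": float(2.0 ** pm_log[p]), "mm": float(2.0 ** mm_log[p]),
                         "detected_truth": bool(detected[gi])})
    return pd.DataFrame(rows)


def simulate_ortholog_map(genes: Sequence[str], coverage: float = 0.9,
                          seed: int = 0) -> pd.DataFrame:
    """One-to-one mouse-to-human symbol map with a fraction of genes unmapped.

    Human symbols follow the upper-case orthography convention.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    genes = pd.Index(genes)
    n_keep = int(round(coverage * len(genes)))
    keep = np.sort(rng.choice(len(genes), size=n_keep, replace=False))
    mouse = genes[keep]
    return pd.DataFrame({"mouse_symbol": mouse,
                         "human_symbol": [g.upper() for g in mouse]})
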