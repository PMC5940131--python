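"""End-to-end pipeline orchestration with a YAML configuration.

The pipeline runs simulate -> preprocess -> de -> interaction -> dominance ->
shared -> meta -> xspecies, writing every intermediate as TSV under the
output directory together with a JSON run manifest (config hash, seed,
package versions, per-stage gene/sample counts).  Stages communicate only
through these files, so individual stages can be re-run from a populated
output directory, and reruns with an identical configuration reproduce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import (ExpressionStudy, PairedExperiment,
                         experiment_manifest, read_tsv, write_tsv)
from . import cross_species, diffexpr, global_structure, human_meta
from . import preprocess, shared_response, simulate

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "de", "interaction", "dominance",
          "shared", "meta", "xspecies")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``mouse``/``human`` carry keyword overrides for the simulator dataclasses
    (:class:`~crstrains.simulate.StudyDesign` /
    :class:`~crstrains.simulate.MouseEffectModel` /
    :class:`~crstrains.simulate.HumanMetaConfig`).
    """

    seed: int
    out_dir: str = "results"
    design: dict = field(default_factory=dict)
    mouse_effects: dict = field(default_factory=dict)
    human: dict = field(default_factory=dict)
    ortholog_coverage: float = 0.9
    reference_tissue: str | None = None
    alpha: float = 0.05
    q_max: float = 0.10
    fc_up: float = 1.50
    fc_down: float = 0.67
    detect_fraction: float = 1.0 / 3.0
    min_experiments: int = 6
    interaction_fdr: float = 0.15
    shared_permutations: int = 1000
    gsea_permutations: int = 1000
    top_n: int = 100
    plots: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory (stochastic stages present)")
        checks = {
            "alpha": (self.alpha, 0.0, 1.0),
            "q_max": (self.q_max, 0.0, 1.0),
            "detect_fraction": (self.detect_fraction, 0.0, 1.0),
            "interaction_fdr": (self.interaction_fdr, 0.0, 1.0),
            "ortholog_coverage": (self.ortholog_coverage, 0.0, 1.0),
        }
        for name, (value, lo, hi) in checks.items():
            if not lo < value <= hi:
                raise ValueError(f"{name} must lie in ({lo}, {hi}], got {value}")
        if self.fc_up <= 1.0:
            raise ValueError("fc_up must exceed 1")
        if not 0.0 < self.fc_down < 1.0:
            raise ValueError("fc_down must lie in (0, 1)")
        if self.shared_permutations < 100 or self.gsea_permutations < 100:
            raise ValueError("permutation counts must be >= 100")
        # validate simulator overrides eagerly so nothing is written on error
        self.study_design()
        self.effect_model()
        self.human_config()

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("configuration must provide a seed")
        return cls(**raw)

    def study_design(self) -> simulate.StudyDesign:
        kwargs = dict(self.design)
        for key in ("strains", "tissues", "diets"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return simulate.StudyDesign(**kwargs)

    def effect_model(self) -> simulate.MouseEffectModel:
        kwargs = dict(self.mouse_effects)
        if kwargs.get("interaction_strains") is not None:
            kwargs["interaction_strains"] = tuple(kwargs["interaction_strains"])
        return simulate.MouseEffectModel(**kwargs)

    def human_config(self) -> simulate.HumanMetaConfig:
        kwargs = dict(self.human)
        for key in ("subjects_range", "baseline_set_sizes"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(kwargs[key])
        return simulate.HumanMetaConfig(**kwargs)

    def canonical(self) -> dict:
        """Scientific configuration only: output location and plot toggles do
        not influence results and are excluded, so runs into different
        directories remain byte-identical."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        d.pop("plots")
        return json.loads(json.dumps(d, sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed below 2**31."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)


def _comment(cfg: PipelineConfig, stage: str) -> str:
    return f"crstrains {stage} config={cfg.config_hash()} seed={cfg.seed}"


# --------------------------------------------------------------------------
# stage implementations; each reads its inputs from out_dir and writes there

def _stage_simulate(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    design = cfg.study_design()
    study, truth = simulate.simulate_mouse_study(design, cfg.effect_model(),
                                                 cfg.stage_seed("simulate"))
    omap = simulate.simulate_ortholog_map(study.genes, cfg.ortholog_coverage,
                                          cfg.stage_seed("orthologs"))
    experiments = simulate.simulate_human_experiments(
        cfg.human_config(), truth, cfg.stage_seed("human"),
        reference_tissue=cfg.reference_tissue or design.tissues[0],
        ortholog_map=omap)
    comment = _comment(cfg, "simulate")
    study.write(out, "study", comment)
    truth.write(out, comment)
    write_tsv(omap, out / "ortholog_map.tsv", comment=comment, index_label="row")
    for exp in experiments:
        exp.write(out / "human", comment)
    write_tsv(experiment_manifest(experiments), out / "human" / "manifest.tsv",
              comment=comment)
    manifest["stages"]["simulate"] = {
        "n_samples": study.n_samples,
        "n_genes": study.n_genes,
        "n_qc_fail": int((study.samples["qc_flag"] == "fail").sum()),
        "n_human_experiments": len(experiments),
        "n_baseline_sets": len({e.baseline_set_id for e in experiments}),
        "n_orthologs": len(omap),
    }


def _load_study(out: Path, stem: str) -> ExpressionStudy:
    path = out / f"{stem}_matrix.tsv"
    if not path.exists():
        raise FileNotFoundError(f"missing pipeline input: {path}")
    return ExpressionStudy.read(out, stem)


def _stage_preprocess(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    study = _load_study(out, "study")
    filtered = preprocess.exclude_flagged_samples(study)
    filtered.write(out, "study_qc", _comment(cfg, "preprocess"))
    manifest["stages"]["preprocess"] = {
        "n_samples_in": study.n_samples,
        "n_samples_out": filtered.n_samples,
        "n_removed": study.n_samples - filtered.n_samples,
    }


def _per_tissue_strains(study: ExpressionStudy):
    for tissue in sorted(study.samples["tissue"].unique()):
        yield tissue, study.tissue(tissue)


def _stage_de(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    study = _load_study(out, "study_qc")
    comment = _comment(cfg, "de")
    counts: dict[str, dict[str, int]] = {}
    genes_used: dict[str, dict[str, int]] = {}
    for tissue, sub in _per_tissue_strains(study):
        counts[tissue] = {}
        genes_used[tissue] = {}
        for strain in sorted(sub.samples["strain"].unique()):
            ids = sub.samples.index[sub.samples["strain"] == strain]
            cell = sub.subset_samples(ids)
            genes = preprocess.expression_filter(cell.detection, ids,
                                                 cfg.detect_fraction)
            fit = diffexpr.cr_contrast(cell.matrix.loc[genes],
                                       cell.samples["diet"],
                                       cfg.q_max, cfg.fc_up, cfg.fc_down)
            write_tsv(fit, out / "de" / f"{tissue}_{strain}.tsv",
                      comment=comment, index_label="gene")
            counts[tissue][strain] = int(fit["deg"].sum())
            genes_used[tissue][strain] = len(genes)
    manifest["stages"]["de"] = {"deg_counts": counts, "genes_tested": genes_used}


def _stage_interaction(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    study = _load_study(out, "study_qc")
    comment = _comment(cfg, "interaction")
    counts: dict[str, dict[str, dict[str, int]]] = {}
    for tissue, sub in _per_tissue_strains(study):
        # detectability rule: a third of all samples for the tissue
        genes = preprocess.expression_filter(sub.detection, sub.matrix.columns,
                                             cfg.detect_fraction)
        counts[tissue] = {}
        for strain in sorted(sub.samples["strain"].unique()):
            fit = diffexpr.interaction_scan(sub.matrix.loc[genes],
                                            sub.samples["strain"],
                                            sub.samples["diet"], strain,
                                            cfg.q_max, cfg.fc_up, cfg.fc_down)
            write_tsv(fit, out / "interaction" / f"{tissue}_{strain}.tsv",
                      comment=comment, index_label="gene")
            counts[tissue][strain] = {
                "fdr10": int((fit["fdr"] < cfg.q_max).sum()),
                "fdr15": int((fit["fdr"] < cfg.interaction_fdr).sum()),
            }
    manifest["stages"]["interaction"] = {"significant": counts}


def _stage_dominance(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    study = _load_study(out, "study_qc")
    comment = _comment(cfg, "dominance")
    summary: dict[str, dict[str, float]] = {}
    for tissue, sub in _per_tissue_strains(study):
        genes = preprocess.expression_filter(sub.detection, sub.matrix.columns,
                                             cfg.detect_fraction)
        dom = global_structure.factor_dominance(sub.matrix.loc[genes],
                                                sub.samples["strain"],
                                                sub.samples["diet"])
        write_tsv(dom.per_gene, out / "dominance" / f"{tissue}.tsv",
                  comment=comment, index_label="gene")
        vec = global_structure.pc_response_vectors(sub.matrix.loc[genes],
                                                   sub.samples["strain"],
                                                   sub.samples["diet"])
        write_tsv(vec.arrows, out / "dominance" / f"{tissue}_vectors.tsv",
                  comment=comment)
        summary[tissue] = {
            "percent_strain_dominant": dom.percent_strain_dominant,
            "percent_diet_dominant": dom.percent_diet_dominant,
            "pc1_var": float(vec.explained_variance[0]),
            "pc2_var": float(vec.explained_variance[1]),
        }
    manifest["stages"]["dominance"] = summary


def _load_fit_tables(out: Path, tissue: str) -> dict[str, pd.DataFrame]:
    tables = {}
    for path in sorted((out / "de").glob(f"{tissue}_*.tsv")):
        strain = path.stem.removeprefix(f"{tissue}_")
        tables[strain] = read_tsv(path)
    if not tables:
        raise FileNotFoundError(f"no DE tables for tissue {tissue!r} under {out/'de'}")
    return tables


def _stage_shared(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    study = _load_study(out, "study_qc")
    comment = _comment(cfg, "shared")
    summary: dict[str, Any] = {}
    for tissue in sorted(study.samples["tissue"].unique()):
        tables = _load_fit_tables(out, tissue)
        null = shared_response.shared_null(tables, cfg.alpha,
                                           cfg.shared_permutations,
                                           cfg.stage_seed(f"shared:{tissue}"))
        write_tsv(null.table, out / "shared" / f"{tissue}_counts.tsv",
                  comment=comment, index_label="k")
        corr = global_structure.fc_correlation_matrix(tables)
        write_tsv(corr, out / "shared" / f"{tissue}_corr.tsv",
                  comment=comment, index_label="strain")
        cluster = global_structure.strain_cluster(corr)
        (out / "shared" / f"{tissue}.nwk").write_text(cluster.newick + "\n")
        k_all = null.n_strains
        summary[tissue] = {
            "all_strain_concordant": int(null.table.loc[k_all, "observed"]),
            "p_perm_all_strains": float(null.table.loc[k_all, "p_perm"]),
            "discordant": null.discordant,
        }
    manifest["stages"]["shared"] = summary


def _load_experiments(out: Path) -> list[PairedExperiment]:
    mpath = out / "human" / "manifest.tsv"
    if not mpath.exists():
        raise FileNotFoundError(f"missing pipeline input: {mpath}")
    man = read_tsv(mpath)
    experiments = []
    for eid, row in man.iterrows():
        experiments.append(PairedExperiment(
            experiment_id=str(eid),
            baseline=read_tsv(out / "human" / f"{eid}_baseline.tsv"),
            post=read_tsv(out / "human" / f"{eid}_post.tsv"),
            baseline_set_id=str(row["baseline_set_id"]),
            sex=str(row["sex"]),
            duration_weeks=int(row["duration_weeks"]),
        ))
    return experiments


def _stage_meta(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    experiments = _load_experiments(out)
    sig = human_meta.meta_signature(experiments,
                                    min_experiments=cfg.min_experiments)
    write_tsv(sig.table, out / "meta_signature.tsv",
              comment=_comment(cfg, "meta"), index_label="gene")
    manifest["stages"]["meta"] = {
        "n_experiments_in": sig.n_input_experiments,
        "n_experiments_retained": len(sig.retained_experiments),
        "retained": sig.retained_experiments,
        "n_genes_union": sig.n_genes_union,
        "n_genes_included": sig.n_genes_included,
        "n_significant_fdr10": int((sig.table["fdr"] < cfg.q_max).sum()),
    }


def _stage_xspecies(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    study = _load_study(out, "study_qc")
    tissue = cfg.reference_tissue or sorted(study.samples["tissue"].unique())[0]
    mouse_fits = _load_fit_tables(out, tissue)
    omap = read_tsv(out / "ortholog_map.tsv")
    meta_table = read_tsv(out / "meta_signature.tsv")
    experiments = _load_experiments(out)
    comment = _comment(cfg, "xspecies")

    human_fcs = {}
    for exp in experiments:
        keep = human_meta.low_expression_filter(exp)
        diffs = human_meta.paired_log2_differences(exp).loc[keep]
        human_fcs[exp.experiment_id] = diffs.mean(axis=1)

    grid = cross_species.species_correlations(mouse_fits, human_fcs, omap,
                                              meta_fc=meta_table["meta_log2fc"])
    write_tsv(grid.rho, out / "xspecies" / "grid.tsv", comment=comment,
              index_label="strain")
    write_tsv(grid.strain_summary.assign(rho_vs_meta=grid.meta_rho),
              out / "xspecies" / "strain_summary.tsv", comment=comment,
              index_label="strain")

    # enrichment of each strain's top-N genes inside the human meta-ranking
    ranked = meta_table.assign(_gene=meta_table.index).sort_values(
        ["meta_log2fc", "p", "_gene"], ascending=[False, True, True])
    ranking_univ = ranked.index
    mapped = omap.set_index("mouse_symbol")["human_symbol"]
    rows = []
    for strain, fit in mouse_fits.items():
        for direction in ("up", "down"):
            n_top = min(cfg.top_n, len(fit))
            top = cross_species.top_n_genes(fit, n_top, direction)
            top_h = [mapped[g] for g in top
                     if g in mapped.index and mapped[g] in ranking_univ]
            if len(top_h) < 5:
                log.warning("top-%s set for %s too small after mapping", direction, strain)
                continue
            res = cross_species.cumulative_overlap_gsea(
                ranking_univ, top_h, cfg.gsea_permutations,
                cfg.stage_seed(f"gsea:{strain}:{direction}"))
            rows.append({"strain": strain, "direction": direction,
                         "n_genes": len(top_h), "statistic": res.statistic,
                         "p": res.p})
    gsea = pd.DataFrame(rows)
    write_tsv(gsea, out / "xspecies" / "gsea_running_overlap.tsv",
              comment=comment + " statistic=running-overlap (package definition)",
              index_label="row")

    # median human FC of genes consistently altered across mouse strains
    strains = list(mouse_fits)
    med_rows = []
    for direction, sign in (("up", 1.0), ("down", -1.0)):
        universe = mouse_fits[strains[0]].index
        for s in strains[1:]:
            universe = universe.intersection(mouse_fits[s].index)
        consistent = universe
        for s in strains:
            fit = mouse_fits[s].loc[consistent]
            consistent = consistent[(fit["p"] < cfg.alpha)
                                    & (np.sign(fit["log2fc"]) == sign)]
        consistent_h = pd.Index([mapped[g] for g in consistent
                                 if g in mapped.index]).intersection(meta_table.index)
        if len(consistent_h) < 5:
            med_rows.append({"direction": direction, "n_genes": len(consistent_h),
                             "median_fc": np.nan, "p": np.nan})
            continue
        res = cross_species.median_fc_test(meta_table.loc[consistent_h, "meta_fc"])
        med_rows.append({"direction": direction, "n_genes": res.n,
                         "median_fc": res.median_fc, "p": res.p})
    medians = pd.DataFrame(med_rows).set_index("direction")
    write_tsv(medians, out / "xspecies" / "median_fc_tests.tsv", comment=comment)

    mean_rho = grid.rho.mean(axis=1)
    summary = {
        "reference_tissue": tissue,
        "grid_mean_rho": {s: (None if np.isnan(v) else round(float(v), 6))
                          for s, v in mean_rho.items()},
        "rho_vs_meta": {s: (None if pd.isna(v) else round(float(v), 6))
                        for s, v in grid.meta_rho.items()},
    }
    (out / "xspecies" / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    manifest["stages"]["xspecies"] = summary

    if cfg.plots:
        from . import plots
        plots.plot_correlation_grid(grid.rho, out / "plots" / "xspecies_grid.png")


_STAGE_FUNCS: dict[str, Callable[[PipelineConfig, Path, dict], None]] = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "de": _stage_de,
    "interaction": _stage_interaction,
    "dominance": _stage_dominance,
    "shared": _stage_shared,
    "meta": _stage_meta,
    "xspecies": _stage_xspecies,
}


def run_pipeline(config: PipelineConfig, stages=None) -> dict:
    """Run the requested stages (default: all) and return the run manifest.

    The manifest is also written to ``<out_dir>/manifest.json``; on a stage
    failure, outputs of completed stages are retained and an error manifest
    is written before the exception propagates.
    """
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages.sort(key=STAGES.index)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest: dict = {"config": config.canonical(),
                      "config_hash": config.config_hash(),
                      "seed": config.seed,
                      "versions": _versions(),
                      "stages": {}}
    if manifest_path.exists():
        try:
            previous = json.loads(manifest_path.read_text())
            if previous.get("config_hash") == manifest["config_hash"]:
                manifest["stages"] = previous.get("stages", {})
        except (json.JSONDecodeError, OSError):
            pass

    if config.plots:
        from . import plots  # noqa: F401  (fail early if matplotlib broken)

    for stage in stages:
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](config, out, manifest)
        except Exception as err:
            manifest["error"] = {"stage": stage, "message": str(err)}
            _write_manifest(manifest_path, manifest)
            raise
        log.info("stage %-10s done in %.1fs", stage, time.perf_counter() - t0)

    if config.plots and "dominance" in stages:
        from . import plots
        study = _load_study(out, "study_qc")
        tissue = config.reference_tissue or sorted(study.samples["tissue"].unique())[0]
        sub = study.tissue(tissue)
        vec = global_structure.pc_response_vectors(sub.matrix, sub.samples["strain"],
                                                   sub.samples["diet"])
        plots.plot_response_vectors(vec, out / "plots" / f"{tissue}_vectors.png")

    _write_manifest(manifest_path, manifest)
    return manifest


def _versions() -> dict:
    import scipy
    return {"crstrains": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__}


def _write_manifest(path: Path, manifest: dict) -> None:
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
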