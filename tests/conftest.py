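import numpy as np
import pandas as pd
import pytest

import crstrains as cs


@pytest.fixture(scope="session")
def small_sim():
    """A 3-strain, single-tissue simulated study with planted effects."""
    design = cs.StudyDesign(strains=("A", "B", "C"), tissues=("eWAT",),
                            replicates_per_cell=6, n_genes=400)
    effects = cs.MouseEffectModel(n_qc_fail=4, interaction_strains=("A",))
    study, truth = cs.simulate_mouse_study(design, effects, seed=101)
    return design, effects, study, truth


@pytest.fixture(scope="session")
def fit_tables(small_sim):
    """Per-strain CR-vs-CTL fit tables for the small simulated study."""
    _, _, study, _ = small_sim
    study = cs.exclude_flagged_samples(study)
    sub = study.tissue("eWAT")
    tables = {}
    for strain in ("A", "B", "C"):
        ids = sub.samples.index[sub.samples["strain"] == strain]
        cell = sub.subset_samples(ids)
        tables[strain] = cs.cr_contrast(cell.matrix, cell.samples["diet"])
    return tables


def make_fit_table(p, log2fc, genes=None) -> pd.DataFrame:
    """Minimal gene fit table for operations that consume one."""
    p = np.asarray(p, dtype=float)
    log2fc = np.asarray(log2fc, dtype=float)
    if genes is None:
        genes = [f"g{i:04d}" for i in range(p.size)]
    table = pd.DataFrame({"log2fc": log2fc, "fc": np.exp2(log2fc), "p": p},
                         index=pd.Index(genes, name="gene"))
    table["fdr"] = cs.bh_adjust(table["p"])
    return table
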