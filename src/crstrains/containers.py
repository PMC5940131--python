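"""Shared in-memory containers and TSV round-trip helpers.

All expression values are log2-scale throughout the package; linear
fold-changes (FC = CR/CTL) are only formed by exponentiation at reporting
boundaries.  Matrices are pandas DataFrames with genes as rows and samples
(or subjects) as columns; per-sample metadata travels alongside the matrix
in an :class:`ExpressionStudy`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ExpressionStudy",
    "TruthTable",
    "PairedExperiment",
    "read_tsv",
    "write_tsv",
]


def write_tsv(df: pd.DataFrame, path: str | Path, *, comment: str | None = None,
              index_label: str | None = None) -> None:
    """Write a DataFrame as TSV, optionally with a leading ``#`` comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = io.StringIO()
    if comment:
        buf.write(f"# {comment}\n")
    df.to_csv(buf, sep="\t", index_label=index_label)
    path.write_text(buf.getvalue())


def read_tsv(path: str | Path, *, index_col: int | str | None = 0) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv`, skipping ``#`` comment lines."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


SAMPLE_META_COLUMNS = ("strain", "diet", "tissue", "qc_flag")


@dataclass
class ExpressionStudy:
    """A log2 gene-by-sample expression matrix with per-sample metadata.

    Parameters
    ----------
    matrix
        genes x samples log2 expression, gene symbols as index.
    samples
        Per-sample metadata indexed by sample id with columns
        ``strain``, ``diet``, ``tissue``, ``qc_flag`` (``pass``/``fail``).
    detection
        Optional boolean genes x samples matrix of above-background
        detection calls, aligned with ``matrix``.
    seed
        Seed recorded by the simulator (``None`` for observed data).
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    detection: pd.DataFrame | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.matrix.columns.equals(self.samples.index):
            raise ValueError("matrix columns and sample metadata rows must match one-to-one")
        if self.matrix.index.has_duplicates:
            dups = self.matrix.index[self.matrix.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups[:5]}")
        if self.matrix.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        missing = [c for c in SAMPLE_META_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample metadata lacks columns: {missing}")
        if self.detection is not None:
            if not (self.detection.index.equals(self.matrix.index)
                    and self.detection.columns.equals(self.matrix.columns)):
                raise ValueError("detection matrix must align with the expression matrix")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionStudy":
        ids = pd.Index(sample_ids)
        unknown = ids.difference(self.samples.index)
        if len(unknown):
            raise KeyError(f"unknown sample ids: {list(unknown)[:5]}")
        det = self.detection[ids] if self.detection is not None else None
        return ExpressionStudy(self.matrix[ids], self.samples.loc[ids], det, self.seed)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionStudy":
        idx = pd.Index(genes)
        det = self.detection.loc[idx] if self.detection is not None else None
        return ExpressionStudy(self.matrix.loc[idx], self.samples.loc[:], det, self.seed)

    def tissue(self, tissue: str) -> "ExpressionStudy":
        ids = self.samples.index[self.samples["tissue"] == tissue]
        if not len(ids):
            raise KeyError(f"no samples for tissue {tissue!r}")
        return self.subset_samples(ids)

    # -- TSV round trip ---------------------------------------------------
    def write(self, directory: str | Path, stem: str = "study",
              comment: str | None = None) -> None:
        directory = Path(directory)
        write_tsv(self.matrix, directory / f"{stem}_matrix.tsv",
                  comment=comment, index_label="gene")
        write_tsv(self.samples, directory / f"{stem}_samples.tsv",
                  comment=comment, index_label="sample_id")
        if self.detection is not None:
            write_tsv(self.detection.astype(int), directory / f"{stem}_detection.tsv",
                      comment=comment, index_label="gene")

    @classmethod
    def read(cls, directory: str | Path, stem: str = "study") -> "ExpressionStudy":
        directory = Path(directory)
        matrix = read_tsv(directory / f"{stem}_matrix.tsv")
        samples = read_tsv(directory / f"{stem}_samples.tsv")
        det_path = directory / f"{stem}_detection.tsv"
        detection = read_tsv(det_path).astype(bool) if det_path.exists() else None
        return cls(matrix, samples, detection)


TRUTH_FLAGS = ("shared", "strain_specific", "interaction")


@dataclass
class TruthTable:
    """Ground truth of a simulated study.

    ``mouse`` is a long-format table with one row per (gene, tissue, strain):
    columns ``gene``, ``tissue``, ``strain``, ``true_log2fc`` plus boolean
    flags ``shared``, ``strain_specific``, ``interaction`` (constant across
    strains within a gene/tissue).  ``human`` is the per-gene true human
    log2 CR effect, indexed by mouse gene symbol.
    """

    mouse: pd.DataFrame
    human: pd.Series

    def __post_init__(self) -> None:
        needed = {"gene", "tissue", "strain", "true_log2fc", *TRUTH_FLAGS}
        missing = needed.difference(self.mouse.columns)
        if missing:
            raise ValueError(f"truth table lacks columns: {sorted(missing)}")

    def effects(self, tissue: str) -> pd.DataFrame:
        """True log2 CR effect, genes x strains, for one tissue."""
        sub = self.mouse[self.mouse["tissue"] == tissue]
        return sub.pivot(index="gene", columns="strain", values="true_log2fc")

    def flags(self, tissue: str) -> pd.DataFrame:
        """Per-gene boolean flags (shared / strain_specific / interaction)."""
        sub = self.mouse[self.mouse["tissue"] == tissue]
        return sub.drop_duplicates("gene").set_index("gene")[list(TRUTH_FLAGS)]

    def write(self, directory: str | Path, comment: str | None = None) -> None:
        directory = Path(directory)
        write_tsv(self.mouse, directory / "truth_mouse.tsv", comment=comment,
                  index_label="row")
        write_tsv(self.human.rename("true_log2fc").to_frame(),
                  directory / "truth_human.tsv", comment=comment, index_label="gene")

    @classmethod
    def read(cls, directory: str | Path) -> "TruthTable":
        directory = Path(directory)
        mouse = read_tsv(directory / "truth_mouse.tsv")
        for flag in TRUTH_FLAGS:
            mouse[flag] = mouse[flag].astype(bool)
        human = read_tsv(directory / "truth_human.tsv")["true_log2fc"]
        return cls(mouse, human)


@dataclass
class PairedExperiment:
    """One paired human experiment: baseline and post-intervention matrices.

    Baseline and post share identical gene and subject indexing; experiments
    drawn from the same ``baseline_set_id`` are statistically dependent
    because they reuse the same pre-intervention samples.
    """

    experiment_id: str
    baseline: pd.DataFrame   # genes x subjects, log2
    post: pd.DataFrame       # same shape, subject-aligned
    baseline_set_id: str
    sex: str = "unknown"
    duration_weeks: int | None = None

    def __post_init__(self) -> None:
        if not (self.baseline.index.equals(self.post.index)
                and self.baseline.columns.equals(self.post.columns)):
            raise ValueError(
                f"experiment {self.experiment_id}: baseline and post matrices "
                "must share gene and subject indexing")
        if self.baseline.shape[1] < 2:
            raise ValueError(f"experiment {self.experiment_id}: needs >= 2 subjects")

    @property
    def n_subjects(self) -> int:
        return self.baseline.shape[1]

    @property
    def genes(self) -> pd.Index:
        return self.baseline.index

    def write(self, directory: str | Path, comment: str | None = None) -> None:
        directory = Path(directory)
        write_tsv(self.baseline, directory / f"{self.experiment_id}_baseline.tsv",
                  comment=comment, index_label="gene")
        write_tsv(self.post, directory / f"{self.experiment_id}_post.tsv",
                  comment=comment, index_label="gene")


def experiment_manifest(experiments: Iterable[PairedExperiment]) -> pd.DataFrame:
    """Manifest table (one row per experiment) for a list of paired experiments."""
    rows = [
        {
            "experiment_id": e.experiment_id,
            "baseline_set_id": e.baseline_set_id,
            "n_subjects": e.n_subjects,
            "sex": e.sex,
            "duration_weeks": e.duration_weeks,
        }
        for e in experiments
    ]
    return pd.DataFrame(rows).set_index("experiment_id")
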