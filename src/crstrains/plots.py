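"""Basic diagnostic plots (PC response vectors, correlation grids)."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .global_structure import ResponseVectorSet

__all__ = ["plot_response_vectors", "plot_correlation_grid"]


def plot_response_vectors(vectors: ResponseVectorSet, path: str | Path) -> None:
    """Arrows from the CTL bivariate mean to the CR bivariate mean per strain."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 5))
    for strain, row in vectors.arrows.iterrows():
        ax.annotate("", xy=(row["cr_pc1"], row["cr_pc2"]),
                    xytext=(row["ctl_pc1"], row["ctl_pc2"]),
                    arrowprops=dict(arrowstyle="->", lw=1.5))
        ax.text(row["cr_pc1"], row["cr_pc2"], str(strain), fontsize=8)
    ev = vectors.explained_variance
    ax.set_xlabel(f"PC1 ({100 * ev[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * ev[1]:.1f}%)")
    ax.set_title("CR response vectors")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_correlation_grid(rho, path: str | Path) -> None:
    """Heatmap of the strains x experiments Spearman grid."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * rho.shape[1]), 3))
    im = ax.imshow(rho.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
    ax.set_yticks(range(rho.shape[0]), rho.index)
    ax.set_xticks(range(rho.shape[1]), rho.columns, rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
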