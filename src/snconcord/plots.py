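"""Optional figures (QC violins, embedding scatter). Kept minimal."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def qc_violin(metrics: pd.DataFrame, path: str | Path) -> Path:
    """Violin plots of UMI, detected genes and mito % per droplet."""
    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    for ax, col, label in zip(
        axes,
        ["total_umi", "n_genes_detected", "mito_fraction"],
        ["UMI", "genes", "mito %"],
    ):
        vals = metrics[col].to_numpy(dtype=float)
        if col == "mito_fraction":
            vals = 100 * vals
        else:
            vals = np.log10(vals + 1)
            label = f"log10 {label}"
        ax.violinplot(vals, showmedians=True)
        ax.set_ylabel(label)
        ax.set_xticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def embedding_scatter(coords: np.ndarray, labels, path: str | Path) -> Path:
    """2-D scatter of an embedding coloured by label."""
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    for lab in pd.unique(labels):
        sel = labels == lab
        ax.scatter(coords[sel, 0], coords[sel, 1], s=6, label=str(lab), alpha=0.7)
    ax.legend(markerscale=2, fontsize=7)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
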