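"""Core in-memory containers shared across the pipeline.

The central object is :class:`DropletMatrix`: a sparse gene x droplet matrix of
UMI counts together with per-gene annotation and droplet barcodes.  Genes are
rows and droplets are columns everywhere in memory (matching the on-disk
Matrix Market convention of the 10x triplet, which is 1-based on disk).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: Required columns of a gene-annotation table.
GENE_ANNOTATION_COLUMNS = ("gene_id", "symbol", "species", "biotype", "is_mito")


def validate_gene_annotations(genes: pd.DataFrame) -> None:
    """Raise ``ValueError`` naming the first missing annotation column."""
    for col in GENE_ANNOTATION_COLUMNS:
        if col not in genes.columns:
            raise ValueError(f"gene annotation table is missing column {col!r}")


@dataclass
class DropletMatrix:
    """Sparse non-negative integer UMI counts (genes x droplets).

    Parameters
    ----------
    counts
        ``scipy.sparse`` matrix of shape ``(n_genes, n_droplets)`` with
        non-negative integer entries.
    genes
        Gene annotation table with columns ``gene_id``, ``symbol``,
        ``species`` ("human"/"mouse"), ``biotype`` ("protein_coding",
        "lncRNA", "mito") and boolean ``is_mito``.
    barcodes
        One barcode string per droplet (column).
    modality
        One of ``whole_cell``, ``nucleus``, ``graft_nucleus`` (free-form
        strings are allowed for externally loaded data).
    """

    counts: sp.spmatrix
    genes: pd.DataFrame
    barcodes: np.ndarray
    modality: str = "unknown"

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        validate_gene_annotations(self.genes)
        ng, nd = self.counts.shape
        if len(self.genes) != ng:
            raise ValueError(
                f"gene table has {len(self.genes)} rows but matrix has {ng} gene rows"
            )
        if len(self.barcodes) != nd:
            raise ValueError(
                f"{len(self.barcodes)} barcodes but matrix has {nd} droplet columns"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        self.genes = self.genes.reset_index(drop=True)

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_droplets(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.genes["gene_id"])

    # -- subsetting ------------------------------------------------------
    def subset_droplets(self, sel) -> "DropletMatrix":
        """Return a new matrix restricted to selected droplet columns."""
        sel = np.asarray(sel)
        if sel.dtype == bool:
            sel = np.flatnonzero(sel)
        return replace(
            self,
            counts=self.counts[:, sel],
            genes=self.genes.copy(),
            barcodes=self.barcodes[sel],
        )

    def subset_genes(self, sel) -> "DropletMatrix":
        """Return a new matrix restricted to selected gene rows."""
        sel = np.asarray(sel)
        if sel.dtype == bool:
            sel = np.flatnonzero(sel)
        return replace(
            self,
            counts=self.counts[sel, :],
            genes=self.genes.iloc[sel].reset_index(drop=True),
            barcodes=self.barcodes.copy(),
        )

    def total_umi(self) -> np.ndarray:
        """Per-droplet total UMI (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()
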