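"""Concordance statistics between two droplet datasets.

The four comparisons made between a whole-cell and a nucleus dataset (or an
in vitro and an in vivo one):

* detected-gene-set overlap (a gene is detected with >= 1 UMI in >= 3
  droplets) — reported both as Jaccard and as percent of the smaller set;
* per-cell-type expression correlation: ordinary least squares of one
  dataset's mean ln counts per gene on the other's, reporting R^2 (the
  squared Pearson correlation) and its p value, for all type pairs;
* fractional overlap of the top-N genes per type (N = 100, 200, 500, 1000),
  ranking genes by per-type mean ln counts;
* detection-rate enrichment: genes detected in a significantly higher
  (> 1.5-fold) percentage of nuclei than cells, with the biotype breakdown
  of the enriched set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .datatypes import DropletMatrix

DEFAULT_TOP_N = (100, 200, 500, 1000)


@dataclass
class ConcordanceReport:
    """Assembled concordance statistics plus provenance."""

    gene_set_stats: Dict[str, float]
    correlations: pd.DataFrame
    top_overlap: pd.DataFrame
    enrichment: pd.DataFrame
    biotype_proportions: pd.Series
    provenance: Dict[str, object] = field(default_factory=dict)

    def to_dict(self) -> Dict[str, object]:
        return {
            "gene_set_stats": self.gene_set_stats,
            "correlations": self.correlations.to_dict(orient="records"),
            "top_overlap": self.top_overlap.to_dict(orient="records"),
            "n_enriched": int(self.enrichment["enriched"].sum()) if len(self.enrichment) else 0,
            "biotype_proportions": self.biotype_proportions.to_dict(),
            "provenance": self.provenance,
        }


def detected_gene_set(matrix: DropletMatrix, min_cells: int = 3) -> Set[str]:
    """Genes with >= 1 UMI in at least ``min_cells`` droplets."""
    n_cells = np.asarray((matrix.counts > 0).sum(axis=1)).ravel()
    ids = matrix.genes["gene_id"].to_numpy()
    return set(ids[n_cells >= min_cells])


def gene_set_overlap(set_a: Iterable[str], set_b: Iterable[str]) -> Dict[str, float]:
    """Sizes, intersection, Jaccard and percent-of-smaller-set overlap."""
    a, b = set(set_a), set(set_b)
    inter = len(a & b)
    union = len(a | b)
    smaller = min(len(a), len(b))
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_intersection": inter,
        "jaccard": inter / union if union else 0.0,
        "percent_of_smaller": 100.0 * inter / smaller if smaller else 0.0,
    }


def celltype_mean_profiles(
    ln_matrix: sp.spmatrix,
    cell_types: Sequence[str],
    gene_ids: Sequence[str],
    min_droplets: int = 10,
) -> Tuple[pd.DataFrame, Dict[str, bool]]:
    """Per-type mean ln expression per gene.

    Returns a genes x types DataFrame and a per-type flag marking types with
    fewer than ``min_droplets`` droplets; types with zero droplets are
    omitted with a warning.
    """
    ln = sp.csc_matrix(ln_matrix)
    cell_types = np.asarray(cell_types, dtype=object)
    if ln.shape[1] != len(cell_types):
        raise ValueError("one cell-type label per droplet required")
    cols: Dict[str, np.ndarray] = {}
    small: Dict[str, bool] = {}
    for t in pd.unique(cell_types):
        members = np.flatnonzero(cell_types == t)
        if len(members) == 0:  # pragma: no cover - unique() precludes it
            warnings.warn(f"type {t!r} has no droplets; omitted", stacklevel=2)
            continue
        cols[str(t)] = np.asarray(ln[:, members].mean(axis=1)).ravel()
        small[str(t)] = len(members) < min_droplets
    return pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id")), small


def profile_correlation(
    means_a: pd.DataFrame,
    means_b: pd.DataFrame,
    min_genes: int = 10,
) -> pd.DataFrame:
    """All-vs-all per-type-pair Pearson correlation on the shared gene space.

    Returns a tidy table with columns type_a, type_b, r, r2, p, n_genes,
    where r2 = r**2 and p is the two-sided test of r != 0 (equivalently the
    slope of the least-squares line of B on A).
    """
    shared = means_a.index.intersection(means_b.index)
    if len(shared) < min_genes:
        raise ValueError(f"only {len(shared)} shared genes (< {min_genes})")
    rows = []
    for ta in means_a.columns:
        x = means_a.loc[shared, ta].to_numpy()
        for tb in means_b.columns:
            y = means_b.loc[shared, tb].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                r, p = 0.0, 1.0
            else:
                r, p = stats.pearsonr(x, y)
            rows.append(
                {
                    "type_a": ta,
                    "type_b": tb,
                    "r": float(r),
                    "r2": float(r) ** 2,
                    "p": float(p),
                    "n_genes": len(shared),
                }
            )
    return pd.DataFrame(rows)


def _top_genes(means: pd.Series, n: int) -> Set[str]:
    """Top-n gene ids by mean (descending; ties broken by gene id)."""
    df = means.reset_index()
    df.columns = ["gene_id", "mean"]
    df = df.sort_values(["mean", "gene_id"], ascending=[False, True], kind="stable")
    return set(df["gene_id"].head(n))


def top_gene_overlap(
    means_a: pd.DataFrame,
    means_b: pd.DataFrame,
    n_list: Sequence[int] = DEFAULT_TOP_N,
    cross_types: bool = True,
) -> pd.DataFrame:
    """Fractional overlap of top-N gene lists per type (and type pair).

    Rankings are over the shared gene space; infeasible N (larger than the
    shared space) are skipped with a warning.  The matched-type rows have
    ``type_a == type_b``; cross-type rows mirror the full comparison grid.
    """
    shared = means_a.index.intersection(means_b.index)
    feasible = [n for n in n_list if n <= len(shared)]
    if len(feasible) < len(n_list):
        warnings.warn(
            f"shared gene space ({len(shared)}) smaller than max N; computing N={feasible}",
            stacklevel=2,
        )
    rows = []
    for ta in means_a.columns:
        bs = means_b.columns if cross_types else ([ta] if ta in means_b.columns else [])
        for tb in bs:
            for n in feasible:
                top_a = _top_genes(means_a.loc[shared, ta], n)
                top_b = _top_genes(means_b.loc[shared, tb], n)
                rows.append(
                    {
                        "type_a": ta,
                        "type_b": tb,
                        "n": n,
                        "overlap": len(top_a & top_b) / n,
                    }
                )
    return pd.DataFrame(rows)


def detection_rates(matrix: DropletMatrix) -> pd.DataFrame:
    """Per-gene detection: droplets with >= 1 UMI, as count and percentage."""
    if matrix.n_droplets == 0:
        raise ValueError("detection rates undefined for zero droplets")
    detected = np.asarray((matrix.counts > 0).sum(axis=1)).ravel().astype(int)
    return pd.DataFrame(
        {
            "gene_id": matrix.genes["gene_id"].to_numpy(),
            "n_detected": detected,
            "pct_detected": 100.0 * detected / matrix.n_droplets,
        }
    ).set_index("gene_id")


def _two_proportion_pvalues(
    k1: np.ndarray, n1: int, k2: np.ndarray, n2: int
) -> np.ndarray:
    """Two-sided pooled two-proportion z-test, vectorised over genes."""
    p1 = k1 / n1
    p2 = k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (p1 - p2) / se, 0.0)
    return 2.0 * stats.norm.sf(np.abs(z))


def detection_enrichment(
    rates_sn: pd.DataFrame,
    rates_sc: pd.DataFrame,
    n_droplets_sn: int,
    n_droplets_sc: int,
    annotations: pd.DataFrame,
    fold: float = 1.5,
    alpha: float = 0.05,
    method: str = "ztest",
) -> Tuple[pd.DataFrame, pd.Series]:
    """Genes detected at a significantly higher rate in nuclei than cells.

    ``rates_*`` are the tables from :func:`detection_rates` (they carry both
    the detection counts used for testing and the percentages).  A gene is
    enriched when its fold change (pct_sn / pct_sc; infinity when pct_sc is
    zero, flagged ``fold_undefined``) exceeds ``fold`` and its BH-adjusted
    two-proportion p value is <= ``alpha``.  Returns the per-gene table
    (sorted by fold change, with a ``rank_by_pct`` column giving the ordering
    by nuclear detection percentage) and the biotype proportions among
    enriched genes.
    """
    if not rates_sn.index.equals(rates_sc.index):
        shared = rates_sn.index.intersection(rates_sc.index)
        if len(shared) != len(rates_sn) or len(shared) != len(rates_sc):
            raise ValueError("gene spaces of the two rate tables differ")
        rates_sc = rates_sc.loc[rates_sn.index]
    k_sn = rates_sn["n_detected"].to_numpy()
    k_sc = rates_sc["n_detected"].to_numpy()
    pct_sn = 100.0 * k_sn / n_droplets_sn
    pct_sc = 100.0 * k_sc / n_droplets_sc

    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(pct_sc > 0, pct_sn / np.where(pct_sc > 0, pct_sc, 1.0), np.inf)
    fc = np.where((pct_sc == 0) & (pct_sn == 0), 0.0, fc)
    undefined = (pct_sc == 0) & (pct_sn > 0)

    if method == "ztest":
        p = _two_proportion_pvalues(k_sn, n_droplets_sn, k_sc, n_droplets_sc)
    elif method == "fisher":
        p = np.array(
            [
                stats.fisher_exact(
                    [[a, n_droplets_sn - a], [b, n_droplets_sc - b]]
                ).pvalue
                for a, b in zip(k_sn, k_sc)
            ]
        )
    else:
        raise ValueError(f"unknown test method {method!r}")
    q = stats.false_discovery_control(p, method="bh")

    anno = annotations.set_index("gene_id") if "gene_id" in annotations.columns else annotations
    biotype = anno.reindex(rates_sn.index)["biotype"].fillna("unknown")

    table = pd.DataFrame(
        {
            "gene_id": rates_sn.index,
            "pct_sn": pct_sn,
            "pct_sc": pct_sc,
            "fold_change": fc,
            "fold_undefined": undefined,
            "p": p,
            "q": q,
            "biotype": biotype.to_numpy(),
        }
    )
    table["enriched"] = (table["fold_change"] > fold) & (table["q"] <= alpha)
    table = table.sort_values(
        ["fold_change", "pct_sn", "gene_id"], ascending=[False, False, True], kind="stable"
    ).reset_index(drop=True)
    table["rank_by_pct"] = (
        table["pct_sn"].rank(method="first", ascending=False).astype(int)
    )

    enriched = table[table["enriched"]]
    if len(enriched):
        props = enriched["biotype"].value_counts(normalize=True).sort_index()
    else:
        props = pd.Series(dtype=float)
    return table, props


def compare_datasets(
    matrix_a: DropletMatrix,
    matrix_b: DropletMatrix,
    ln_a: sp.spmatrix,
    ln_b: sp.spmatrix,
    labels_a: Sequence[str],
    labels_b: Sequence[str],
    annotations: pd.DataFrame,
    min_cells: int = 3,
    fold: float = 1.5,
    alpha: float = 0.05,
    n_list: Sequence[int] = DEFAULT_TOP_N,
) -> ConcordanceReport:
    """Assemble the full concordance report for dataset A (e.g. nuclei)
    versus dataset B (e.g. whole cells)."""
    set_a = detected_gene_set(matrix_a, min_cells=min_cells)
    set_b = detected_gene_set(matrix_b, min_cells=min_cells)
    overlap = gene_set_overlap(set_a, set_b)

    means_a, _ = celltype_mean_profiles(ln_a, labels_a, matrix_a.genes["gene_id"])
    means_b, _ = celltype_mean_profiles(ln_b, labels_b, matrix_b.genes["gene_id"])
    shared_detected = pd.Index(sorted(set_a & set_b))
    means_a_det = means_a.loc[means_a.index.intersection(shared_detected)]
    means_b_det = means_b.loc[means_b.index.intersection(shared_detected)]
    correlations = profile_correlation(means_a_det, means_b_det)
    top = top_gene_overlap(means_a_det, means_b_det, n_list=n_list)

    rates_a = detection_rates(matrix_a)
    rates_b = detection_rates(matrix_b)
    shared = rates_a.index.intersection(rates_b.index)
    enrich, props = detection_enrichment(
        rates_a.loc[shared],
        rates_b.loc[shared],
        matrix_a.n_droplets,
        matrix_b.n_droplets,
        annotations,
        fold=fold,
        alpha=alpha,
    )
    return ConcordanceReport(
        gene_set_stats=overlap,
        correlations=correlations,
        top_overlap=top,
        enrichment=enrich,
        biotype_proportions=props,
        provenance={
            "modality_a": matrix_a.modality,
            "modality_b": matrix_b.modality,
            "min_cells": min_cells,
            "fold": fold,
            "alpha": alpha,
            "n_list": list(n_list),
        },
    )
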