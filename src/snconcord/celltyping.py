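"""Normalisation, clustering, reference-centroid annotation, marker genes.

Expression values are natural-log transformed: ln(1 + UMI).  Concordance
statistics downstream use the raw-count ln transform (no depth scaling);
clustering uses a depth-scaled variant (counts per 10k, then ln(1+x)) to
stabilise structure.  Clusters come from a k-nearest-neighbour graph and
modularity (Leiden) community detection on 25 principal components by
default; cluster ids are ordered by decreasing size.  Annotation assigns each
cluster the reference cell type whose ln-profile correlates best with the
cluster centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu, false_discovery_control
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from .datatypes import DropletMatrix
from .simgen import ReferenceProfiles


@dataclass
class AnalysisParams:
    """Clustering / annotation parameters."""

    n_pcs: int = 25
    k_neighbors: int = 15
    resolution: float = 1.0
    expressed_min_umi: int = 1
    annotation_min_correlation: float = 0.5
    marker_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pcs < 2:
            raise ValueError("n_pcs must be >= 2")
        if self.k_neighbors < 2:
            raise ValueError("k_neighbors must be >= 2")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")


def normalize_ln(matrix: DropletMatrix, depth_scale: bool = False) -> sp.csr_matrix:
    """ln(1 + count), genes x droplets.

    With ``depth_scale=True``, counts are first scaled to 10,000 per droplet
    (the clustering variant); without, raw UMI are transformed (the
    concordance variant).
    """
    counts = matrix.counts.tocsc().astype(float)
    if counts.nnz and counts.data.min() < 0:
        raise ValueError("counts must be non-negative")
    if depth_scale:
        total = np.asarray(counts.sum(axis=0)).ravel()
        scale = 1e4 / np.where(total > 0, total, 1)
        counts = counts @ sp.diags(scale)
    counts.data = np.log1p(counts.data)
    return counts.tocsr()


def reduce_and_cluster(ln_matrix: sp.spmatrix, params: AnalysisParams) -> np.ndarray:
    """PCA + kNN graph + Leiden communities on an ln matrix (genes x droplets).

    Top-2000 variable genes, standardised, projected to ``n_pcs`` components;
    cluster ids are relabelled by decreasing size (ties by smallest contained
    droplet index, i.e. barcode order).
    """
    n_droplets = ln_matrix.shape[1]
    if n_droplets < params.k_neighbors + 1:
        raise ValueError(
            f"need at least k_neighbors+1={params.k_neighbors + 1} droplets, got {n_droplets}"
        )
    X = np.asarray(sp.csr_matrix(ln_matrix).todense()).T  # droplets x genes
    var = X.var(axis=0)
    n_top = min(2000, X.shape[1])
    top = np.sort(np.argsort(-var, kind="stable")[:n_top])
    X = X[:, top]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd

    n_comps = max(1, min(params.n_pcs, X.shape[0] - 1, X.shape[1]))
    pca = PCA(n_components=n_comps, svd_solver="full", random_state=params.seed % (2**31))
    with np.errstate(invalid="ignore"):  # zero-variance input is legal
        emb = pca.fit_transform(X)

    k = min(params.k_neighbors, n_droplets - 1)
    adj = kneighbors_graph(emb, n_neighbors=k, mode="connectivity", include_self=False)
    adj = adj.maximum(adj.T)
    sources, targets = adj.nonzero()
    keep = sources < targets
    g = ig.Graph(
        n=n_droplets, edges=list(zip(sources[keep].tolist(), targets[keep].tolist()))
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=params.resolution,
        seed=params.seed % (2**31),
    )
    labels = np.asarray(part.membership)

    # relabel by decreasing size; tie-break by smallest member index
    ids, counts = np.unique(labels, return_counts=True)
    first = np.array([np.flatnonzero(labels == i)[0] for i in ids])
    order = np.lexsort((first, -counts))
    remap = {int(ids[o]): rank for rank, o in enumerate(order)}
    return np.array([remap[int(l)] for l in labels], dtype=int)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    return float(a @ b / denom) if denom > 0 else 0.0


def annotate_clusters(
    ln_matrix: sp.spmatrix,
    clusters: np.ndarray,
    genes: pd.Index,
    reference: ReferenceProfiles,
    params: AnalysisParams,
    min_shared_genes: int = 100,
) -> pd.DataFrame:
    """Label clusters by best Pearson correlation with reference ln-centroids.

    The reference centroid of a type is ln(1 + S * profile) with S the median
    droplet library size, i.e. the expected ln counts of a typical droplet of
    that type.  Clusters whose best correlation falls below
    ``annotation_min_correlation`` keep the argmax label but are flagged
    low-confidence.  Returns one row per droplet: cluster, cell_type,
    correlation, low_confidence.
    """
    genes = pd.Index(genes)
    shared = genes.intersection(reference.profiles.index)
    if len(shared) == 0:
        raise ValueError("no genes shared between matrix and reference")
    if len(shared) < min_shared_genes:
        raise ValueError(
            f"only {len(shared)} genes shared with reference (< {min_shared_genes})"
        )
    ln = sp.csr_matrix(ln_matrix)
    row_of = {g: i for i, g in enumerate(genes)}
    rows = np.array([row_of[g] for g in shared])

    totals = np.asarray(np.expm1(ln.copy().todense()).sum(axis=0)).ravel()
    scale = float(np.median(totals)) if len(totals) else 1e4
    ref = np.log1p(scale * reference.profiles.loc[shared].to_numpy())  # shared x types
    types = reference.cell_types

    cluster_ids = np.unique(clusters)
    assign: dict[int, tuple[str, float, bool]] = {}
    for c in cluster_ids:
        members = np.flatnonzero(clusters == c)
        centroid = np.asarray(ln[:, members].mean(axis=1)).ravel()[rows]
        cors = np.array([_pearson(centroid, ref[:, t]) for t in range(len(types))])
        best = int(np.argmax(cors))
        assign[int(c)] = (
            types[best],
            float(cors[best]),
            bool(cors[best] < params.annotation_min_correlation),
        )

    return pd.DataFrame(
        {
            "cluster": clusters,
            "cell_type": [assign[int(c)][0] for c in clusters],
            "correlation": [assign[int(c)][1] for c in clusters],
            "low_confidence": [assign[int(c)][2] for c in clusters],
        }
    )


def find_cluster_markers(
    ln_matrix: sp.spmatrix,
    clusters: np.ndarray,
    params: AnalysisParams,
    gene_ids: pd.Index | None = None,
) -> pd.DataFrame:
    """Per-cluster marker genes by one-sided Wilcoxon rank-sum.

    For each gene and cluster, tests in-cluster vs rest on ln values
    (alternative: greater); q-values are Benjamini-Hochberg within each
    cluster.  ``is_marker`` requires q <= marker_alpha and positive effect
    (difference of mean ln expression).
    """
    clusters = np.asarray(clusters)
    ids = np.unique(clusters)
    if len(ids) < 2:
        warnings.warn("single cluster: no marker test possible", stacklevel=2)
        return pd.DataFrame(columns=["gene", "cluster", "effect", "p", "q", "is_marker"])
    X = np.asarray(sp.csr_matrix(ln_matrix).todense())  # genes x droplets
    if gene_ids is None:
        gene_ids = pd.Index([f"g{i}" for i in range(X.shape[0])])
    out = []
    for c in ids:
        inside = X[:, clusters == c]
        outside = X[:, clusters != c]
        with np.errstate(all="ignore"):
            res = mannwhitneyu(inside, outside, axis=1, alternative="greater")
        p = np.nan_to_num(res.pvalue, nan=1.0)
        q = false_discovery_control(p, method="bh")
        effect = inside.mean(axis=1) - outside.mean(axis=1)
        out.append(
            pd.DataFrame(
                {
                    "gene": gene_ids,
                    "cluster": c,
                    "effect": effect,
                    "p": p,
                    "q": q,
                    "is_marker": (q <= params.marker_alpha) & (effect > 0),
                }
            )
        )
    return pd.concat(out, ignore_index=True)
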