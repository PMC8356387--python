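"""Droplet-level quality control.

Per-droplet metrics, empty-droplet calling (two-component mixture on log
library size as a lightweight stand-in for a full generative ambient model),
ambient-fraction estimation by per-droplet maximum likelihood, artificial-
doublet kNN scoring, and the filter cascade with xenograft mouse-UMI
filtering.

Filter semantics follow the removal phrasing: droplets with *more than* 20%
mitochondrial UMI or *more than* 25% mouse UMI are removed (boundary values
survive); graft droplets with UMI < 1000 or expressed genes < 500 are
removed; genes must be detected (>= 1 UMI) in at least 3 surviving droplets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize_scalar
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

from .datatypes import DropletMatrix, validate_gene_annotations

#: minimum separation (ln units) of mixture means to accept a two-mode fit
_MIN_MODE_SEPARATION = 2.0


@dataclass
class QCThresholds:
    """Filter cutoffs; defaults are the pipeline's published rules."""

    min_cells_per_gene: int = 3
    min_genes_per_droplet: int = 200
    max_mito_fraction: float = 0.20
    max_mouse_fraction: float = 0.25
    graft_min_umi: int = 1000
    graft_min_genes: int = 500
    empty_posterior_cutoff: float = 0.5
    expected_doublet_rate: float = 0.08

    def __post_init__(self) -> None:
        for name in ("max_mito_fraction", "max_mouse_fraction", "empty_posterior_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("min_cells_per_gene", "min_genes_per_droplet", "graft_min_umi", "graft_min_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class QCReport:
    """Per-droplet metrics plus filter decisions and per-stage tallies."""

    metrics: pd.DataFrame
    thresholds: Optional[QCThresholds] = None
    tallies: Dict[str, int] = field(default_factory=dict)
    ambient_profile: Optional[np.ndarray] = None

    def summary(self) -> Dict[str, object]:
        out: Dict[str, object] = dict(self.tallies)
        for col in ("total_umi", "n_genes_detected", "mito_fraction", "mouse_fraction"):
            if col in self.metrics:
                out[f"mean_{col}"] = float(self.metrics[col].mean())
        return out


def compute_droplet_metrics(matrix: DropletMatrix) -> QCReport:
    """Per-droplet totals, detected genes (>=1 UMI), mito and mouse fractions.

    Zero-total droplets get fractions 0 by convention.
    """
    validate_gene_annotations(matrix.genes)
    counts = matrix.counts.tocsc()
    total = np.asarray(counts.sum(axis=0)).ravel().astype(np.int64)
    n_genes = np.asarray((counts > 0).sum(axis=0)).ravel().astype(np.int64)
    is_mito = matrix.genes["is_mito"].to_numpy(dtype=bool)
    is_mouse = (matrix.genes["species"] == "mouse").to_numpy(dtype=bool)
    mito_umi = np.asarray(counts[is_mito, :].sum(axis=0)).ravel() if is_mito.any() else np.zeros_like(total)
    mouse_umi = np.asarray(counts[is_mouse, :].sum(axis=0)).ravel() if is_mouse.any() else np.zeros_like(total)
    denom = np.where(total > 0, total, 1)
    metrics = pd.DataFrame(
        {
            "barcode": matrix.barcodes,
            "total_umi": total,
            "n_genes_detected": n_genes,
            "mito_fraction": mito_umi / denom,
            "mouse_fraction": mouse_umi / denom,
        }
    )
    return QCReport(metrics=metrics)


def empty_posterior(matrix: DropletMatrix, seed: int = 0) -> np.ndarray:
    """Posterior probability that each droplet is empty.

    Two-component Gaussian mixture on ln(total UMI + 1); the low-mean
    component is "empty".  A degenerate fit (modes closer than
    ``_MIN_MODE_SEPARATION`` ln units) yields all-zero posteriors with a
    warning — the caller falls back to a low-count ambient profile.
    """
    n = matrix.n_droplets
    if n < 100:
        raise ValueError(f"empty-droplet calling needs >= 100 droplets, got {n}")
    total = matrix.total_umi()
    x = np.log(total + 1.0).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, n_init=5, random_state=int(seed) % (2**31))
    gm.fit(x)
    means = gm.means_.ravel()
    low = int(np.argmin(means))
    if abs(means[0] - means[1]) < _MIN_MODE_SEPARATION:
        warnings.warn(
            "library-size distribution looks single-mode; no droplets flagged empty, "
            "ambient profile taken from the lowest 1% of droplets",
            stacklevel=2,
        )
        return np.zeros(n)
    return gm.predict_proba(x)[:, low]


def call_empty_droplets(
    matrix: DropletMatrix,
    thresholds: QCThresholds,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Flag empty droplets and derive the ambient expression profile.

    Droplets whose empty posterior exceeds ``empty_posterior_cutoff`` are
    flagged; the ambient profile is the normalised pooled counts of the
    flagged droplets, falling back to the bottom 1% of droplets by library
    size when none is flagged.
    """
    n = matrix.n_droplets
    total = matrix.total_umi()
    post = empty_posterior(matrix, seed=seed)
    empty = post > thresholds.empty_posterior_cutoff

    counts = matrix.counts.tocsc()
    if empty.any():
        pooled = np.asarray(counts[:, np.flatnonzero(empty)].sum(axis=1)).ravel()
    else:
        k = max(1, int(np.ceil(0.01 * n)))
        order = np.argsort(total, kind="stable")[:k]
        pooled = np.asarray(counts[:, order].sum(axis=1)).ravel()
    pooled = pooled.astype(float)
    if pooled.sum() == 0:
        pooled = np.ones_like(pooled)
    ambient_profile = pooled / pooled.sum()
    return empty, ambient_profile


def _ln_cp10k(counts: sp.spmatrix) -> sp.csr_matrix:
    """ln(1 + counts-per-10k) on droplets (columns)."""
    counts = counts.tocsc().astype(float)
    total = np.asarray(counts.sum(axis=0)).ravel()
    scale = 1e4 / np.where(total > 0, total, 1)
    mat = counts @ sp.diags(scale)
    mat.data = np.log1p(mat.data)
    return mat.tocsr()


def _pca_embed(counts: sp.spmatrix, n_comps: int, seed: int) -> np.ndarray:
    """Dense PCA embedding of droplets from ln-normalised counts."""
    X = np.asarray(_ln_cp10k(counts).todense()).T  # droplets x genes
    n_comps = max(1, min(n_comps, X.shape[0] - 1, X.shape[1]))
    pca = PCA(n_components=n_comps, svd_solver="full", random_state=int(seed) % (2**31))
    with np.errstate(invalid="ignore"):  # zero-variance input is legal
        return pca.fit_transform(X)


def estimate_ambient_fractions(
    matrix: DropletMatrix,
    ambient_profile: np.ndarray,
    n_groups: int = 5,
    seed: int = 0,
    n_refine: int = 30,
    refine_tol: float = 5e-4,
) -> np.ndarray:
    """Per-droplet ambient fraction by 1-D maximum likelihood.

    Droplets (assumed non-empty) are coarse-grouped by k-means on top
    principal components of ln-normalised counts; each droplet's ``rho``
    maximises the multinomial likelihood of its counts under
    ``(1 - rho) * group_centroid + rho * ambient_profile``.  Because the
    empirical centroid itself carries ambient contamination, the centroid is
    purified (subtract the group-mean ambient estimate, renormalise) and the
    estimate refined until the group means move less than ``refine_tol``
    (at most ``n_refine`` rounds) — without this the estimator is biased low
    by roughly the mean ambient fraction.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    ambient_profile = np.asarray(ambient_profile, dtype=float).ravel()
    if ambient_profile.shape[0] != matrix.n_genes:
        raise ValueError(
            f"ambient profile has {ambient_profile.shape[0]} genes, matrix has {matrix.n_genes}"
        )
    n = matrix.n_droplets
    emb = _pca_embed(matrix.counts, n_comps=20, seed=seed)
    if n_groups == 1:
        groups = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=min(n_groups, n), n_init=10, random_state=int(seed) % (2**31))
        groups = km.fit_predict(emb)

    counts = matrix.counts.tocsc()
    # raw centroids as probability vectors
    centroids = np.zeros((matrix.n_genes, n_groups))
    for g in range(n_groups):
        members = np.flatnonzero(groups == g)
        if len(members) == 0:
            centroids[:, g] = ambient_profile
            continue
        pooled = np.asarray(counts[:, members].sum(axis=1)).ravel().astype(float)
        centroids[:, g] = pooled / max(pooled.sum(), 1.0)

    counts_csc = counts
    eps = 1e-12

    def _fit_droplet(d: int, centroid: np.ndarray) -> float:
        col = counts_csc[:, d]
        idx = col.indices if sp.issparse(col) else np.flatnonzero(col)
        x = col.data.astype(float)
        if len(idx) == 0:
            return 0.0
        c = centroid[idx]
        a = ambient_profile[idx]

        def nll(rho: float) -> float:
            return -float(x @ np.log((1.0 - rho) * c + rho * a + eps))

        res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": 1e-4})
        return float(res.x)

    rho_hat = np.zeros(n)
    rho_bar = np.zeros(n_groups)  # current purification level per group
    for round_ in range(max(1, n_refine)):
        work = np.empty_like(centroids)
        for g in range(n_groups):
            pure = (centroids[:, g] - rho_bar[g] * ambient_profile) / (1.0 - rho_bar[g])
            pure = np.clip(pure, 0.0, None)
            s = pure.sum()
            work[:, g] = pure / s if s > 0 else centroids[:, g]
        for d in range(n):
            rho_hat[d] = _fit_droplet(d, work[:, groups[d]])
        new_bar = rho_bar.copy()
        for g in range(n_groups):
            members = np.flatnonzero(groups == g)
            if len(members):
                new_bar[g] = min(float(rho_hat[members].mean()), 0.95)
        shift = float(np.max(np.abs(new_bar - rho_bar)))
        rho_bar = new_bar
        if shift < refine_tol:
            break
    return rho_hat


def flag_doublets(
    matrix: DropletMatrix,
    thresholds: QCThresholds,
    seed: int = 0,
    artificial_fraction: float = 0.25,
    k_neighbors: int = 20,
    n_pcs: int = 30,
) -> Tuple[np.ndarray, np.ndarray]:
    """Score droplets by their artificial-doublet neighbourhood.

    Synthesises artificial doublets by summing random droplet pairs, embeds
    real and artificial droplets in a shared PCA space of ln-normalised
    counts, and scores each real droplet by the fraction of artificial
    neighbours among its ``k_neighbors`` nearest.  The top
    ``expected_doublet_rate`` quantile by score is flagged (ties broken by
    barcode order).
    """
    rate = thresholds.expected_doublet_rate
    if not 0.0 <= rate < 0.5:
        raise ValueError(f"expected_doublet_rate must be in [0, 0.5), got {rate}")
    n = matrix.n_droplets
    if n < 50:
        raise ValueError(f"doublet flagging needs >= 50 droplets, got {n}")
    rng = np.random.default_rng(int(seed) % (2**31))
    n_art = max(2, int(round(artificial_fraction * n)))
    ia = rng.integers(0, n, n_art)
    ib = rng.integers(0, n, n_art)

    counts = matrix.counts.tocsc()
    art = counts[:, ia] + counts[:, ib]
    X_real = np.asarray(_ln_cp10k(counts).todense()).T
    X_art = np.asarray(_ln_cp10k(art).todense()).T

    n_comps = max(1, min(n_pcs, X_real.shape[0] - 1, X_real.shape[1]))
    pca = PCA(n_components=n_comps, svd_solver="full", random_state=int(seed) % (2**31))
    emb_real = pca.fit_transform(X_real)
    emb_art = pca.transform(X_art)
    emb = np.vstack([emb_real, emb_art])
    is_art = np.zeros(len(emb), dtype=bool)
    is_art[n:] = True

    k = min(k_neighbors, len(emb) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb[:n])
    neigh = idx[:, 1:]  # drop self
    score = is_art[neigh].mean(axis=1)

    n_flag = int(round(rate * n))
    flags = np.zeros(n, dtype=bool)
    if n_flag > 0:
        order = np.argsort(-score, kind="stable")  # ties -> earlier barcode first
        flags[order[:n_flag]] = True
    return flags, score


def apply_qc_filters(
    matrix: DropletMatrix,
    report: QCReport,
    thresholds: QCThresholds,
    graft_mode: bool = False,
) -> Tuple[DropletMatrix, QCReport]:
    """Run the filter cascade and update the report with per-stage tallies.

    Removal order: empty -> doublet -> droplet thresholds (min genes; mito
    strictly-more-than; graft additionally min UMI, min genes, mouse
    strictly-more-than) -> drop mouse genes (graft) -> gene filter (detected
    in >= min_cells_per_gene surviving droplets).
    """
    m = report.metrics
    if len(m) != matrix.n_droplets:
        raise ValueError("report does not match matrix droplet count")
    n0 = matrix.n_droplets
    empty = m["is_empty"].to_numpy(dtype=bool) if "is_empty" in m else np.zeros(n0, bool)
    doublet = m["is_doublet"].to_numpy(dtype=bool) if "is_doublet" in m else np.zeros(n0, bool)

    alive = ~empty
    removed_empty = int(empty.sum())
    removed_doublet = int((alive & doublet).sum())
    alive &= ~doublet

    genes_ok = m["n_genes_detected"].to_numpy() >= thresholds.min_genes_per_droplet
    mito_ok = m["mito_fraction"].to_numpy() <= thresholds.max_mito_fraction  # "more than" removed
    keep = genes_ok & mito_ok
    if graft_mode:
        keep &= m["total_umi"].to_numpy() >= thresholds.graft_min_umi  # "< 1000" removed
        keep &= m["n_genes_detected"].to_numpy() >= thresholds.graft_min_genes
        keep &= m["mouse_fraction"].to_numpy() <= thresholds.max_mouse_fraction
    removed_thresholds = int((alive & ~keep).sum())
    alive &= keep

    out = matrix.subset_droplets(alive)

    genes_removed_mouse = 0
    if graft_mode:
        is_mouse = (out.genes["species"] == "mouse").to_numpy()
        genes_removed_mouse = int(is_mouse.sum())
        out = out.subset_genes(~is_mouse)

    detected_in = np.asarray((out.counts > 0).sum(axis=1)).ravel()
    gene_keep = detected_in >= thresholds.min_cells_per_gene
    genes_removed_low = int((~gene_keep).sum())
    out = out.subset_genes(gene_keep)

    if out.n_droplets == 0:
        warnings.warn("all droplets removed by QC filters", stacklevel=2)

    tallies = {
        "n_droplets_in": n0,
        "removed_empty": removed_empty,
        "removed_doublet": removed_doublet,
        "removed_droplet_thresholds": removed_thresholds,
        "n_droplets_out": int(alive.sum()),
        "n_genes_in": matrix.n_genes,
        "genes_removed_mouse": genes_removed_mouse,
        "genes_removed_low_cells": genes_removed_low,
        "n_genes_out": out.n_genes,
    }
    metrics = m.copy()
    metrics["pass_qc"] = alive
    new_report = QCReport(
        metrics=metrics,
        thresholds=thresholds,
        tallies={**report.tallies, **tallies},
        ambient_profile=report.ambient_profile,
    )
    return out, new_report


def run_qc(
    matrix: DropletMatrix,
    thresholds: QCThresholds,
    graft_mode: bool = False,
    seed: int = 0,
    n_ambient_groups: int = 5,
) -> Tuple[DropletMatrix, QCReport]:
    """Convenience wrapper: metrics -> empty call -> doublets -> ambient ->
    filter cascade.  Doublet scoring and ambient estimation run on non-empty
    droplets only; removed droplets keep NaN ambient estimates."""
    report = compute_droplet_metrics(matrix)
    post = empty_posterior(matrix, seed=seed)
    empty, ambient_profile = call_empty_droplets(matrix, thresholds, seed=seed)
    metrics = report.metrics
    metrics["is_empty"] = empty
    metrics["empty_posterior"] = post

    nonempty_idx = np.flatnonzero(~empty)
    sub = matrix.subset_droplets(nonempty_idx)
    flags = np.zeros(matrix.n_droplets, dtype=bool)
    scores = np.zeros(matrix.n_droplets)
    if sub.n_droplets >= 50 and thresholds.expected_doublet_rate > 0:
        f, s = flag_doublets(sub, thresholds, seed=seed)
        flags[nonempty_idx] = f
        scores[nonempty_idx] = s
    metrics["is_doublet"] = flags
    metrics["doublet_score"] = scores

    amb = np.full(matrix.n_droplets, np.nan)
    if sub.n_droplets > 0:
        amb[nonempty_idx] = estimate_ambient_fractions(
            sub, ambient_profile, n_groups=n_ambient_groups, seed=seed
        )
    metrics["ambient_estimate"] = amb

    report = QCReport(metrics=metrics, thresholds=thresholds, ambient_profile=ambient_profile)
    return apply_qc_filters(matrix, report, thresholds, graft_mode=graft_mode)
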