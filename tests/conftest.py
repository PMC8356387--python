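"""Shared fixtures: small hand-built matrices and one seeded paired run.

The expensive artifacts (default paired simulation, its QC and annotation)
are session-scoped and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import snconcord as s


def make_matrix(
    counts: np.ndarray,
    biotypes=None,
    species=None,
    symbols=None,
    modality: str = "whole_cell",
) -> s.DropletMatrix:
    """Build a DropletMatrix from a dense genes x droplets array."""
    counts = np.asarray(counts)
    n_genes = counts.shape[0]
    biotypes = list(biotypes) if biotypes is not None else ["protein_coding"] * n_genes
    species = list(species) if species is not None else ["human"] * n_genes
    symbols = list(symbols) if symbols is not None else [f"SYM{i}" for i in range(n_genes)]
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i:04d}" for i in range(n_genes)],
            "symbol": symbols,
            "species": species,
            "biotype": biotypes,
            "is_mito": [b == "mito" for b in biotypes],
        }
    )
    barcodes = np.array([f"BC-{j:04d}" for j in range(counts.shape[1])], dtype=object)
    return s.DropletMatrix(sp.csr_matrix(counts), genes, barcodes, modality)


@pytest.fixture(scope="session")
def default_config() -> s.SimulationConfig:
    return s.SimulationConfig(seed=3)


@pytest.fixture(scope="session")
def paired(default_config) -> s.PairedExperiment:
    return s.simulate_paired_experiment(default_config, seed=3)


@pytest.fixture(scope="session")
def qc_results(paired):
    """QC-filtered matrices and reports for both modalities."""
    out = {}
    for modality, matrix in paired.matrices.items():
        out[modality] = s.run_qc(matrix, s.QCThresholds(), graft_mode=False, seed=3)
    return out


@pytest.fixture(scope="session")
def annotations(paired, qc_results):
    """Cluster + annotate each QC-filtered modality."""
    params = s.AnalysisParams(seed=3)
    labels = {}
    for modality, (filtered, _) in qc_results.items():
        clusters = s.reduce_and_cluster(s.normalize_ln(filtered, depth_scale=True), params)
        labels[modality] = s.annotate_clusters(
            s.normalize_ln(filtered), clusters, filtered.gene_ids, paired.profiles, params
        )
    return labels


@pytest.fixture(scope="session")
def concordance(paired, qc_results, annotations) -> s.ConcordanceReport:
    fl = {m: f for m, (f, _) in qc_results.items()}
    return s.compare_datasets(
        fl["nucleus"],
        fl["whole_cell"],
        s.normalize_ln(fl["nucleus"]),
        s.normalize_ln(fl["whole_cell"]),
        annotations["nucleus"]["cell_type"],
        annotations["whole_cell"]["cell_type"],
        paired.profiles.genes,
    )
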