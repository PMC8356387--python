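"""Synthetic paired whole-cell / nucleus droplet-count generator.

Emulates the data a droplet-based islet experiment produces so the QC,
annotation and concordance stages can be exercised and tested without any
download: shared cell-type expression programs with modality differences
(library size, mitochondrial fraction, nuclear lncRNA retention, ambient
contamination), empty droplets, doublets, and — for xenograft nuclei — a
per-droplet mouse-UMI admixture drawn from a two-component Beta mixture.

Ground truth for every droplet (kind, type(s), ambient fraction, mouse
fraction, library size) is returned alongside the counts so parameter
recovery is directly testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import DropletMatrix

MODALITIES = ("whole_cell", "nucleus", "graft_nucleus")
#: modalities that sequence nuclei (lncRNA retention applies)
NUCLEAR_MODALITIES = ("nucleus", "graft_nucleus")

#: The 13 protein-coding genes of the human mitochondrial genome.
MITO_SYMBOLS = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
)

#: Canonical islet marker symbols assigned when the matching type is configured.
#: The first symbol of each list is the type's hallmark (hormone) gene.
CANONICAL_MARKERS: Dict[str, Tuple[str, ...]] = {
    "beta": ("INS", "ABCC8", "SLC30A8", "MAFA", "PAX6"),
    "alpha": ("GCG",),
    "delta": ("SST",),
    "PP": ("PPY",),
    "ductal": ("CFTR", "SOX9", "KRT19"),
}

#: Canonical nuclear-retained lncRNA symbols, given to the first lncRNA genes.
CANONICAL_LNCRNAS = ("NEAT1", "MEG3")

#: Deterministic per-modality seed offsets for paired experiments.
MODALITY_SEED_OFFSETS = {"whole_cell": 1, "nucleus": 2, "graft_nucleus": 3}


def _default_biotype_fractions() -> Dict[str, float]:
    # 0.0065 * 2000 genes = 13 mitochondrial genes
    return {"protein_coding": 0.8435, "lncRNA": 0.15, "mito": 0.0065}


def _default_proportions() -> Tuple[float, ...]:
    return (0.35, 0.30, 0.10, 0.05, 0.10, 0.10)


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions.

    Per-modality dictionaries are keyed by ``whole_cell`` / ``nucleus`` /
    ``graft_nucleus``.  Ambient levels default to the measured means for
    cells (5.87%), nuclei (1.42%) and grafted nuclei (4.6%); mitochondrial
    UMI targets to 4.2% (cells), 2.7% (nuclei) and 1.5% (graft nuclei,
    observed < 2%).
    """

    n_genes_human: int = 2000
    n_genes_mouse: int = 500
    biotype_fractions: Dict[str, float] = field(default_factory=_default_biotype_fractions)
    cell_type_names: Tuple[str, ...] = ("alpha", "beta", "delta", "PP", "ductal", "other")
    cell_type_proportions: Tuple[float, ...] = field(default_factory=_default_proportions)
    markers_per_type: int = 20
    marker_fold: float = 8.0
    #: extra boost of each type's hallmark gene on top of marker_fold
    hallmark_extra: float = 3.0
    #: lncRNA baseline abundance relative to the mean protein-coding gene
    lncRNA_expression_scale: float = 0.12
    #: log-sd of the lognormal lncRNA baseline spread
    lncRNA_expression_logsd: float = 0.5
    library_size_logmean: Dict[str, float] = field(
        default_factory=lambda: {
            "whole_cell": math.log(6000.0),
            "nucleus": math.log(4500.0),
            "graft_nucleus": math.log(4000.0),
        }
    )
    library_size_logsd: Dict[str, float] = field(
        default_factory=lambda: {m: 0.35 for m in MODALITIES}
    )
    ambient_level: Dict[str, float] = field(
        default_factory=lambda: {
            "whole_cell": 0.0587,
            "nucleus": 0.0142,
            "graft_nucleus": 0.046,
        }
    )
    #: Beta concentration of the per-droplet ambient fraction around its mean
    ambient_concentration: float = 50.0
    doublet_rate: float = 0.08
    doublet_library_factor: float = 1.6
    n_empty_droplets: int = 300
    empty_size_logmean: float = math.log(50.0)
    empty_size_logsd: float = 0.5
    mito_target: Dict[str, float] = field(
        default_factory=lambda: {
            "whole_cell": 0.042,
            "nucleus": 0.027,
            "graft_nucleus": 0.015,
        }
    )
    lncRNA_retention_factor: float = 3.0
    #: ((a_clean, b_clean), (a_contaminated, b_contaminated), weight_contaminated)
    mouse_beta_params: Tuple[Tuple[float, float], Tuple[float, float], float] = (
        (3.0, 57.0),
        (10.0, 7.0),
        0.1,
    )
    n_droplets: Dict[str, int] = field(
        default_factory=lambda: {m: 1200 for m in MODALITIES}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes_human <= 0 or self.n_genes_mouse <= 0:
            raise ValueError("gene counts must be positive")
        bf = self.biotype_fractions
        if set(bf) != {"protein_coding", "lncRNA", "mito"}:
            raise ValueError("biotype_fractions must cover protein_coding, lncRNA, mito")
        if any(not 0.0 <= v <= 1.0 for v in bf.values()) or abs(sum(bf.values()) - 1.0) > 1e-9:
            raise ValueError("biotype_fractions must be in [0,1] and sum to 1")
        props = np.asarray(self.cell_type_proportions, dtype=float)
        if len(props) != len(self.cell_type_names):
            raise ValueError("one proportion per cell type required")
        if (props < 0).any() or (props > 1).any() or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("cell_type_proportions must be in [0,1] and sum to 1")
        if self.markers_per_type <= 0:
            raise ValueError("markers_per_type must be positive")
        n_pc = self.n_biotype("protein_coding")
        if self.markers_per_type * len(self.cell_type_names) > n_pc:
            raise ValueError(
                f"{self.markers_per_type} markers x {len(self.cell_type_names)} types "
                f"exceed the {n_pc} protein-coding genes available"
            )
        if self.marker_fold <= 0:
            raise ValueError("marker_fold must be positive")
        if not 0.0 <= self.doublet_rate < 1.0:
            raise ValueError("doublet_rate must be in [0,1)")
        for m in MODALITIES:
            if not 0.0 <= self.ambient_level[m] < 1.0:
                raise ValueError("ambient_level must be in [0,1)")
            if not 0.0 <= self.mito_target[m] < 1.0:
                raise ValueError("mito_target must be in [0,1)")
        if self.lncRNA_retention_factor < 1.0:
            raise ValueError("lncRNA_retention_factor must be >= 1")
        (_, _), (_, _), w = self.mouse_beta_params
        if not 0.0 <= w <= 1.0:
            raise ValueError("mouse mixture weight must be in [0,1]")

    def n_biotype(self, biotype: str) -> int:
        """Number of human genes of a biotype; mito count is rounded last."""
        n_mito = max(1, round(self.biotype_fractions["mito"] * self.n_genes_human))
        n_lnc = round(self.biotype_fractions["lncRNA"] * self.n_genes_human)
        n_pc = self.n_genes_human - n_mito - n_lnc
        return {"protein_coding": n_pc, "lncRNA": n_lnc, "mito": n_mito}[biotype]


@dataclass
class ReferenceProfiles:
    """Per-type expression programs on the human gene space.

    ``profiles`` holds one probability vector per cell type (columns), indexed
    by gene id; every column is non-negative and sums to one.  These play the
    role of a harmonised whole-cell reference for centroid annotation.
    """

    profiles: pd.DataFrame
    genes: pd.DataFrame
    marker_genes: Dict[str, List[str]]
    mouse_profile: np.ndarray
    mouse_genes: pd.DataFrame

    @property
    def cell_types(self) -> List[str]:
        return list(self.profiles.columns)


def _substream(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng((int(seed) + offset) % (2**31))


def _build_gene_table(config: SimulationConfig) -> pd.DataFrame:
    n_pc = config.n_biotype("protein_coding")
    n_lnc = config.n_biotype("lncRNA")
    n_mito = config.n_biotype("mito")
    ids, symbols, biotypes = [], [], []
    for i in range(n_pc):
        ids.append(f"HG{i + 1:06d}")
        symbols.append(f"PCG{i + 1}")
        biotypes.append("protein_coding")
    for i in range(n_lnc):
        ids.append(f"HG{n_pc + i + 1:06d}")
        symbols.append(
            CANONICAL_LNCRNAS[i] if i < len(CANONICAL_LNCRNAS) else f"LINC{i + 1:05d}"
        )
        biotypes.append("lncRNA")
    for i in range(n_mito):
        ids.append(f"HG{n_pc + n_lnc + i + 1:06d}")
        symbols.append(MITO_SYMBOLS[i] if i < len(MITO_SYMBOLS) else f"MT-X{i + 1}")
        biotypes.append("mito")
    genes = pd.DataFrame(
        {
            "gene_id": ids,
            "symbol": symbols,
            "species": "human",
            "biotype": biotypes,
        }
    )
    genes["is_mito"] = genes["biotype"] == "mito"
    return genes


def _mouse_gene_table(config: SimulationConfig) -> pd.DataFrame:
    genes = pd.DataFrame(
        {
            "gene_id": [f"MM{i + 1:06d}" for i in range(config.n_genes_mouse)],
            "symbol": [f"Mmg{i + 1}" for i in range(config.n_genes_mouse)],
            "species": "mouse",
            "biotype": "protein_coding",
        }
    )
    genes["is_mito"] = False
    return genes


def build_reference_profiles(config: SimulationConfig) -> ReferenceProfiles:
    """Build per-type gene-expression probability vectors.

    All types share one baseline drawn once (Dirichlet-like gamma(0.5) masses
    for coding and mitochondrial genes; a low lognormal band for lncRNAs).
    Each type then multiplies its disjoint marker set by ``marker_fold``
    (hallmark gene by ``hallmark_extra`` more) and renormalises.  Marker genes
    are given the mean non-marker baseline before boosting so the realised
    marker fold equals ``marker_fold``.
    """
    config.validate()
    genes = _build_gene_table(config)
    rng = _substream(config.seed, 0)
    n = config.n_genes_human

    base = rng.gamma(shape=0.5, scale=2.0, size=n)  # chi2(1): Dirichlet(0.5) masses
    is_lnc = (genes["biotype"] == "lncRNA").to_numpy()
    pc_mask = (genes["biotype"] == "protein_coding").to_numpy()
    mean_pc = base[pc_mask].mean()
    # lncRNAs: uniformly low expression with moderate spread
    base[is_lnc] = (
        mean_pc
        * config.lncRNA_expression_scale
        * rng.lognormal(0.0, config.lncRNA_expression_logsd, is_lnc.sum())
    )

    # disjoint marker sets from protein-coding genes
    pc_idx = np.flatnonzero(pc_mask)
    k = config.markers_per_type
    chosen = rng.choice(pc_idx, size=k * len(config.cell_type_names), replace=False)
    marker_idx = {
        t: chosen[i * k : (i + 1) * k] for i, t in enumerate(config.cell_type_names)
    }
    all_markers = np.concatenate(list(marker_idx.values()))
    nonmarker_mean = np.delete(base, all_markers).mean()
    base[all_markers] = nonmarker_mean  # typical baseline, so boost == realised fold

    # canonical symbols onto the first marker slots of matching type names
    symbols = genes["symbol"].to_numpy(dtype=object)
    for t, canon in CANONICAL_MARKERS.items():
        if t in marker_idx:
            for j, sym in enumerate(canon[: len(marker_idx[t])]):
                symbols[marker_idx[t][j]] = sym
    genes["symbol"] = symbols

    cols = {}
    for t in config.cell_type_names:
        prof = base.copy()
        prof[marker_idx[t]] *= config.marker_fold
        prof[marker_idx[t][0]] *= config.hallmark_extra  # hallmark dominance
        cols[t] = prof / prof.sum()
    profiles = pd.DataFrame(cols, index=genes["gene_id"].to_numpy())

    mouse_genes = _mouse_gene_table(config)
    mouse_rng = _substream(config.seed, 11)
    mouse_raw = mouse_rng.gamma(0.5, 2.0, config.n_genes_mouse)
    mouse_profile = mouse_raw / mouse_raw.sum()

    marker_ids = {
        t: list(genes["gene_id"].to_numpy()[idx]) for t, idx in marker_idx.items()
    }
    return ReferenceProfiles(
        profiles=profiles,
        genes=genes,
        marker_genes=marker_ids,
        mouse_profile=mouse_profile,
        mouse_genes=mouse_genes,
    )


def _modality_profiles(
    config: SimulationConfig, profiles: ReferenceProfiles, modality: str
) -> np.ndarray:
    """Apply modality rescaling: lncRNA retention (nuclei) and mito target."""
    mat = profiles.profiles.to_numpy(copy=True)  # genes x types
    is_lnc = (profiles.genes["biotype"] == "lncRNA").to_numpy()
    is_mito = profiles.genes["is_mito"].to_numpy()
    if modality in NUCLEAR_MODALITIES:
        mat[is_lnc, :] *= config.lncRNA_retention_factor
        mat /= mat.sum(axis=0, keepdims=True)
    target = config.mito_target[modality]
    cur = mat[is_mito, :].sum(axis=0)
    nonmito_scale = (1.0 - target) / (1.0 - cur)
    mat[is_mito, :] *= target / cur
    mat[~is_mito, :] *= nonmito_scale
    return mat


def simulate_modality(
    config: SimulationConfig,
    profiles: ReferenceProfiles,
    modality: str,
    seed: int,
) -> Tuple[DropletMatrix, pd.DataFrame]:
    """Simulate one modality's droplet-count bundle plus its truth table.

    Counts for each droplet are a single multinomial draw of its lognormal
    library size over the (concatenated human+mouse, for grafts) gene space;
    the expected gene distribution of a singlet is
    ``(1-rho) * pi_type + rho * pi_ambient`` with the droplet's ambient
    fraction ``rho`` Beta-distributed around the modality's ambient level.
    """
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    n_real = config.n_droplets[modality]
    if n_real <= 0:
        raise ValueError("n_droplets must be positive")
    config.validate()
    rng = np.random.default_rng(int(seed) % (2**31))

    type_mat = _modality_profiles(config, profiles, modality)  # genes x types
    props = np.asarray(config.cell_type_proportions, dtype=float)
    ambient = type_mat @ props  # abundance-weighted mixture

    n_doublet = int(round(config.doublet_rate * n_real))
    n_singlet = n_real - n_doublet
    n_empty = config.n_empty_droplets
    n_types = len(config.cell_type_names)

    kinds = np.array(
        ["singlet"] * n_singlet + ["doublet"] * n_doublet + ["empty"] * n_empty,
        dtype=object,
    )
    type_a = np.full(n_singlet + n_doublet + n_empty, "", dtype=object)
    type_b = np.full_like(type_a, "")
    t1 = rng.choice(n_types, size=n_singlet, p=props)
    t2a = rng.choice(n_types, size=n_doublet, p=props)
    t2b = rng.choice(n_types, size=n_doublet, p=props)
    names = np.asarray(config.cell_type_names, dtype=object)
    type_a[:n_singlet] = names[t1]
    type_a[n_singlet : n_singlet + n_doublet] = names[t2a]
    type_b[n_singlet : n_singlet + n_doublet] = names[t2b]

    # per-droplet ambient fraction
    level = config.ambient_level[modality]
    conc = config.ambient_concentration
    rho = np.zeros(len(kinds))
    if level > 0:
        rho[: n_real] = rng.beta(level * conc, (1.0 - level) * conc, size=n_real)
    rho[n_real:] = 1.0  # empties are pure ambient

    # library sizes
    lib = np.zeros(len(kinds), dtype=np.int64)
    mu, sd = config.library_size_logmean[modality], config.library_size_logsd[modality]
    lib[:n_singlet] = np.maximum(1, np.round(rng.lognormal(mu, sd, n_singlet))).astype(np.int64)
    lib[n_singlet : n_real] = np.maximum(
        1,
        np.round(
            rng.lognormal(mu, sd, n_doublet) * config.doublet_library_factor
        ),
    ).astype(np.int64)
    lib[n_real:] = np.maximum(
        1, np.round(rng.lognormal(config.empty_size_logmean, config.empty_size_logsd, n_empty))
    ).astype(np.int64)

    # mouse admixture (graft only)
    mouse_frac = np.zeros(len(kinds))
    mouse_comp = np.full(len(kinds), "", dtype=object)
    if modality == "graft_nucleus":
        (a0, b0), (a1, b1), w = config.mouse_beta_params
        contaminated = rng.random(n_real) < w
        m = np.where(
            contaminated,
            rng.beta(a1, b1, n_real),
            rng.beta(a0, b0, n_real),
        )
        mouse_frac[:n_real] = m
        mouse_comp[:n_real] = np.where(contaminated, "contaminated", "clean")
        # empties carry ambient-level (clean) mouse admixture
        mouse_frac[n_real:] = rng.beta(a0, b0, n_empty)
        mouse_comp[n_real:] = "clean"

    n_genes_h = config.n_genes_human
    graft = modality == "graft_nucleus"
    n_genes_total = n_genes_h + (config.n_genes_mouse if graft else 0)

    counts = np.zeros((len(kinds), n_genes_total), dtype=np.int32)
    for d in range(len(kinds)):
        if kinds[d] == "singlet":
            human_p = type_mat[:, np.flatnonzero(names == type_a[d])[0]]
        elif kinds[d] == "doublet":
            ia = np.flatnonzero(names == type_a[d])[0]
            ib = np.flatnonzero(names == type_b[d])[0]
            human_p = 0.5 * (type_mat[:, ia] + type_mat[:, ib])
        else:
            human_p = ambient
        p = (1.0 - rho[d]) * human_p + rho[d] * ambient
        if graft:
            p = np.concatenate(
                [(1.0 - mouse_frac[d]) * p, mouse_frac[d] * profiles.mouse_profile]
            )
        counts[d] = rng.multinomial(lib[d], p / p.sum())

    gene_table = profiles.genes.copy()
    if graft:
        gene_table = pd.concat(
            [gene_table, profiles.mouse_genes], ignore_index=True
        )

    prefix = {"whole_cell": "SC", "nucleus": "SN", "graft_nucleus": "GR"}[modality]
    barcodes = np.array([f"{prefix}-{i + 1:06d}" for i in range(len(kinds))], dtype=object)

    matrix = DropletMatrix(
        counts=sp.csr_matrix(counts.T),
        genes=gene_table,
        barcodes=barcodes,
        modality=modality,
    )
    truth = pd.DataFrame(
        {
            "barcode": barcodes,
            "kind": kinds,
            "cell_type": type_a,
            "cell_type_2": type_b,
            "ambient_fraction": rho,
            "mouse_fraction": mouse_frac,
            "mouse_component": mouse_comp,
            "library_size": lib,
        }
    )
    return matrix, truth


@dataclass
class PairedExperiment:
    """Bundle of matched modalities simulated from one set of type programs."""

    profiles: ReferenceProfiles
    matrices: Dict[str, DropletMatrix]
    truths: Dict[str, pd.DataFrame]
    config: SimulationConfig


def simulate_paired_experiment(
    config: SimulationConfig,
    seed: int | None = None,
    include_graft: bool = False,
) -> PairedExperiment:
    """Simulate whole-cell and nucleus (optionally graft) bundles that share
    one set of cell-type programs, with deterministic per-modality seeds."""
    base_seed = config.seed if seed is None else int(seed)
    cfg = config
    if seed is not None and seed != config.seed:
        from dataclasses import replace as _replace

        cfg = _replace(config, seed=int(seed))
    profiles = build_reference_profiles(cfg)
    modalities = ["whole_cell", "nucleus"] + (["graft_nucleus"] if include_graft else [])
    matrices: Dict[str, DropletMatrix] = {}
    truths: Dict[str, pd.DataFrame] = {}
    for m in modalities:
        mat, truth = simulate_modality(
            cfg, profiles, m, seed=(base_seed + MODALITY_SEED_OFFSETS[m]) % (2**31)
        )
        matrices[m] = mat
        truths[m] = truth
    return PairedExperiment(profiles=profiles, matrices=matrices, truths=truths, config=cfg)
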