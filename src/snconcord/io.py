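"""Readers and writers for 10x-style triplet bundles and sidecar tables.

A bundle directory holds ``matrix.mtx[.gz]`` (Matrix Market coordinate,
integer, genes as rows, 1-based on disk), ``features.tsv[.gz]`` (gene id,
symbol, biotype; xenograft bundles prefix ids with ``hg-`` / ``mm-``) and
``barcodes.tsv[.gz]``.  Optional sidecars: ``gene_annotations.tsv`` (full
annotation), ``truth.tsv`` (simulator ground truth) and a YAML config.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .datatypes import DropletMatrix
from .simgen import ReferenceProfiles, SimulationConfig


def _find(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {directory}")


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_tenx_bundle(directory: str | Path, modality: str = "unknown") -> DropletMatrix:
    """Read a triplet bundle (plain or gzipped) into a :class:`DropletMatrix`.

    Species is inferred from ``hg-``/``mm-`` feature-id prefixes when present,
    else from the ``gene_annotations.tsv`` sidecar, else assumed human; the
    mitochondrial flag comes from the sidecar or an ``MT-`` symbol prefix.
    """
    directory = Path(directory)
    with _open_maybe_gz(_find(directory, "matrix.mtx"), "rb") as fh:
        counts = scipy.io.mmread(fh)
    counts = sp.csr_matrix(counts)
    if not np.issubdtype(counts.dtype, np.integer):
        if counts.nnz and not np.allclose(counts.data, np.round(counts.data)):
            raise ValueError("matrix.mtx contains non-integer values")
        counts = counts.astype(np.int64)

    def _read_tsv(stem: str) -> pd.DataFrame:
        with _open_maybe_gz(_find(directory, stem)) as fh:
            try:
                return pd.read_csv(fh, sep="\t", header=None)
            except pd.errors.EmptyDataError:
                return pd.DataFrame()

    features = _read_tsv("features.tsv")
    features.columns = ["gene_id", "symbol", "biotype"][: features.shape[1]]
    bc = _read_tsv("barcodes.tsv")
    barcodes = (
        bc[0].to_numpy(dtype=object) if len(bc.columns) else np.array([], dtype=object)
    )

    if counts.shape[0] != len(features):
        raise ValueError(
            f"matrix has {counts.shape[0]} gene rows but features.tsv has {len(features)}"
        )
    if counts.shape[1] != len(barcodes):
        raise ValueError(
            f"matrix has {counts.shape[1]} droplet columns but barcodes.tsv has {len(barcodes)}"
        )

    ids = features["gene_id"].astype(str)
    prefixed = ids.str.startswith(("hg-", "mm-"))
    species = np.where(ids.str.startswith("mm-"), "mouse", "human")
    stripped = ids.str.replace(r"^(hg|mm)-", "", regex=True)

    sidecar = directory / "gene_annotations.tsv"
    if sidecar.exists():
        anno = pd.read_csv(sidecar, sep="\t").set_index("gene_id").reindex(stripped)
        if prefixed.any():
            species_col = species
        else:
            species_col = anno["species"].fillna("human").to_numpy()
        sym = anno["symbol"].to_numpy(dtype=object)
        fallback = (features["symbol"] if "symbol" in features else stripped).to_numpy(dtype=object)
        sym = np.where(pd.isna(sym), fallback, sym)
        genes = pd.DataFrame(
            {
                "gene_id": stripped.to_numpy(),
                "symbol": sym,
                "species": species_col,
                "biotype": anno["biotype"].fillna("unknown").to_numpy(),
                "is_mito": anno["is_mito"].fillna(False).to_numpy(dtype=bool),
            }
        )
    else:
        symbol = features["symbol"] if "symbol" in features else stripped
        biotype = features["biotype"] if "biotype" in features else pd.Series("unknown", index=features.index)
        genes = pd.DataFrame(
            {
                "gene_id": stripped.to_numpy(),
                "symbol": symbol.to_numpy(),
                "species": species,
                "biotype": biotype.to_numpy(),
                "is_mito": symbol.astype(str).str.startswith("MT-").to_numpy(),
            }
        )
    return DropletMatrix(counts=counts, genes=genes, barcodes=barcodes, modality=modality)


def write_tenx_bundle(
    matrix: DropletMatrix,
    directory: str | Path,
    gzipped: bool = False,
) -> Path:
    """Write the triplet plus a full ``gene_annotations.tsv`` sidecar.

    Xenograft bundles (any mouse gene present) get species-prefixed feature
    ids on disk; in-memory ids are always unprefixed.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gzipped else ""

    mtx_path = directory / f"matrix.mtx{suffix}"
    coo = sp.coo_matrix(matrix.counts)
    with _open_maybe_gz(mtx_path, "wb") as fh:
        scipy.io.mmwrite(fh, coo, field="integer")

    has_mouse = (matrix.genes["species"] == "mouse").any()
    ids = matrix.genes["gene_id"].astype(str)
    if has_mouse:
        prefix = matrix.genes["species"].map({"human": "hg-", "mouse": "mm-"})
        ids = prefix + ids
    features = pd.DataFrame(
        {
            "gene_id": ids,
            "symbol": matrix.genes["symbol"],
            "biotype": matrix.genes["biotype"],
        }
    )
    with _open_maybe_gz(directory / f"features.tsv{suffix}", "wt") as fh:
        features.to_csv(fh, sep="\t", header=False, index=False)
    with _open_maybe_gz(directory / f"barcodes.tsv{suffix}", "wt") as fh:
        pd.Series(matrix.barcodes).to_csv(fh, sep="\t", header=False, index=False)
    matrix.genes.to_csv(directory / "gene_annotations.tsv", sep="\t", index=False)
    return directory


def write_truth(truth: pd.DataFrame, directory: str | Path) -> Path:
    path = Path(directory) / "truth.tsv"
    truth.to_csv(path, sep="\t", index=False)
    return path


def read_truth(directory: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(directory) / "truth.tsv", sep="\t", keep_default_na=False)


def write_reference_profiles(profiles: ReferenceProfiles, path: str | Path) -> Path:
    path = Path(path)
    profiles.profiles.rename_axis("gene_id").to_csv(path, sep="\t")
    return path


def read_reference_profiles(path: str | Path, genes: Optional[pd.DataFrame] = None) -> ReferenceProfiles:
    """Read a per-type profile table; annotation defaults to a minimal one."""
    table = pd.read_csv(path, sep="\t").set_index("gene_id")
    if genes is None:
        genes = pd.DataFrame(
            {
                "gene_id": table.index,
                "symbol": table.index,
                "species": "human",
                "biotype": "unknown",
                "is_mito": False,
            }
        )
    return ReferenceProfiles(
        profiles=table,
        genes=genes.reset_index(drop=True),
        marker_genes={},
        mouse_profile=np.zeros(0),
        mouse_genes=genes.iloc[0:0],
    )


def load_simulation_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = SimulationConfig(**raw)
    cfg.validate()
    return cfg


def save_simulation_config(config: SimulationConfig, path: str | Path) -> Path:
    from dataclasses import asdict

    path = Path(path)
    data = asdict(config)
    data["cell_type_names"] = list(data["cell_type_names"])
    data["cell_type_proportions"] = list(data["cell_type_proportions"])
    data["mouse_beta_params"] = [
        list(data["mouse_beta_params"][0]),
        list(data["mouse_beta_params"][1]),
        data["mouse_beta_params"][2],
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
    return path


def write_json(data: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
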