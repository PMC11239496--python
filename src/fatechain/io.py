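"""Readers and writers for the package's on-disk formats.

Sparse matrices travel as Matrix Market (.mtx) with sidecar delimited
index files mapping rows/columns to cell identifiers; datasets travel as
an MTX + features/barcodes TSV triplet, a delimited dense matrix, or an
h5ad container (via anndata).  Pseudotime vectors are 2-column tables,
couplings are per-pair MTX files listed in a manifest.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .datatypes import ExpressionDataset, NeighborGraph, TransitionMatrix
from .kernels.pseudotime import PseudotimeVector
from .kernels.realtime import TransportMap

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_transition_matrix",
    "read_transition_matrix",
    "write_pseudotime",
    "read_pseudotime",
    "write_couplings",
    "read_couplings",
]


def write_dataset(ds: ExpressionDataset, path: str | Path, format: str = "mtx_dir") -> None:
    path = Path(path)
    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        mmwrite(path / "matrix.mtx", sp.coo_matrix(ds.X))
        pd.Series(ds.cell_ids).to_csv(path / "barcodes.tsv", sep="\t", index=False, header=False)
        pd.Series(ds.gene_ids.astype(str)).to_csv(
            path / "features.tsv", sep="\t", index=False, header=False
        )
        ds.cell_meta.to_csv(path / "cell_meta.tsv", sep="\t")
        if ds.layers:
            (path / "layers").mkdir(exist_ok=True)
            for name, layer in ds.layers.items():
                mmwrite(path / "layers" / f"{name}.mtx", sp.coo_matrix(layer))
        if ds.embeddings:
            (path / "embeddings").mkdir(exist_ok=True)
            for name, Z in ds.embeddings.items():
                pd.DataFrame(Z, index=ds.cell_ids).to_csv(
                    path / "embeddings" / f"{name}.tsv", sep="\t", header=False
                )
    elif format == "delimited":
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(ds.dense_X(), index=ds.cell_ids, columns=ds.gene_ids.astype(str)).to_csv(
            path / "matrix.csv"
        )
        ds.cell_meta.to_csv(path / "cell_meta.tsv", sep="\t")
    elif format == "h5ad":
        ds.to_anndata().write_h5ad(path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_dataset(path: str | Path, format: str = "mtx_dir") -> ExpressionDataset:
    path = Path(path)
    if format == "mtx_dir":
        X = sp.csr_matrix(mmread(path / "matrix.mtx"))
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
        features = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].astype(str)
        meta_path = path / "cell_meta.tsv"
        if meta_path.exists():
            meta = pd.read_csv(meta_path, sep="\t", index_col=0)
            meta.index = meta.index.astype(str)
        else:
            meta = pd.DataFrame(index=pd.Index(barcodes, name="cell_id"))
        if X.shape[0] != len(meta):
            raise ValueError(
                f"matrix has {X.shape[0]} cells but metadata has {len(meta)} rows"
            )
        if X.shape[1] != len(features):
            raise ValueError(
                f"matrix has {X.shape[1]} genes but features lists {len(features)}"
            )
        layers = {}
        if (path / "layers").is_dir():
            for f in sorted((path / "layers").glob("*.mtx")):
                layers[f.stem] = sp.csr_matrix(mmread(f))
        embeddings = {}
        if (path / "embeddings").is_dir():
            for f in sorted((path / "embeddings").glob("*.tsv")):
                embeddings[f.stem] = (
                    pd.read_csv(f, sep="\t", header=None, index_col=0).to_numpy(dtype=float)
                )
        return ExpressionDataset(
            X=X, cell_meta=meta, gene_ids=features.to_numpy(), layers=layers,
            embeddings=embeddings,
        )
    if format == "delimited":
        M = pd.read_csv(path / "matrix.csv", index_col=0)
        meta = pd.read_csv(path / "cell_meta.tsv", sep="\t", index_col=0)
        meta.index = meta.index.astype(str)
        if len(M) != len(meta):
            raise ValueError(
                f"matrix has {len(M)} cells but metadata has {len(meta)} rows"
            )
        return ExpressionDataset(
            X=M.to_numpy(dtype=float), cell_meta=meta, gene_ids=M.columns.to_numpy()
        )
    if format == "h5ad":
        import anndata as ad

        return ExpressionDataset.from_anndata(ad.read_h5ad(path))
    raise ValueError(f"unknown format {format!r}")


def write_transition_matrix(T: TransitionMatrix, path: str | Path, cell_ids=None) -> None:
    """MTX file plus a sidecar ``<stem>.cells.tsv`` mapping rows to cells."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mmwrite(path, sp.coo_matrix(T.P))
    ids = cell_ids if cell_ids is not None else np.arange(T.n_cells)
    side = path.with_suffix("").with_suffix(".cells.tsv")
    pd.Series(np.asarray(ids).astype(str)).to_csv(side, sep="\t", index=False, header=False)


def read_transition_matrix(path: str | Path, direction: str = "forward") -> TransitionMatrix:
    return TransitionMatrix(sp.csr_matrix(mmread(path)), direction=direction)


def write_pseudotime(pt: PseudotimeVector, path: str | Path, cell_ids=None) -> None:
    ids = cell_ids if cell_ids is not None else np.arange(len(pt))
    pd.DataFrame({"cell_id": np.asarray(ids).astype(str), "pseudotime": pt.values}).to_csv(
        path, sep="\t", index=False
    )


def read_pseudotime(path: str | Path, source: str = "user") -> PseudotimeVector:
    tab = pd.read_csv(path, sep="\t")
    return PseudotimeVector(values=tab["pseudotime"].to_numpy(dtype=float), source=source)


def write_couplings(couplings: list[TransportMap], outdir: str | Path) -> None:
    """One MTX per consecutive time-point pair plus a manifest TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cp in couplings:
        fname = f"coupling_{cp.source_time:g}_{cp.target_time:g}.mtx"
        mmwrite(outdir / fname, sp.coo_matrix(cp.coupling))
        rows.append(
            {"source_time": cp.source_time, "target_time": cp.target_time, "file": fname}
        )
    pd.DataFrame(rows).to_csv(outdir / "manifest.tsv", sep="\t", index=False)


def read_couplings(outdir: str | Path) -> list[TransportMap]:
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.tsv", sep="\t")
    out = []
    for _, row in manifest.iterrows():
        M = np.asarray(mmread(outdir / row["file"]).todense())
        out.append(
            TransportMap(
                coupling=M,
                source_time=float(row["source_time"]),
                target_time=float(row["target_time"]),
            )
        )
    return out
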