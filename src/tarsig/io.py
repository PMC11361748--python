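"""Readers and writers for the pipeline's on-disk formats.

Bulk counts travel as TSV (genes as rows, samples as columns) with a
companion design TSV; single-cell matrices as a MatrixMarket triple
(``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``, 10x convention:
genes x cells on disk, cells x genes in memory) with a cell-metadata
TSV; gene sets, signatures and reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse

from .bulkde import BulkCountMatrix
from .scscore import SignatureDef

__all__ = [
    "read_bulk_counts",
    "read_mtx_dir",
    "read_signature",
    "write_bulk_counts",
    "write_json",
    "write_mtx_dir",
]


def read_bulk_counts(counts_path, design_path) -> BulkCountMatrix:
    """Read a bulk counts TSV (gene_id x samples) plus its design TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or not np.allclose(
        values, np.round(values)
    ):
        raise ValueError(f"{counts_path}: counts must be integer-valued")
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    return BulkCountMatrix(counts=counts.astype(np.int64), design=design)


def write_bulk_counts(m: BulkCountMatrix, counts_path, design_path) -> None:
    m.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    m.design.rename_axis("sample_id").to_csv(design_path, sep="\t")


def read_mtx_dir(directory, metadata_path=None) -> ad.AnnData:
    """Read a 10x-style MatrixMarket directory into cells x genes AnnData.

    Expects ``matrix.mtx`` (genes x cells), ``features.tsv`` and
    ``barcodes.tsv``; dimensions of the companions must match the matrix
    header. An optional cell-metadata TSV (indexed by barcode, with at
    least a ``cluster`` column) is merged into ``obs``.
    """
    directory = Path(directory)
    for name in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
        if not (directory / name).exists():
            raise FileNotFoundError(f"MatrixMarket triple incomplete: missing {name}")
    mat = scio.mmread(directory / "matrix.mtx")  # genes x cells on disk
    features = pd.read_csv(directory / "features.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0]
    if mat.shape[0] != len(features):
        raise ValueError(
            f"matrix declares {mat.shape[0]} genes but features.tsv has "
            f"{len(features)} rows"
        )
    if mat.shape[1] != len(barcodes):
        raise ValueError(
            f"matrix declares {mat.shape[1]} cells but barcodes.tsv has "
            f"{len(barcodes)} rows"
        )
    if features.duplicated().any():
        raise ValueError("duplicate gene symbols in features.tsv")
    if barcodes.duplicated().any():
        raise ValueError("duplicate barcodes in barcodes.tsv")
    dense = np.asarray(sparse.csr_matrix(mat).todense())
    if not np.allclose(dense, np.round(dense)) or (dense < 0).any():
        raise ValueError("matrix entries must be non-negative integers")
    adata = ad.AnnData(
        X=dense.T.astype(np.int64),
        obs=pd.DataFrame(index=pd.Index(barcodes.astype(str).to_numpy())),
        var=pd.DataFrame(index=pd.Index(features.astype(str).to_numpy())),
    )
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
        missing = adata.obs_names.difference(meta.index)
        if len(missing):
            raise ValueError(f"cell metadata missing barcodes: {list(missing)[:5]}")
        adata.obs = adata.obs.join(meta.loc[adata.obs_names])
    return adata


def write_mtx_dir(adata: ad.AnnData, directory, metadata: bool = True) -> None:
    """Write cells x genes AnnData as a 10x-style MatrixMarket triple."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = sparse.coo_matrix(np.asarray(adata.X).T)  # genes x cells on disk
    scio.mmwrite(str(directory / "matrix.mtx"), mat, field="integer")
    pd.Series(adata.var_names).to_csv(
        directory / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )
    if metadata and len(adata.obs.columns):
        adata.obs.rename_axis("barcode").to_csv(
            directory / "cell_metadata.tsv", sep="\t"
        )


def read_signature(path) -> SignatureDef:
    """Read a signature from JSON ({"name", "genes"}) or newline text."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        payload = json.loads(text)
        return SignatureDef(name=payload.get("name", path.stem),
                            genes=tuple(payload["genes"]))
    genes = tuple(line.strip() for line in text.splitlines() if line.strip())
    return SignatureDef(name=path.stem, genes=genes)


def write_json(payload: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
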