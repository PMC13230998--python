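"""Readers and writers for 10x-style MTX triplet directories.

A directory holds ``matrix.mtx``, ``features.tsv`` (or ``genes.tsv``) and
``barcodes.tsv``, each optionally gzipped.  Simulated populations add a
``labels.tsv`` (barcode, state, depth) so ground truth round-trips with the
counts.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .populations import CellPopulation

__all__ = ["read_10x_matrix", "write_10x_matrix", "write_population", "read_population"]

_MATRIX_NAMES = ["matrix.mtx", "matrix.mtx.gz"]
_FEATURE_NAMES = ["features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz"]
_BARCODE_NAMES = ["barcodes.tsv", "barcodes.tsv.gz"]


def _find(path: Path, candidates: list[str], what: str) -> Path:
    for name in candidates:
        if (path / name).exists():
            return path / name
    raise FileNotFoundError(f"no {what} file in {path} (looked for {candidates})")


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_10x_matrix(path) -> tuple[sp.csc_matrix, pd.DataFrame, np.ndarray]:
    """Read a 10x MTX triplet directory.

    Returns (counts genes x cells, features frame with gene_id / gene_symbol
    columns, barcode array).  Distinct errors for missing files, malformed
    matrices, dimension mismatches and non-integer values.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"{path} is not a directory")
    mtx_path = _find(path, _MATRIX_NAMES, "matrix")
    feat_path = _find(path, _FEATURE_NAMES, "features")
    bc_path = _find(path, _BARCODE_NAMES, "barcodes")
    try:
        with _open_maybe_gz(mtx_path) as fh:
            mat = scipy.io.mmread(fh)
    except Exception as exc:
        raise ValueError(f"malformed Matrix Market file {mtx_path}: {exc}") from exc
    mat = sp.csc_matrix(mat)
    if mat.data.size and np.any(mat.data != np.floor(mat.data)):
        raise ValueError(f"{mtx_path} contains non-integer values")
    if mat.data.size and np.any(mat.data < 0):
        raise ValueError(f"{mtx_path} contains negative values")
    mat = mat.astype(np.int64)
    feats = pd.read_csv(feat_path, sep="\t", header=None)
    if feats.shape[1] == 1:
        feats[1] = feats[0]
    feats = feats.rename(columns={0: "gene_id", 1: "gene_symbol"})
    barcodes = pd.read_csv(bc_path, sep="\t", header=None)[0].to_numpy()
    if mat.shape[0] != len(feats):
        raise ValueError(
            f"dimension mismatch: matrix has {mat.shape[0]} rows but "
            f"{feat_path.name} lists {len(feats)} features"
        )
    if mat.shape[1] != len(barcodes):
        raise ValueError(
            f"dimension mismatch: matrix has {mat.shape[1]} columns but "
            f"{bc_path.name} lists {len(barcodes)} barcodes"
        )
    return mat, feats, barcodes


def write_10x_matrix(path, counts, gene_ids=None, gene_symbols=None, barcodes=None) -> None:
    """Write a genes x cells integer matrix as a plain (uncompressed) MTX triplet."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    counts = sp.coo_matrix(counts)
    n_genes, n_cells = counts.shape
    if gene_ids is None:
        gene_ids = [f"GENE{i + 1:05d}" for i in range(n_genes)]
    if gene_symbols is None:
        gene_symbols = gene_ids
    if barcodes is None:
        barcodes = [f"CELL_{j + 1:04d}" for j in range(n_cells)]
    with open(path / "matrix.mtx", "wb") as fh:
        scipy.io.mmwrite(fh, counts, field="integer")
    pd.DataFrame(
        {"id": gene_ids, "symbol": gene_symbols, "type": "Gene Expression"}
    ).to_csv(path / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(barcodes).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)


def write_population(path, pop: CellPopulation) -> None:
    """Write a simulated population as MTX triplet plus a labels TSV."""
    path = Path(path)
    barcodes = [f"{state}_{j + 1:04d}" for j, state in enumerate(pop.labels)]
    write_10x_matrix(path, pop.counts, barcodes=barcodes)
    pd.DataFrame(
        {"barcode": barcodes, "state": pop.labels, "depth": pop.depths}
    ).to_csv(path / "labels.tsv", sep="\t", index=False)


def read_population(path) -> CellPopulation:
    """Round-trip reader for :func:`write_population` output."""
    path = Path(path)
    counts, _, barcodes = read_10x_matrix(path)
    labels_path = path / "labels.tsv"
    if not labels_path.exists():
        raise FileNotFoundError(f"no labels.tsv in {path}")
    lab = pd.read_csv(labels_path, sep="\t")
    if not np.array_equal(lab["barcode"].to_numpy(), barcodes):
        raise ValueError("labels.tsv barcodes disagree with barcodes.tsv")
    pop = CellPopulation(
        counts=counts,
        labels=lab["state"].to_numpy(dtype=str),
        depths=lab["depth"].to_numpy(dtype=np.int64),
        provenance={"source": str(path)},
    )
    pop.validate()
    return pop
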