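"""Droplet count matrix I/O and hard-count threshold filtering.

Droplet-based single-cell/single-nucleus experiments emit a gene x droplet
matrix of deduplicated molecule (UMI) counts, conventionally stored as a
MatrixMarket triplet: ``matrix.mtx`` plus barcode and gene/feature TSVs.
Two dialects are in the wild: the older one with a two-column ``genes.tsv``
and the newer one with a three-column, gzipped ``features.tsv.gz`` carrying a
feature-type column. This module reads and writes both, computes per-droplet
summaries, and implements the quantile-based hard-count baseline filter
(the 99th percent quantile of the top ``C`` barcode totals divided by 10,
with droplets at or above the threshold kept as putative nuclei).
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

__all__ = [
    "SparseCountMatrix",
    "read_10x_mtx",
    "write_10x_mtx",
    "droplet_stats",
    "write_stats_tsv",
    "quantile_threshold",
    "filter_by_count",
]


class CountMatrixFormatError(ValueError):
    """A triplet file is missing or cannot be parsed."""


class CountMatrixIntegrityError(ValueError):
    """Matrix dimensions disagree with the barcode/gene annotation files."""


@dataclass
class SparseCountMatrix:
    """Gene x droplet matrix of nonnegative integer UMI counts.

    Rows are genes, columns are droplets, mirroring the on-disk layout of
    the MatrixMarket triplet. ``gene_ids`` and ``barcodes`` must be unique;
    ``gene_names`` may repeat (gene symbols are not unique in practice).
    """

    gene_ids: list[str]
    gene_names: list[str]
    barcodes: list[str]
    counts: sp.spmatrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.barcodes)):
            raise CountMatrixIntegrityError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} barcodes"
            )
        if len(self.gene_names) != len(self.gene_ids):
            raise CountMatrixIntegrityError("gene_names length != gene_ids length")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise CountMatrixIntegrityError("duplicate gene ids")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise CountMatrixIntegrityError("duplicate barcodes")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise CountMatrixIntegrityError("negative counts")
        data = self.counts.data
        if data.size and not np.allclose(data, np.round(data)):
            raise CountMatrixIntegrityError("non-integer counts")
        self.counts = self.counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_droplets(self) -> int:
        return len(self.barcodes)

    def subset_genes(self, index) -> "SparseCountMatrix":
        """Row subset by integer/boolean index, preserving droplet order."""
        idx = np.arange(self.n_genes)[index] if np.asarray(index).dtype == bool else np.asarray(index)
        return SparseCountMatrix(
            [self.gene_ids[i] for i in idx],
            [self.gene_names[i] for i in idx],
            list(self.barcodes),
            self.counts[idx, :],
        )

    def subset_barcodes(self, barcodes: list[str]) -> "SparseCountMatrix":
        """Column subset by barcode, in the given order."""
        pos = {b: j for j, b in enumerate(self.barcodes)}
        idx = np.array([pos[b] for b in barcodes], dtype=int)
        return SparseCountMatrix(
            list(self.gene_ids), list(self.gene_names), list(barcodes), self.counts[:, idx]
        )


def _find_file(directory: str, candidates: list[str], what: str) -> str:
    for name in candidates:
        path = os.path.join(directory, name)
        if os.path.exists(path):
            return path
    raise CountMatrixFormatError(
        f"no {what} file found in {directory!r} (looked for: {', '.join(candidates)})"
    )


def _open_maybe_gz(path: str, mode: str = "rt"):
    return gzip.open(path, mode) if path.endswith(".gz") else open(path, mode)


def read_10x_mtx(directory: str) -> SparseCountMatrix:
    """Read a CellRanger-style MTX triplet directory.

    Accepts both dialects: ``genes.tsv`` (two columns: id, name) and
    ``features.tsv`` (three columns: id, name, feature type), each optionally
    gzipped, alongside ``matrix.mtx[.gz]`` and ``barcodes.tsv[.gz]``.

    Raises
    ------
    CountMatrixFormatError
        If a required file is missing.
    CountMatrixIntegrityError
        If the MatrixMarket header dimensions disagree with the TSV lengths.
    """
    mtx_path = _find_file(directory, ["matrix.mtx", "matrix.mtx.gz"], "matrix")
    bc_path = _find_file(directory, ["barcodes.tsv", "barcodes.tsv.gz"], "barcodes")
    gene_path = _find_file(
        directory,
        ["features.tsv.gz", "features.tsv", "genes.tsv", "genes.tsv.gz"],
        "genes/features",
    )

    with _open_maybe_gz(mtx_path, "rb") as fh:
        counts = sp.csr_matrix(mmread(fh))
    genes = pd.read_csv(gene_path, sep="\t", header=None, dtype=str)
    bcs = pd.read_csv(bc_path, sep="\t", header=None, dtype=str)

    if counts.shape[0] != len(genes) or counts.shape[1] != len(bcs):
        raise CountMatrixIntegrityError(
            f"matrix is {counts.shape[0]} x {counts.shape[1]} but annotation has "
            f"{len(genes)} genes and {len(bcs)} barcodes"
        )
    gene_ids = genes[0].tolist()
    gene_names = genes[1].tolist() if genes.shape[1] > 1 else list(gene_ids)
    return SparseCountMatrix(gene_ids, gene_names, bcs[0].tolist(), counts)


def write_10x_mtx(matrix: SparseCountMatrix, directory: str, version: str = "v2") -> None:
    """Write ``matrix`` as an MTX triplet.

    ``version='v2'`` emits plain ``matrix.mtx``/``barcodes.tsv``/``genes.tsv``;
    ``version='v3'`` emits the gzipped three-column ``features.tsv.gz`` dialect
    with a "Gene Expression" feature-type column.
    """
    if version not in {"v2", "v3"}:
        raise ValueError(f"unknown triplet dialect {version!r}")
    os.makedirs(directory, exist_ok=True)
    gz = version == "v3"
    suffix = ".gz" if gz else ""

    with _open_maybe_gz(os.path.join(directory, "matrix.mtx" + suffix), "wb") as fh:
        mmwrite(fh, sp.coo_matrix(matrix.counts), field="integer")
    with _open_maybe_gz(os.path.join(directory, "barcodes.tsv" + suffix), "wt") as fh:
        fh.write("".join(b + "\n" for b in matrix.barcodes))
    gene_file = "features.tsv.gz" if gz else "genes.tsv"
    with _open_maybe_gz(os.path.join(directory, gene_file), "wt") as fh:
        for gid, name in zip(matrix.gene_ids, matrix.gene_names):
            row = [gid, name] + (["Gene Expression"] if gz else [])
            fh.write("\t".join(row) + "\n")


def droplet_stats(matrix: SparseCountMatrix) -> pd.DataFrame:
    """Per-droplet total UMI counts and number of genes detected.

    Returns a DataFrame with columns ``barcode``, ``total_counts`` (the
    droplet size u_i) and ``genes_detected`` (genes with count > 0), one row
    per barcode in matrix column order.
    """
    csc = matrix.counts.tocsc()
    totals = np.asarray(csc.sum(axis=0)).ravel()
    # explicit zeros are legal in MTX files; count strictly positive entries
    pos = sp.csc_matrix((csc.data > 0, csc.indices, csc.indptr), shape=csc.shape)
    detected = np.asarray(pos.sum(axis=0)).ravel()
    return pd.DataFrame(
        {
            "barcode": matrix.barcodes,
            "total_counts": totals.astype(np.int64),
            "genes_detected": detected.astype(np.int64),
        }
    )


def write_stats_tsv(stats: pd.DataFrame, path: str) -> None:
    stats.to_csv(path, sep="\t", index=False)


def quantile_threshold(
    stats: pd.DataFrame | np.ndarray,
    top_c: int = 3000,
    quantile: float = 0.99,
    divisor: float = 10.0,
) -> float:
    """Hard-count threshold from the upper tail of the barcode-rank curve.

    Sorts droplet totals in decreasing order, takes the ``top_c`` largest,
    computes their ``quantile`` (linear interpolation between order
    statistics) and divides by ``divisor``. With the defaults this is the
    99th percent quantile of the top 3,000 barcodes divided by 10; the high
    quantile guards the estimate against doublets at the very top of the
    curve.
    """
    totals = (
        np.asarray(stats["total_counts"], dtype=float)
        if isinstance(stats, pd.DataFrame)
        else np.asarray(stats, dtype=float)
    )
    if totals.size == 0:
        raise ValueError("no droplets")
    if top_c < 1:
        raise ValueError("top_c must be >= 1")
    if totals.size < top_c:
        logger.warning(
            "only %d droplets available for a top-%d quantile; using all",
            totals.size,
            top_c,
        )
    top = np.sort(totals)[::-1][: min(top_c, totals.size)]
    return float(np.quantile(top, quantile) / divisor)


def filter_by_count(
    matrix: SparseCountMatrix, threshold: float
) -> tuple[list[str], list[str]]:
    """Partition barcodes into (kept, removed) by ``total >= threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    totals = np.asarray(matrix.counts.sum(axis=0)).ravel()
    keep = totals >= threshold
    kept = [b for b, k in zip(matrix.barcodes, keep) if k]
    removed = [b for b, k in zip(matrix.barcodes, keep) if not k]
    return kept, removed
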