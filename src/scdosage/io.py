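"""Readers and writers for the formats the pipeline touches.

The count matrix travels as a 10x-style MatrixMarket triplet (genes as rows
on disk) with one-per-line barcode and gene-id sidecars; in memory it is an
:class:`anndata.AnnData` oriented cells x genes with sparse integer UMI
counts. Gene and cell annotations are TSVs with headers. Chromatin entry
sites (CES) arrive as BED3+ (0-based half-open) and are converted at the
boundary to the package's internal 1-based inclusive convention.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_count_matrix",
    "write_count_matrix",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_ces_bed",
    "write_ces_bed",
    "read_cell_labels",
    "write_cell_labels",
    "validate_labels",
]

AUTOSOMES_DEFAULT = ("2L", "2R", "3L", "3R", "4")

GENE_REQUIRED_COLS = ("gene_id", "chromosome", "start", "end")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


def _read_lines(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_count_matrix(
    matrix_path: str | Path,
    barcodes_path: str | Path,
    genes_path: str | Path,
) -> ad.AnnData:
    """Read a triplet count matrix plus sidecars into AnnData (cells x genes).

    The on-disk orientation is genes x cells (10x convention); the returned
    AnnData is transposed to cells x genes. Entries absent from the triplet
    are zero.

    Raises
    ------
    FormatError
        If the header dimensions disagree with the sidecar line counts, or
        the matrix body is unparseable.
    ValueError
        If any entry is negative or non-integer.
    """
    try:
        mat = spio.mmread(str(matrix_path))
    except Exception as exc:  # scipy raises assorted types on bad input
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    mat = sparse.coo_matrix(mat)

    barcodes = _read_lines(barcodes_path)
    gene_ids = _read_lines(genes_path)
    n_genes, n_cells = mat.shape
    if n_genes != len(gene_ids):
        raise FormatError(
            f"{genes_path}: {len(gene_ids)} gene ids but matrix has {n_genes} rows"
        )
    if n_cells != len(barcodes):
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} barcodes but matrix has {n_cells} columns"
        )
    if len(set(barcodes)) != len(barcodes):
        raise FormatError(f"{barcodes_path}: duplicate barcodes")
    if len(set(gene_ids)) != len(gene_ids):
        raise FormatError(f"{genes_path}: duplicate gene ids")

    data = mat.data
    if data.size:
        neg = np.flatnonzero(data < 0)
        if neg.size:
            i = neg[0]
            raise ValueError(
                f"{matrix_path}: negative count {data[i]} at entry "
                f"(gene {mat.row[i] + 1}, cell {mat.col[i] + 1})"
            )
        frac = np.flatnonzero(data != np.round(data))
        if frac.size:
            i = frac[0]
            raise ValueError(
                f"{matrix_path}: non-integer count {data[i]} at entry "
                f"(gene {mat.row[i] + 1}, cell {mat.col[i] + 1})"
            )
    x = sparse.csr_matrix(mat.T).astype(np.int64)
    adata = ad.AnnData(X=x)
    adata.obs_names = barcodes
    adata.var_names = gene_ids
    return adata


def write_count_matrix(
    adata: ad.AnnData,
    matrix_path: str | Path,
    barcodes_path: str | Path,
    genes_path: str | Path,
) -> None:
    """Write AnnData counts as a genes x cells MatrixMarket triplet with sidecars."""
    x = sparse.coo_matrix(adata.X).T  # back to genes x cells on disk
    spio.mmwrite(str(matrix_path), x, field="integer")
    Path(barcodes_path).write_text("".join(f"{b}\n" for b in adata.obs_names))
    Path(genes_path).write_text("".join(f"{g}\n" for g in adata.var_names))


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read the per-gene annotation TSV.

    Required columns: gene_id, chromosome, start, end. Optional: strand
    (defaults to "."), testis_specific and testis_biased flags (default
    False). Returns a DataFrame indexed by gene_id.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = [c for c in GENE_REQUIRED_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise FormatError(f"{path}: duplicate gene_id(s) {dupes[:5]}")
    if "strand" not in df.columns:
        df["strand"] = "."
    df["strand"] = df["strand"].fillna(".")
    for flag in ("testis_specific", "testis_biased"):
        if flag not in df.columns:
            df[flag] = False
        else:
            df[flag] = df[flag].astype(bool)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] < 1).any():
        bad = df.loc[df["start"] < 1, "gene_id"].iloc[0]
        raise ValueError(f"{path}: start < 1 for gene {bad}")
    if (df["end"] < df["start"]).any():
        bad = df.loc[df["end"] < df["start"], "gene_id"].iloc[0]
        raise ValueError(f"{path}: end < start for gene {bad}")
    return df.set_index("gene_id", drop=False)


def write_gene_annotation(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_ces_bed(path: str | Path) -> pd.DataFrame:
    """Read CES intervals from BED3+ and convert to 1-based inclusive.

    BED is 0-based half-open; internally start = bed_start + 1 and
    end = bed_end. Records not on chromosome X are dropped with a warning.
    Output is sorted ascending by start. Columns: chromosome, start, end,
    site_id (from BED column 4 when present, else "site_<n>").
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable coordinates") from exc
            if start < 0 or end < start:
                raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            site_id = fields[3] if len(fields) > 3 and fields[3] else f"site_{lineno}"
            rows.append((chrom, start + 1, end, site_id))
    df = pd.DataFrame(rows, columns=["chromosome", "start", "end", "site_id"])
    non_x = df["chromosome"] != "X"
    if non_x.any():
        warnings.warn(
            f"{path}: dropped {int(non_x.sum())} CES record(s) not on chromosome X",
            stacklevel=2,
        )
        df = df[~non_x]
    return df.sort_values("start", kind="stable").reset_index(drop=True)


def write_ces_bed(ces: pd.DataFrame, path: str | Path) -> None:
    """Write a CES table back to BED (reverting to 0-based half-open)."""
    out = ces.copy()
    out["start"] = out["start"] - 1
    out[["chromosome", "start", "end", "site_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_cell_labels(path: str | Path) -> pd.DataFrame:
    """Read the barcode -> cell type (and optional strain) TSV.

    Returns a DataFrame indexed by barcode with columns barcode, cell_type,
    strain (strain defaults to "unspecified").
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("barcode", "cell_type"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    if df["barcode"].duplicated().any():
        dupes = df.loc[df["barcode"].duplicated(), "barcode"].tolist()
        raise FormatError(f"{path}: duplicate barcode(s) {dupes[:5]}")
    if "strain" not in df.columns:
        df["strain"] = "unspecified"
    df["strain"] = df["strain"].fillna("unspecified")
    return df.set_index("barcode", drop=False)


def write_cell_labels(labels: pd.DataFrame, path: str | Path) -> None:
    labels.to_csv(path, sep="\t", index=False)


def validate_labels(adata: ad.AnnData, labels: pd.DataFrame) -> pd.DataFrame:
    """Align a label table to a count matrix.

    Every matrix barcode must be labelled (fatal otherwise); label rows for
    barcodes absent from the matrix are ignored with a warning. Returns the
    label table reindexed to the matrix barcode order.
    """
    matrix_bcs = pd.Index(adata.obs_names)
    missing = matrix_bcs.difference(labels.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} barcode(s) in matrix lack labels, e.g. {list(missing[:5])}"
        )
    extra = labels.index.difference(matrix_bcs)
    if len(extra):
        warnings.warn(
            f"ignoring {len(extra)} labelled barcode(s) absent from matrix",
            stacklevel=2,
        )
    return labels.loc[matrix_bcs]
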