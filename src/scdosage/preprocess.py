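"""Detection filtering, log-normalization, and per-gene scaling.

Conventions follow the standard droplet scRNA-seq workflow: a gene is
"detected" in a cell if it has at least one UMI; genes detected in fewer
than ``min_cells_per_gene`` cells are dropped, then cells expressing no more
than ``min_genes_per_cell`` genes are dropped (strict ">", single pass, gene
filter first). Log-normalization is ln(1 + scale_factor * count /
cell_total). Per-gene scaling across cell types comes in two modes: minmax
(linear map onto [0, 1]) and center (z-score across cell types); constant
genes map to all-zero in both.
"""

from __future__ import annotations

from typing import Literal

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "DetectionFilter",
    "LogNormalizer",
    "GeneScaler",
    "filter_matrix",
    "lognormalize",
    "log2p1",
    "scale_per_gene",
]


def _counts_csr(adata: ad.AnnData) -> sparse.csr_matrix:
    x = adata.X
    if not sparse.issparse(x):
        x = sparse.csr_matrix(x)
    return x.tocsr()


class DetectionFilter(BaseEstimator, TransformerMixin):
    """Drop weakly detected genes, then weakly covered cells.

    Parameters
    ----------
    min_cells_per_gene
        Keep genes detected (count >= 1) in at least this many cells.
    min_genes_per_cell
        Keep cells expressing strictly more than this many genes.
    """

    def __init__(self, min_cells_per_gene: int = 3, min_genes_per_cell: int = 200):
        self.min_cells_per_gene = min_cells_per_gene
        self.min_genes_per_cell = min_genes_per_cell

    def fit(self, X: ad.AnnData, y=None):
        if self.min_cells_per_gene < 0 or self.min_genes_per_cell < 0:
            raise ValueError("thresholds must be >= 0")
        x = _counts_csr(X)
        detected = (x > 0)
        gene_mask = np.asarray(detected.sum(axis=0)).ravel() >= self.min_cells_per_gene
        if not gene_mask.any():
            raise ValueError(
                "gene filter removed every gene; review min_cells_per_gene"
            )
        cell_genes = np.asarray(detected[:, gene_mask].sum(axis=1)).ravel()
        cell_mask = cell_genes > self.min_genes_per_cell
        if not cell_mask.any():
            raise ValueError(
                "cell filter removed every cell; review min_genes_per_cell"
            )
        self.gene_mask_ = gene_mask
        self.cell_mask_ = cell_mask
        self.n_genes_removed_ = int((~gene_mask).sum())
        self.n_cells_removed_ = int((~cell_mask).sum())
        return self

    def transform(self, X: ad.AnnData) -> ad.AnnData:
        return X[self.cell_mask_, self.gene_mask_].copy()


class LogNormalizer(BaseEstimator, TransformerMixin):
    """Per-cell depth normalization followed by log1p.

    value = ln(1 + scale_factor * count / cell_total). Stateless beyond
    parameter validation; zero-total cells are an error (filter first).
    """

    def __init__(self, scale_factor: float = 10_000.0):
        self.scale_factor = scale_factor

    def fit(self, X: ad.AnnData, y=None):
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        return self

    def transform(self, X: ad.AnnData) -> ad.AnnData:
        x = _counts_csr(X).astype(np.float64)
        totals = np.asarray(x.sum(axis=1)).ravel()
        if (totals == 0).any():
            bad = X.obs_names[int(np.flatnonzero(totals == 0)[0])]
            raise ValueError(f"cell {bad!r} has zero total counts")
        scaled = sparse.diags(self.scale_factor / totals) @ x
        scaled.data = np.log1p(scaled.data)
        out = X.copy()
        out.X = scaled.tocsr()
        return out


def log2p1(x):
    """log2(x + 1) for non-negative counts (scalar or array)."""
    arr = np.asarray(x, dtype=np.float64)
    if (arr < 0).any():
        raise ValueError("negative count passed to log2p1")
    result = np.log2(arr + 1.0)
    return result if result.ndim else float(result)


class GeneScaler(BaseEstimator, TransformerMixin):
    """Scale each gene's profile across cell types.

    mode="minmax": (v - min) / (max - min), onto [0, 1].
    mode="center": (v - mean) / sd across cell types (sample sd, ddof=1).
    Constant genes map to all-zero in both modes. Input is a genes x
    cell-types DataFrame; needs at least 2 cell types.
    """

    def __init__(self, mode: Literal["minmax", "center"] = "minmax"):
        self.mode = mode

    def fit(self, X: pd.DataFrame, y=None):
        if self.mode not in ("minmax", "center"):
            raise ValueError(f"unknown scaling mode {self.mode!r}")
        if X.shape[1] < 2:
            raise ValueError("per-gene scaling needs at least 2 cell types")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        values = X.to_numpy(dtype=np.float64)
        if self.mode == "minmax":
            lo = values.min(axis=1, keepdims=True)
            hi = values.max(axis=1, keepdims=True)
            span = hi - lo
            constant = (span == 0).ravel()
            span[span == 0] = 1.0
            out = (values - lo) / span
        else:
            mean = values.mean(axis=1, keepdims=True)
            sd = values.std(axis=1, ddof=1, keepdims=True)
            constant = (sd == 0).ravel()
            sd[sd == 0] = 1.0
            out = (values - mean) / sd
        out[constant, :] = 0.0
        return pd.DataFrame(out, index=X.index, columns=X.columns)


def filter_matrix(
    cm: ad.AnnData, min_cells_per_gene: int = 3, min_genes_per_cell: int = 200
) -> ad.AnnData:
    """Apply the detection filters (gene-then-cell, single pass)."""
    return DetectionFilter(min_cells_per_gene, min_genes_per_cell).fit_transform(cm)


def lognormalize(cm: ad.AnnData, scale_factor: float = 10_000.0) -> ad.AnnData:
    """Log-normalize counts: ln(1 + scale_factor * count / cell_total)."""
    return LogNormalizer(scale_factor).fit_transform(cm)


def scale_per_gene(
    g: pd.DataFrame, mode: Literal["minmax", "center"] = "minmax"
) -> pd.DataFrame:
    """Scale a genes x cell-types table per gene (see GeneScaler)."""
    return GeneScaler(mode).fit_transform(g)
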