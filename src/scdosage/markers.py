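"""One-vs-rest marker enrichment and rule-based cell-type annotation.

For every (gene, cell type) pair the enrichment statistic is a two-sided
rank-sum test of the gene's log-normalized values in the cells of that type
against all other cells, Bonferroni-corrected with m = number of genes
tested. Because ranks are shared across the one-vs-rest splits, the pooled
midranks are computed once per gene and reused for every cell type.

Cluster annotation then applies ordered marker rules: a cluster receives
the first rule whose required markers are all significantly enriched
(adjusted p < alpha and in-type mean above out-of-type mean) and whose
excluded markers are not; unmatched clusters are labelled "unassigned".
This mirrors the marker logic used for testis cell types (e.g. Fas3 for
hub before MtnA-without-Fas3 for epithelial).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats as _sps
from sklearn.base import BaseEstimator

__all__ = [
    "MarkerRule",
    "MarkerEnrichment",
    "enrich_one_vs_rest",
    "annotate_clusters",
    "read_marker_rules",
]


@dataclass(frozen=True)
class MarkerRule:
    cell_type: str
    required: frozenset
    excluded: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.required & self.excluded:
            raise ValueError(
                f"rule {self.cell_type!r}: required and excluded markers overlap"
            )


def read_marker_rules(path) -> list[MarkerRule]:
    """Read ordered marker rules from a TSV (cell_type, required, excluded).

    Gene lists are comma-separated; the excluded column may be empty.
    """
    df = pd.read_csv(path, sep="\t")
    rules = []
    for row in df.itertuples():
        required = frozenset(g.strip() for g in str(row.required).split(",") if g.strip())
        excluded_raw = getattr(row, "excluded", "")
        if pd.isna(excluded_raw):
            excluded_raw = ""
        excluded = frozenset(
            g.strip() for g in str(excluded_raw).split(",") if g.strip()
        )
        rules.append(MarkerRule(row.cell_type, required, excluded))
    return rules


class MarkerEnrichment(BaseEstimator):
    """One-vs-rest enrichment across all cell types.

    Parameters
    ----------
    min_cells
        Cell types with fewer cells are skipped with a warning.

    Attributes
    ----------
    results_ : pandas.DataFrame
        Columns gene_id, cell_type, mean_in, mean_out, pct_in, pct_out,
        raw_p, adj_p (Bonferroni, m = genes tested).
    m_ : int
        Bonferroni family size actually used.
    """

    def __init__(self, min_cells: int = 3):
        self.min_cells = min_cells

    def fit(self, X: ad.AnnData, labels: pd.DataFrame, gene_subset=None):
        """Compute enrichment on a log-normalized matrix.

        ``labels`` must cover every barcode; ``gene_subset`` optionally
        restricts the genes tested (and hence the Bonferroni m).
        """
        types = labels.loc[X.obs_names, "cell_type"].to_numpy()
        unique_types = [t for t in pd.unique(types)]
        if len(unique_types) < 2:
            raise ValueError("need at least 2 cell types")
        if gene_subset is not None:
            keep = [g for g in X.var_names if g in set(gene_subset)]
            X = X[:, keep]
        x = X.X
        dense = np.asarray(x.todense()) if sparse.issparse(x) else np.asarray(x)
        dense = dense.astype(np.float64)
        n_cells, n_genes = dense.shape

        ranks = np.empty_like(dense)
        tie_terms = np.empty(n_genes)
        for j in range(n_genes):
            ranks[:, j] = _sps.rankdata(dense[:, j])
            _, counts = np.unique(dense[:, j], return_counts=True)
            tie_terms[j] = float((counts**3 - counts).sum())

        detected = dense > 0
        rows = []
        for t in unique_types:
            mask = types == t
            n1 = int(mask.sum())
            n2 = n_cells - n1
            if n1 < self.min_cells:
                warnings.warn(
                    f"cell type {t!r} has {n1} cells (< {self.min_cells}); skipped",
                    stacklevel=2,
                )
                continue
            w = ranks[mask].sum(axis=0)
            mu = n1 * (n_cells + 1) / 2.0
            var = (
                n1
                * n2
                / 12.0
                * ((n_cells + 1) - tie_terms / (n_cells * (n_cells - 1)))
            )
            sd = np.sqrt(np.maximum(var, 0.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (np.abs(w - mu) - 0.5) / sd
            p = np.where(sd > 0, 2.0 * _sps.norm.sf(np.maximum(z, 0.0)), 1.0)
            p = np.minimum(p, 1.0)
            rows.append(
                pd.DataFrame(
                    {
                        "gene_id": X.var_names,
                        "cell_type": t,
                        "mean_in": dense[mask].mean(axis=0),
                        "mean_out": dense[~mask].mean(axis=0),
                        "pct_in": detected[mask].mean(axis=0),
                        "pct_out": detected[~mask].mean(axis=0),
                        "raw_p": p,
                    }
                )
            )
        out = pd.concat(rows, ignore_index=True)
        self.m_ = n_genes
        # one Bonferroni family per cell-type sweep: m = genes tested
        out["adj_p"] = np.minimum(1.0, out["raw_p"].to_numpy() * self.m_)
        self.results_ = out
        return self


def enrich_one_vs_rest(
    nm: ad.AnnData, labels: pd.DataFrame, gene_subset=None, min_cells: int = 3
) -> pd.DataFrame:
    """One-vs-rest marker enrichment table (see MarkerEnrichment)."""
    return MarkerEnrichment(min_cells).fit(nm, labels, gene_subset).results_


def annotate_clusters(
    enrich: pd.DataFrame, rules: list[MarkerRule], alpha: float = 0.05
) -> dict:
    """Assign a cell type to each cluster from ordered marker rules.

    A gene counts as enriched in a cluster when adj_p < alpha and
    mean_in > mean_out. Rules naming genes absent from the enrichment table
    are skipped with a warning. Unmatched clusters map to "unassigned".
    """
    genes_present = set(enrich["gene_id"])
    usable = []
    for rule in rules:
        missing = (rule.required | rule.excluded) - genes_present
        if missing:
            warnings.warn(
                f"rule {rule.cell_type!r}: marker(s) {sorted(missing)} absent from "
                "data; rule skipped",
                stacklevel=2,
            )
            continue
        usable.append(rule)

    sig = enrich[(enrich["adj_p"] < alpha) & (enrich["mean_in"] > enrich["mean_out"])]
    enriched_by_cluster = sig.groupby("cell_type")["gene_id"].agg(set).to_dict()

    assignment = {}
    for cluster in pd.unique(enrich["cell_type"]):
        enriched = enriched_by_cluster.get(cluster, set())
        assignment[cluster] = "unassigned"
        for rule in usable:
            if rule.required <= enriched and not (rule.excluded & enriched):
                assignment[cluster] = rule.cell_type
                break
    return assignment
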