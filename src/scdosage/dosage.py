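"""X-versus-autosome dosage-compensation inference.

The central question: does a given cell type along the spermatogenesis
trajectory transcribe its single X chromosome at the per-gene level of the
diploid autosomes? Operationally, for each cell type we sum UMI counts per
gene over the cells of that type, compare the log2(counts+1) distribution of
X-linked genes against autosomal genes with a two-sided Wilcoxon rank-sum
test, correct across cell types with Holm's step-down, and classify:

* ``DC`` (dosage compensated) - no significant X/autosome difference;
* ``Excess DC`` - X significantly above autosomes (X median > A median);
* ``No DC`` - X significantly below autosomes.

The X:A ratio reported alongside is the ratio of per-gene medians of raw
summed counts (not log-transformed). Chromosome-level RNA content per cell
(summed UMIs divided by cell count) is computed separately as a coarser
companion statistic. Robustness reruns drop flagged gene classes
(testis-specific / testis-biased, optionally X-restricted) and report which
cell-type interpretations change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator

from .preprocess import log2p1
from .stats import holm_adjust, wilcoxon_rank_sum

__all__ = [
    "AUTOSOMES",
    "GeneClassFilter",
    "DosageCompensationTest",
    "gene_counts_by_celltype",
    "chrom_umi_per_cell",
    "xa_ratio",
    "dc_test",
    "classify_dc",
    "scaled_dc_test",
    "exclusion_rerun",
]

AUTOSOMES = ("2L", "2R", "3L", "3R", "4")

FilterMode = Literal[
    "none",
    "drop_testis_specific",
    "drop_testis_biased",
    "drop_x_male_specific",
    "drop_x_male_biased",
]


def gene_counts_by_celltype(cm: ad.AnnData, labels: pd.DataFrame) -> pd.DataFrame:
    """Sum raw UMI counts per gene within each cell type.

    Returns a genes x cell-types DataFrame of integer totals. Grand total
    equals the matrix grand total (conservation). Cell types with zero
    cells simply have no column.
    """
    missing = pd.Index(cm.obs_names).difference(labels.index)
    if len(missing):
        raise ValueError(f"barcodes without labels: {list(missing[:5])}")
    types = labels.loc[cm.obs_names, "cell_type"].to_numpy()
    x = cm.X
    if not sparse.issparse(x):
        x = sparse.csr_matrix(x)
    x = x.tocsr()
    cols = {}
    for t in pd.unique(types):
        mask = types == t
        cols[t] = np.asarray(x[mask].sum(axis=0)).ravel().astype(np.int64)
    return pd.DataFrame(cols, index=pd.Index(cm.var_names, name="gene_id"))


def _chrom_groups(genes: pd.DataFrame, autosomes: Sequence[str]) -> dict[str, pd.Index]:
    chrom = genes["chromosome"]
    return {
        "X": genes.index[chrom == "X"],
        "autosomes": genes.index[chrom.isin(list(autosomes))],
        "Y": genes.index[chrom == "Y"],
    }


def chrom_umi_per_cell(
    g: pd.DataFrame,
    genes: pd.DataFrame,
    labels: pd.DataFrame,
    autosomes: Sequence[str] = AUTOSOMES,
) -> pd.DataFrame:
    """Per-cell RNA content by chromosome group for each cell type.

    For each cell type and group (X, autosomes) the summed UMIs across the
    group's genes are divided by the number of cells of that type; X rows
    additionally carry the X:A content ratio. A proxy for relative RNA
    content per cell, not absolute molecule numbers.
    """
    groups = _chrom_groups(genes, autosomes)
    n_cells = labels["cell_type"].value_counts()
    rows = []
    for t in g.columns:
        if t not in n_cells.index or n_cells[t] == 0:
            warnings.warn(f"cell type {t!r} has zero cells; skipped", stacklevel=2)
            continue
        nc = int(n_cells[t])
        per_group = {}
        for name in ("X", "autosomes"):
            ids = groups[name].intersection(g.index)
            total = int(g.loc[ids, t].sum())
            per_group[name] = total / nc
            rows.append(
                {
                    "cell_type": t,
                    "chromosome_group": name,
                    "total_umis": total,
                    "n_cells": nc,
                    "umis_per_cell": total / nc,
                    "xa_content_ratio": np.nan,
                }
            )
        if per_group["autosomes"] > 0:
            for row in rows:
                if row["cell_type"] == t and row["chromosome_group"] == "X":
                    row["xa_content_ratio"] = per_group["X"] / per_group["autosomes"]
    return pd.DataFrame(rows)


def _group_counts(
    g: pd.DataFrame,
    genes: pd.DataFrame,
    cell_type: str,
    autosomes: Sequence[str],
    nonzero_only: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    groups = _chrom_groups(genes, autosomes)
    x_ids = groups["X"].intersection(g.index)
    a_ids = groups["autosomes"].intersection(g.index)
    x = g.loc[x_ids, cell_type].to_numpy(dtype=np.float64)
    a = g.loc[a_ids, cell_type].to_numpy(dtype=np.float64)
    if nonzero_only:
        x = x[x > 0]
        a = a[a > 0]
    return x, a


def xa_ratio(
    g: pd.DataFrame,
    genes: pd.DataFrame,
    cell_type: str,
    autosomes: Sequence[str] = AUTOSOMES,
    nonzero_only: bool = False,
) -> float:
    """X:A ratio of per-gene median raw summed counts for one cell type.

    Genes with zero counts in the cell type are retained as long as they
    passed the global detection filter (``nonzero_only=False``, the
    default); a per-type nonzero restriction is available for sensitivity
    analysis. Returns NaN with a warning when the autosomal median is 0.
    """
    x, a = _group_counts(g, genes, cell_type, autosomes, nonzero_only)
    if x.size == 0 or a.size == 0:
        raise ValueError(f"no X or autosomal genes for cell type {cell_type!r}")
    a_med = float(np.median(a))
    if a_med == 0:
        warnings.warn(
            f"autosomal median is 0 in {cell_type!r}: X:A ratio undefined",
            stacklevel=2,
        )
        return float("nan")
    return float(np.median(x)) / a_med


def classify_dc(
    xa_ratio: float,
    adj_p: float,
    x_median: float,
    a_median: float,
    alpha: float = 0.05,
) -> str:
    """Map a cell type's adjusted p and median direction to a DC call.

    Non-significant -> "DC"; significant with X median above autosomal
    median -> "Excess DC"; significant with X below -> "No DC". A
    significant result with exactly tied medians (possible only through
    heavy-tailed asymmetry) falls back to "DC" with a warning.
    """
    if not 0.0 <= adj_p <= 1.0:
        raise ValueError(f"adjusted p outside [0, 1]: {adj_p}")
    if adj_p >= alpha:
        return "DC"
    if x_median > a_median:
        return "Excess DC"
    if x_median < a_median:
        return "No DC"
    warnings.warn(
        "significant test with exactly tied medians; defaulting to DC", stacklevel=2
    )
    return "DC"


@dataclass
class GeneClassFilter:
    """A gene-class exclusion for robustness reruns.

    ``mode`` selects which annotation flag drives the exclusion;
    ``x_only`` variants restrict the exclusion to X-linked genes.
    """

    mode: FilterMode = "none"
    gene_ids_removed: set = field(default_factory=set)

    def resolve(self, genes: pd.DataFrame) -> set:
        if self.mode == "none":
            removed: set = set()
        elif self.mode == "drop_testis_specific":
            removed = set(genes.index[genes["testis_specific"]])
        elif self.mode == "drop_testis_biased":
            removed = set(genes.index[genes["testis_biased"]])
        elif self.mode == "drop_x_male_specific":
            removed = set(
                genes.index[genes["testis_specific"] & (genes["chromosome"] == "X")]
            )
        elif self.mode == "drop_x_male_biased":
            removed = set(
                genes.index[genes["testis_biased"] & (genes["chromosome"] == "X")]
            )
        else:
            raise ValueError(f"unknown filter mode {self.mode!r}")
        self.gene_ids_removed = removed
        return removed


class DosageCompensationTest(BaseEstimator):
    """Per-cell-type X-vs-autosome dosage-compensation test.

    Parameters
    ----------
    alpha
        Familywise significance level for the classification.
    autosomes
        Chromosome labels forming the autosomal reference set. Chromosome 4
        is included by default; pass ``("2L", "2R", "3L", "3R")`` to drop
        it. Y and anything not listed never enter the autosomal side.
    nonzero_only
        Restrict each cell type's gene sets to genes with nonzero counts in
        that type (sensitivity analysis; default keeps zeros for genes that
        passed the global detection filter).
    min_genes
        Cell types with fewer genes than this on either side are skipped
        with a warning.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per tested cell type: cell_type, xa_ratio, x_median,
        a_median, total_ratio (X/A of summed totals, for transparency),
        raw_p, adj_p, interpretation.
    family_size_ : int
        Number of cell types in the Holm family (all types tested in this
        run).
    """

    def __init__(
        self,
        alpha: float = 0.05,
        autosomes: Sequence[str] = AUTOSOMES,
        nonzero_only: bool = False,
        min_genes: int = 3,
    ):
        self.alpha = alpha
        self.autosomes = autosomes
        self.nonzero_only = nonzero_only
        self.min_genes = min_genes

    def fit(self, X: pd.DataFrame, genes: pd.DataFrame):
        """Run the test.

        Parameters
        ----------
        X
            Genes x cell-types table of raw summed counts
            (from :func:`gene_counts_by_celltype`).
        genes
            Gene annotation indexed by gene_id with a ``chromosome`` column.
        """
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if X.shape[1] < 2:
            raise ValueError("need at least 2 cell types for a Holm family")
        rows = []
        for t in X.columns:
            xv, av = _group_counts(X, genes, t, self.autosomes, self.nonzero_only)
            if xv.size < self.min_genes or av.size < self.min_genes:
                warnings.warn(
                    f"cell type {t!r}: fewer than {self.min_genes} genes on one "
                    "side; skipped",
                    stacklevel=2,
                )
                continue
            res = wilcoxon_rank_sum(log2p1(xv), log2p1(av))
            a_med = float(np.median(av))
            a_tot = float(av.sum())
            rows.append(
                {
                    "cell_type": t,
                    "xa_ratio": float(np.median(xv)) / a_med if a_med else np.nan,
                    "x_median": float(np.median(xv)),
                    "a_median": a_med,
                    "total_ratio": float(xv.sum()) / a_tot if a_tot else np.nan,
                    "raw_p": res.p_value,
                    "n_x": res.n1,
                    "n_a": res.n2,
                }
            )
        if not rows:
            raise ValueError("no cell type had enough genes to test")
        df = pd.DataFrame(rows)
        df["adj_p"] = holm_adjust(df["raw_p"].to_numpy())
        df["interpretation"] = [
            classify_dc(r.xa_ratio, r.adj_p, r.x_median, r.a_median, self.alpha)
            for r in df.itertuples()
        ]
        self.results_ = df
        self.family_size_ = len(df)
        return self


def dc_test(
    g: pd.DataFrame,
    genes: pd.DataFrame,
    alpha: float = 0.05,
    autosomes: Sequence[str] = AUTOSOMES,
    nonzero_only: bool = False,
) -> pd.DataFrame:
    """Dosage-compensation test per cell type (see DosageCompensationTest)."""
    est = DosageCompensationTest(
        alpha=alpha, autosomes=autosomes, nonzero_only=nonzero_only
    )
    return est.fit(g, genes).results_


def scaled_dc_test(
    scaled: pd.DataFrame,
    genes: pd.DataFrame,
    group: Literal["X", "Y"] = "X",
    direction: Literal["greater", "less"] = "greater",
    alpha: float = 0.05,
    autosomes: Sequence[str] = AUTOSOMES,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Directional per-cell-type test of scaled group genes vs autosomes.

    ``scaled`` is a genes x cell-types matrix from per-gene scaling. For
    each cell type, a one-sided rank-sum test asks whether the scaled
    expression of ``group`` genes exceeds ("greater") or falls below
    ("less") that of autosomal genes, Holm-corrected across cell types.
    """
    groups = _chrom_groups(genes, autosomes)
    g_ids = groups[group].intersection(scaled.index)
    a_ids = groups["autosomes"].intersection(scaled.index)
    if len(g_ids) == 0:
        raise ValueError(f"no genes on chromosome group {group!r}")
    rows = []
    for t in scaled.columns:
        gv = scaled.loc[g_ids, t].to_numpy(dtype=np.float64)
        av = scaled.loc[a_ids, t].to_numpy(dtype=np.float64)
        if gv.size < min_genes or av.size < min_genes:
            warnings.warn(f"cell type {t!r}: too few genes; skipped", stacklevel=2)
            continue
        res = wilcoxon_rank_sum(gv, av, alternative=direction)
        rows.append(
            {
                "cell_type": t,
                "group": group,
                "direction": direction,
                "group_median": float(np.median(gv)),
                "a_median": float(np.median(av)),
                "raw_p": res.p_value,
            }
        )
    df = pd.DataFrame(rows)
    df["adj_p"] = holm_adjust(df["raw_p"].to_numpy())
    df["significant"] = df["adj_p"] < alpha
    return df


def exclusion_rerun(
    cm_counts: pd.DataFrame,
    genes: pd.DataFrame,
    gene_filter: GeneClassFilter,
    alpha: float = 0.05,
    autosomes: Sequence[str] = AUTOSOMES,
    nonzero_only: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rerun the DC test after excluding a flagged gene class.

    Parameters
    ----------
    cm_counts
        Genes x cell-types summed counts (the full universe).
    gene_filter
        Which gene class to drop (see :class:`GeneClassFilter`).

    Returns
    -------
    (results, delta)
        ``results`` is the DC table on the reduced universe; ``delta`` has
        one row per cell type whose interpretation changed (columns
        cell_type, before, after). Empty delta when nothing changes.
    """
    removed = gene_filter.resolve(genes)
    keep = cm_counts.index.difference(removed)
    reduced = cm_counts.loc[keep]
    reduced_genes = genes.loc[genes.index.intersection(keep)]
    x_left = (reduced_genes["chromosome"] == "X").sum()
    a_left = reduced_genes["chromosome"].isin(list(autosomes)).sum()
    if x_left == 0 or a_left == 0:
        raise ValueError("gene-class filter emptied the X or autosome set")
    before = dc_test(cm_counts, genes, alpha, autosomes, nonzero_only)
    after = dc_test(reduced, reduced_genes, alpha, autosomes, nonzero_only)
    merged = before[["cell_type", "interpretation"]].merge(
        after[["cell_type", "interpretation"]],
        on="cell_type",
        suffixes=("_before", "_after"),
    )
    changed = merged[merged["interpretation_before"] != merged["interpretation_after"]]
    delta = changed.rename(
        columns={"interpretation_before": "before", "interpretation_after": "after"}
    ).reset_index(drop=True)
    return after, delta
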