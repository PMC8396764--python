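import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

import scdosage as sd

# Published per-cell-type worked example: X:A ratio of raw-count medians,
# raw and Holm-adjusted p of the two-sided rank-sum test, and the resulting
# dosage-compensation interpretation.
XA_TABLE = pd.DataFrame(
    [
        ("hub", 1.00, 1.43e-01, 2.86e-01, "DC"),
        ("cyst", 1.17, 2.34e-02, 8.24e-02, "DC"),
        ("epithelial", 0.92, 1.63e-01, 2.86e-01, "DC"),
        ("GSC/early spermatogonia", 1.83, 6.44e-05, 3.86e-04, "Excess DC"),
        ("late spermatogonia", 0.85, 2.06e-02, 8.24e-02, "DC"),
        ("early spermatocytes", 0.66, 5.35e-08, 4.82e-07, "No DC"),
        ("late spermatocytes", 0.63, 6.69e-08, 5.35e-07, "No DC"),
        ("early spermatids", 0.70, 1.65e-05, 1.16e-04, "No DC"),
        ("late spermatids", 0.77, 1.30e-04, 6.50e-04, "No DC"),
    ],
    columns=["cell_type", "xa_ratio", "raw_p", "adj_p", "interpretation"],
)

# Published CES proximity worked example: close (<10 kb) and distant median
# counts, their ratio, raw and Holm-adjusted p, and the DCC-activity call.
CES_TABLE = pd.DataFrame(
    [
        ("hub", 16.0, 10.0, 1.6, 1.06e-04, 7.42e-04, "Active DCC"),
        ("cyst", 31.5, 16.0, 1.97, 1.38e-09, 1.24e-08, "Active DCC"),
        ("epithelial", 15.0, 9.0, 1.67, 2.65e-04, 1.59e-03, "Active DCC"),
        ("GSC/early spermatogonia", 21.0, 8.0, 2.63, 5.08e-09, 4.06e-08, "Active DCC"),
        ("late spermatogonia", 451.5, 275.0, 1.64, 7.65e-03, 3.82e-02, "Active DCC"),
        ("early spermatocytes", 490.5, 362.0, 1.35, 7.69e-02, 1.54e-01, "Inactive DCC"),
        ("late spermatocytes", 174.5, 132.0, 1.32, 8.41e-02, 1.54e-01, "Inactive DCC"),
        ("early spermatids", 150.0, 107.0, 1.4, 3.99e-02, 1.20e-01, "Inactive DCC"),
        ("late spermatids", 12.0, 9.0, 1.33, 2.31e-02, 9.24e-02, "Inactive DCC"),
    ],
    columns=[
        "cell_type",
        "median_close",
        "median_far",
        "close_far_ratio",
        "raw_p",
        "adj_p",
        "interpretation",
    ],
)


def round_sig3(x: float) -> float:
    return sd.ces.round_sig(x, 3)


def matches_printed(got: float, want: float) -> bool:
    """Agreement with a 3-significant-figure printed value.

    Allows one unit in the last printed digit: printed inputs are
    themselves rounded, so recomputed quantities can land on a half
    boundary (e.g. 7.65e-3 * 5 = 3.825e-2 against a printed 3.82e-2).
    """
    import math

    ulp = 10.0 ** (math.floor(math.log10(abs(want))) - 2)
    return abs(round_sig3(got) - want) <= ulp + 1e-12


def tiny_adata(counts: np.ndarray, barcodes=None, genes=None) -> ad.AnnData:
    counts = np.asarray(counts)
    n, m = counts.shape
    adata = ad.AnnData(X=sparse.csr_matrix(counts.astype(np.int64)))
    adata.obs_names = barcodes or [f"bc{i}" for i in range(n)]
    adata.var_names = genes or [f"g{j}" for j in range(m)]
    return adata


@pytest.fixture(scope="session")
def study_dataset():
    """One seeded dataset from the stylized study-design generator."""
    return sd.generate(sd.default_study_config(seed=7))


@pytest.fixture(scope="session")
def study_counts(study_dataset):
    adata, genes, labels, ces, truth = study_dataset
    counts = sd.gene_counts_by_celltype(adata, labels)
    return counts, genes, ces, truth
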