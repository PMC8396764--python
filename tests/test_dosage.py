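import numpy as np
import pandas as pd
import pytest

import scdosage as sd
from tests.conftest import XA_TABLE, tiny_adata


def annotation(chroms, flags=None):
    n = len(chroms)
    df = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "chromosome": chroms,
            "start": np.arange(1, n + 1) * 1000,
            "end": np.arange(1, n + 1) * 1000 + 500,
            "strand": "+",
            "testis_specific": False,
            "testis_biased": False,
        }
    ).set_index("gene_id", drop=False)
    if flags:
        df.loc[flags, "testis_specific"] = True
    return df


def labels_for(barcodes, types):
    return pd.DataFrame(
        {"barcode": barcodes, "cell_type": types, "strain": "t"}
    ).set_index("barcode", drop=False)


class TestGeneCountsByCelltype:
    def test_summation(self):
        adata = tiny_adata([[3, 1], [4, 0], [2, 2]])
        lab = labels_for(adata.obs_names, ["A", "A", "B"])
        g = sd.gene_counts_by_celltype(adata, lab)
        assert g.loc["g0", "A"] == 7 and g.loc["g0", "B"] == 2

    def test_conservation(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 9, size=(30, 20))
        adata = tiny_adata(counts)
        lab = labels_for(adata.obs_names, rng.choice(["A", "B", "C"], 30))
        g = sd.gene_counts_by_celltype(adata, lab)
        assert g.to_numpy().sum() == counts.sum()
        for t in ("A", "B", "C"):
            assert g[t].sum() == counts[lab["cell_type"] == t].sum()

    def test_missing_label_fatal(self):
        adata = tiny_adata([[1]])
        with pytest.raises(ValueError, match="bc0"):
            sd.gene_counts_by_celltype(adata, labels_for(["other"], ["A"]))


class TestChromContent:
    def test_single_cell_ratio(self):
        g = pd.DataFrame({"A": [10, 100]},
                         index=pd.Index(["g0", "g1"], name="gene_id"))
        genes = annotation(["X", "2L"])
        lab = labels_for(["b0"], ["A"])
        rows = sd.chrom_umi_per_cell(g, genes, lab)
        x_row = rows[(rows.chromosome_group == "X")].iloc[0]
        assert x_row["umis_per_cell"] == 10.0
        assert x_row["xa_content_ratio"] == pytest.approx(0.10)

    def test_identical_composition_identical_ratios(self):
        g = pd.DataFrame({"A": [5, 20], "B": [10, 40]},
                         index=pd.Index(["g0", "g1"], name="gene_id"))
        genes = annotation(["X", "3R"])
        lab = labels_for(["b0", "b1", "b2"],
                         ["A", "B", "B"])
        rows = sd.chrom_umi_per_cell(g, genes, lab)
        ratios = rows.dropna(subset=["xa_content_ratio"])
        assert ratios["xa_content_ratio"].nunique() == 1

    def test_conservation_against_matrix_total(self, study_dataset):
        adata, genes, lab, _, _ = study_dataset
        g = sd.gene_counts_by_celltype(adata, lab)
        rows = sd.chrom_umi_per_cell(g, genes, lab)
        xa_total = rows["total_umis"].sum()
        mask = genes["chromosome"].isin(["X"] + list(sd.AUTOSOMES))
        assert xa_total == int(g.loc[genes.index[mask]].to_numpy().sum())


class TestXaRatio:
    def test_equal_medians(self):
        g = pd.DataFrame({"A": [5, 7, 9, 7]},
                         index=pd.Index([f"g{i}" for i in range(4)], name="gene_id"))
        genes = annotation(["X", "X", "X", "2L"])
        assert sd.xa_ratio(g, genes, "A") == pytest.approx(1.0)

    def test_even_length_median_midpoint(self):
        g = pd.DataFrame({"A": [2, 4, 8]},
                         index=pd.Index(["g0", "g1", "g2"], name="gene_id"))
        genes = annotation(["X", "X", "3L"])
        assert sd.xa_ratio(g, genes, "A") == pytest.approx(0.375)

    def test_matches_bruteforce_median(self, study_counts):
        counts, genes, _, _ = study_counts
        t = counts.columns[3]
        x_vals = sorted(
            counts.loc[gid, t]
            for gid in counts.index
            if genes.loc[gid, "chromosome"] == "X"
        )
        a_vals = sorted(
            counts.loc[gid, t]
            for gid in counts.index
            if genes.loc[gid, "chromosome"] in sd.AUTOSOMES
        )

        def med(v):
            n = len(v)
            return (v[n // 2] if n % 2 else (v[n // 2 - 1] + v[n // 2]) / 2)

        assert sd.xa_ratio(counts, genes, t) == pytest.approx(
            med(x_vals) / med(a_vals)
        )

    def test_zero_autosomal_median_flagged(self):
        g = pd.DataFrame({"A": [5, 0]},
                         index=pd.Index(["g0", "g1"], name="gene_id"))
        genes = annotation(["X", "2R"])
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(sd.xa_ratio(g, genes, "A"))


class TestClassifyDc:
    @pytest.mark.parametrize(
        "row", list(XA_TABLE.itertuples()), ids=list(XA_TABLE.cell_type)
    )
    def test_published_rows(self, row):
        x_med, a_med = (2.0, 1.0) if row.xa_ratio > 1 else (1.0, 2.0)
        if row.xa_ratio == 1.0:
            x_med = a_med = 1.0
        call = sd.classify_dc(row.xa_ratio, row.adj_p, x_med, a_med)
        assert call == row.interpretation

    def test_direction_decides_significant_calls(self):
        assert sd.classify_dc(1.5, 0.001, 3.0, 2.0) == "Excess DC"
        assert sd.classify_dc(0.7, 0.001, 2.0, 3.0) == "No DC"
        assert sd.classify_dc(0.7, 0.5, 2.0, 3.0) == "DC"

    def test_tied_medians_warn(self):
        with pytest.warns(UserWarning, match="tied"):
            assert sd.classify_dc(1.0, 0.001, 2.0, 2.0) == "DC"


class TestDcTest:
    def test_three_factor_recovery(self):
        """Dosage factors {1.0, 1.8, 0.5} recover {DC, Excess DC, No DC}."""
        cfg = sd.default_study_config(seed=42)
        cfg.n_cells_per_type = {"a": 120, "b": 120, "c": 120}
        cfg.depth_per_type = {"a": 6000, "b": 6000, "c": 6000}
        cfg.dosage_factor = {"a": 1.0, "b": 1.8, "c": 0.5}
        cfg.ces_active = {"a": False, "b": False, "c": False}
        cfg.ces_beta = 0.0
        adata, genes, lab, _, _ = sd.generate(cfg)
        res = sd.dc_test(sd.gene_counts_by_celltype(adata, lab), genes)
        got = res.set_index("cell_type")["interpretation"]
        assert got["a"] == "DC" and got["b"] == "Excess DC" and got["c"] == "No DC"

    def test_identical_distributions_p_one(self):
        g = pd.DataFrame({"A": [1, 2, 3, 1, 2, 3], "B": [4, 5, 6, 4, 5, 6]},
                         index=pd.Index([f"g{i}" for i in range(6)], name="gene_id"))
        genes = annotation(["X"] * 3 + ["2L"] * 3)
        res = sd.dc_test(g, genes).set_index("cell_type")
        assert (res["raw_p"] == 1.0).all()
        assert (res["interpretation"] == "DC").all()

    def test_family_size_is_number_of_celltypes(self, study_counts):
        counts, genes, _, _ = study_counts
        est = sd.DosageCompensationTest().fit(counts, genes)
        assert est.family_size_ == counts.shape[1] == 9
        np.testing.assert_allclose(
            est.results_["adj_p"], sd.holm_adjust(est.results_["raw_p"].to_numpy())
        )

    def test_pvalues_invariant_to_log_transform(self, study_counts):
        """Rank tests agree on raw and log2(x+1) counts, so the published
        choice of testing log values is equivalent to testing raw counts."""
        counts, genes, _, _ = study_counts
        raw = sd.dc_test(counts, genes)
        logged = sd.dc_test(
            np.round(np.log2(counts + 1) * 1e6).astype(int), genes
        )
        np.testing.assert_allclose(raw["raw_p"], logged["raw_p"], rtol=1e-9)

    def test_sklearn_param_interface(self):
        est = sd.DosageCompensationTest(alpha=0.01)
        assert est.get_params()["alpha"] == 0.01
        est.set_params(nonzero_only=True)
        assert est.nonzero_only


class TestScaledDcTest:
    def test_constructed_shift_detected_in_one_type(self):
        rng = np.random.default_rng(13)
        n = 300
        genes = annotation(["X"] * n + ["2L"] * n)
        base = rng.normal(0, 1, size=(2 * n, 4))
        g = pd.DataFrame(base, index=genes.index, columns=list("ABCD"))
        g.loc[genes.index[:n], "B"] += 1.2  # X genes shifted up in B only
        scaled = sd.scale_per_gene(g - g.min().min() + 1, "center")
        res = sd.scaled_dc_test(scaled, genes, "X", "greater").set_index("cell_type")
        assert res.loc["B", "significant"]
        assert not res.loc[["A", "C", "D"], "significant"].any()

    def test_null_never_significant(self):
        rng = np.random.default_rng(14)
        genes = annotation(["X"] * 100 + ["3R"] * 100)
        g = pd.DataFrame(rng.random((200, 5)) + 0.5, index=genes.index)
        scaled = sd.scale_per_gene(g, "center")
        res = sd.scaled_dc_test(scaled, genes, "X", "greater")
        assert (res["adj_p"] >= 0.05).all()

    def test_direction_reversal_flips_tail(self):
        rng = np.random.default_rng(15)
        genes = annotation(["X"] * 150 + ["2R"] * 150)
        g = pd.DataFrame(rng.random((300, 3)) + 0.5, index=genes.index)
        g.iloc[:150, 0] += 2.0
        scaled = sd.scale_per_gene(g, "center")
        up = sd.scaled_dc_test(scaled, genes, "X", "greater")
        down = sd.scaled_dc_test(scaled, genes, "X", "less")
        assert up.loc[0, "significant"] and not down.loc[0, "significant"]


class TestExclusionRerun:
    def test_noop_filter_identity(self, study_counts):
        counts, genes, _, _ = study_counts
        res, delta = sd.exclusion_rerun(counts, genes, sd.GeneClassFilter("none"))
        base = sd.dc_test(counts, genes)
        pd.testing.assert_frame_equal(res, base)
        assert delta.empty

    def test_flag_driven_excess_disappears(self):
        """When apparent excess compensation is carried entirely by flagged
        X-linked genes, excluding them demotes the call to plain DC."""
        cfg = sd.default_study_config(seed=21)
        cfg.dosage_factor = {t: 1.0 for t in cfg.dosage_factor}
        cfg.ces_active = {t: False for t in cfg.ces_active}
        cfg.ces_beta = 0.0
        cfg.testis_specific_fraction = 0.3
        cfg.testis_flags_x_only = True
        cfg.testis_specific_boost = {"GSC/early spermatogonia": 6.0}
        adata, genes, lab, _, _ = sd.generate(cfg)
        counts = sd.gene_counts_by_celltype(adata, lab)
        flt = sd.GeneClassFilter("drop_testis_specific")
        before = sd.dc_test(counts, genes).set_index("cell_type")
        after, delta = sd.exclusion_rerun(counts, genes, flt)
        after = after.set_index("cell_type")
        gsc = "GSC/early spermatogonia"
        assert before.loc[gsc, "interpretation"] == "Excess DC"
        assert after.loc[gsc, "interpretation"] == "DC"
        assert gsc in set(delta["cell_type"])

    def test_emptying_x_side_rejected(self):
        g = pd.DataFrame({"A": [1, 2], "B": [3, 4]},
                         index=pd.Index(["g0", "g1"], name="gene_id"))
        genes = annotation(["X", "2L"], flags=["g0"])
        with pytest.raises(ValueError, match="emptied"):
            sd.exclusion_rerun(g, genes, sd.GeneClassFilter("drop_testis_specific"))
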