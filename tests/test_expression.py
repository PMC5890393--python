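import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import spongelnc as sl

from conftest import make_matrix, make_meta


class TestFilterSamples:
    def test_threshold_is_strictly_less_than(self):
        m = make_matrix([[5, 5, 5]], samples=["a", "b", "c"])
        meta = make_meta(["a", "b", "c"], ["g1"] * 3,
                         [2_000_000, 1_000_000, 999_999])
        kept = sl.filter_samples(m, meta)
        assert list(kept.samples) == ["a", "b"]

    def test_all_passing_is_identity(self, tiny_matrix):
        meta = make_meta(["s1", "s2", "s3"], ["x", "y", "z"])
        kept = sl.filter_samples(tiny_matrix, meta)
        pd.testing.assert_frame_equal(kept.counts, tiny_matrix.counts)

    def test_empty_result_names_discarded_samples(self):
        m = make_matrix([[5, 5]], samples=["a", "b"])
        meta = make_meta(["a", "b"], ["g", "g"], [10, 20])
        with pytest.raises(ValueError, match="a, b"):
            sl.filter_samples(m, meta)

    def test_planted_39_to_31(self, bundle):
        kept = sl.filter_samples(bundle.counts_celltype_a,
                                 bundle.meta_celltype_a)
        assert len(bundle.counts_celltype_a.samples) == 39
        assert len(kept.samples) == 31
        assert set(bundle.truth["subthreshold_samples"]).isdisjoint(kept.samples)


class TestNormalization:
    def test_identical_columns_give_unit_factors(self):
        m = make_matrix([[10, 10, 10], [7, 7, 7]])
        norm = sl.normalize_median_of_ratios(m)
        np.testing.assert_allclose(norm.size_factors.values, 1.0)

    def test_scale_equivariance_and_hand_computed_factors(self, tiny_matrix):
        norm = sl.normalize_median_of_ratios(tiny_matrix)
        sf = norm.size_factors
        # column s2 = 2 x s1 elementwise; factors proportional to (1, 2, 1)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)
        assert sf["s3"] / sf["s1"] == pytest.approx(1.0)
        np.testing.assert_allclose(
            norm.normalized["s1"].values, norm.normalized["s2"].values)

    def test_fallback_to_library_size(self, caplog):
        m = make_matrix([[10, 0], [0, 10]])
        with caplog.at_level("WARNING", logger="spongelnc"):
            norm = sl.normalize_median_of_ratios(m)
        assert "library-size" in caplog.text
        np.testing.assert_allclose(norm.size_factors.values, 1.0)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert sl.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(sl.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_nan_passthrough(self):
        q = sl.bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not np.isnan(q[0])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            sl.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_q_at_least_p_and_matches_statsmodels(self, pvals):
        q = sl.bh_adjust(pvals)
        assert (q >= np.asarray(pvals) - 1e-12).all()
        from statsmodels.stats.multitest import multipletests
        expected = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(q, expected, atol=1e-12)


class TestDETest:
    @pytest.fixture
    def two_group_setup(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(50, size=(30, 8))
        counts[0] = 0  # all-zero gene
        samples = [f"s{i}" for i in range(8)]
        m = make_matrix(counts.tolist(), samples=samples)
        meta = make_meta(samples, ["A"] * 4 + ["B"] * 4)
        return sl.normalize_median_of_ratios(m), meta

    def test_all_zero_gene_gets_na(self, two_group_setup):
        m, meta = two_group_setup
        res = sl.de_test_pairwise(m, meta, "A", "B")
        assert np.isnan(res.loc[res["gene"] == "g0", "p"]).all()
        assert np.isnan(res.loc[res["gene"] == "g0", "Q"]).all()

    def test_contrast_swap_negates_lfc_keeps_p(self, two_group_setup):
        m, meta = two_group_setup
        ab = sl.de_test_pairwise(m, meta, "A", "B")
        ba = sl.de_test_pairwise(m, meta, "B", "A")
        np.testing.assert_allclose(ab["log2fc"].dropna().values,
                                   -ba["log2fc"].dropna().values)
        np.testing.assert_allclose(ab["p"].dropna().values,
                                   ba["p"].dropna().values)

    def test_missing_group_errors(self, two_group_setup):
        m, meta = two_group_setup
        with pytest.raises(ValueError, match="absent"):
            sl.de_test_pairwise(m, meta, "A", "C")

    def test_sample_order_permutation_invariance(self, two_group_setup):
        m, meta = two_group_setup
        perm = list(m.samples)[::-1]
        m2 = sl.ExpressionMatrix(m.counts[perm], m.biotype)
        m2 = sl.normalize_median_of_ratios(m2)
        r1 = sl.de_test_pairwise(m, meta, "A", "B")
        r2 = sl.de_test_pairwise(m2, meta, "A", "B")
        np.testing.assert_allclose(r1["p"].values, r2["p"].values,
                                   equal_nan=True)

    def test_power_on_planted_fourfold_change(self):
        """Regression floor from the pre-build simulation: power ~0.996.

        Only a tenth of the genes carry the 4-fold change so the size-factor
        normalization is anchored by the null majority.
        """
        rng = np.random.default_rng(17)
        n_genes, n_de = 300, 30
        mu = rng.uniform(20, 500, size=n_genes)
        fold = np.ones(n_genes)
        fold[:n_de] = 4.0
        a = rng.poisson(rng.gamma(5.0, mu[:, None] / 5.0, (n_genes, 5)))
        b = rng.poisson(rng.gamma(5.0, (fold * mu)[:, None] / 5.0, (n_genes, 5)))
        samples = [f"s{i}" for i in range(10)]
        m = make_matrix(np.hstack([a, b]).tolist(), samples=samples)
        m = sl.normalize_median_of_ratios(m)
        meta = make_meta(samples, ["A"] * 5 + ["B"] * 5)
        res = sl.de_test_pairwise(m, meta, "A", "B")
        assert (res["p"].values[:n_de] < 0.05).mean() >= 0.9


class TestEnrichment:
    def test_winner_of_all_significant_contrasts(self, two_types=None):
        samples = [f"s{i}" for i in range(9)]
        groups = ["arch"] * 3 + ["cho"] * 3 + ["pin"] * 3
        counts = [[10, 10, 10, 500, 480, 520, 10, 12, 9],
                  [50, 55, 45, 50, 52, 49, 51, 50, 50]]
        m = sl.normalize_median_of_ratios(make_matrix(counts, samples=samples))
        meta = make_meta(samples, groups)
        de = pd.DataFrame({
            "gene": ["g0", "g0"],
            "contrast": ["arch_vs_cho", "cho_vs_pin"],
            "log2fc": [-5.0, 5.0], "p": [1e-9, 1e-9], "Q": [1e-8, 1e-8]})
        calls = sl.call_enrichment(de, m, meta)
        assert calls.loc[calls["gene"] == "g0", "category"].item() == \
               "cho-enriched"

    def test_no_significant_q_means_no_call(self, normalized_celltype, bundle):
        de = pd.DataFrame({"gene": ["codA0000"], "contrast": ["x_vs_y"],
                           "log2fc": [0.0], "p": [0.9], "Q": [0.9]})
        calls = sl.call_enrichment(de, normalized_celltype,
                                   bundle.meta_celltype_a)
        assert calls.empty

    def test_planted_celltype_recovery(self, normalized_celltype, bundle):
        """Planted cell-type DE genes recover their target category >= 95%."""
        meta = bundle.meta_celltype_a
        de = sl.de_all_pairs(normalized_celltype, meta)
        calls = sl.call_enrichment(de, normalized_celltype, meta)
        cat = dict(zip(calls["gene"], calls["category"]))
        planted = bundle.truth["de_genes"]
        hits = sum(1 for g, t in planted.items()
                   if cat.get(g, "") == f"{t}-enriched")
        assert hits / len(planted) >= 0.95


class TestQuartiles:
    def test_all_zero_gene_unassigned(self):
        counts = [[0, 0], [1, 2], [5, 6], [10, 12], [20, 25]]
        m = sl.normalize_median_of_ratios(make_matrix(counts))
        meta = make_meta(["s0", "s1"], ["g", "g"])
        bins = sl.quartile_bins(m, meta)
        assert "g0" not in set(bins["gene"])

    def test_eight_distinct_genes_two_per_quartile(self):
        counts = [[v] for v in [1, 2, 4, 8, 16, 32, 64, 128]]
        m = make_matrix(counts, samples=["s0"])
        m = sl.ExpressionMatrix(m.counts, m.biotype,
                                normalized=m.counts.astype(float),
                                size_factors=pd.Series([1.0], index=["s0"]))
        meta = make_meta(["s0"], ["g"])
        bins = sl.quartile_bins(m, meta)
        occupancy = bins["quartile"].value_counts()
        assert sorted(occupancy.values.tolist()) == [2, 2, 2, 2]

    def test_above_75th_breakpoint_is_q4(self):
        counts = [[v, v] for v in [1, 2, 3, 4, 5, 6, 7, 1000]]
        m = sl.normalize_median_of_ratios(make_matrix(counts))
        meta = make_meta(["s0", "s1"], ["g", "g"])
        bins = sl.quartile_bins(m, meta)
        assert bins.loc[bins["gene"] == "g7", "quartile"].item() == "Q4"

    def test_too_few_expressed_genes_errors(self):
        m = sl.normalize_median_of_ratios(make_matrix([[1, 1], [2, 2]]))
        with pytest.raises(ValueError, match=">= 4"):
            sl.quartile_bins(m, make_meta(["s0", "s1"], ["g", "g"]))
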