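import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import spongelnc as sl
from spongelnc.context import (ANTISENSE, GENIC_OTHER, INTERGENIC,
                               _u_statistic)


def gene(gid, biotype, contig, strand, exons):
    return sl.GeneAnnotation(gid, biotype, contig, strand, tuple(exons))


class TestPositionClassification:
    def test_no_coding_on_contig_is_intergenic(self):
        lnc = gene("l1", "lncRNA", "cX", "+", [(100, 200)])
        coding = [gene("c1", "coding", "cY", "+", [(0, 500)])]
        assert sl.classify_lncrna_position(lnc, coding).position_class == \
               INTERGENIC

    def test_opposite_strand_exon_overlap_is_antisense(self):
        lnc = gene("l1", "lncRNA", "c1", "+", [(100, 200)])
        coding = [gene("c1", "coding", "c1", "-", [(150, 250)])]
        res = sl.classify_lncrna_position(lnc, coding)
        assert res.position_class == ANTISENSE
        assert res.supporting == ("c1",)

    def test_intronic_same_strand_is_genic_other(self):
        # hand interval arithmetic: lnc exon sits in the coding intron
        coding = [gene("c1", "coding", "c1", "+", [(0, 500), (1500, 2000)])]
        lnc = gene("l1", "lncRNA", "c1", "+", [(600, 1200)])
        res = sl.classify_lncrna_position(lnc, coding)
        assert res.position_class == GENIC_OTHER
        assert res.supporting == ("c1",)

    def test_antisense_has_priority_over_genic(self):
        coding = [gene("c1", "coding", "c1", "-", [(0, 500), (1500, 2000)])]
        lnc = gene("l1", "lncRNA", "c1", "+", [(400, 700)])
        assert sl.classify_lncrna_position(lnc, coding).position_class == \
               ANTISENSE

    def test_classes_partition_the_lnc_set(self, bundle):
        lncs = [g for g in bundle.annotation_a if g.biotype == "lncRNA"]
        coding = [g for g in bundle.annotation_a if g.biotype == "coding"]
        classes = sl.classify_all(lncs, coding)
        counts = {c: 0 for c in (INTERGENIC, ANTISENSE, GENIC_OTHER)}
        for c in classes:
            counts[c.position_class] += 1
        assert sum(counts.values()) == len(lncs)

    def test_strand_flip_covariance(self):
        coding = [gene("c1", "coding", "c1", "-", [(150, 250)])]
        lnc = gene("l1", "lncRNA", "c1", "+", [(100, 200)])
        flipped_coding = [gene("c1", "coding", "c1", "+", [(150, 250)])]
        flipped_lnc = gene("l1", "lncRNA", "c1", "-", [(100, 200)])
        assert sl.classify_lncrna_position(lnc, coding).position_class == \
               sl.classify_lncrna_position(flipped_lnc,
                                           flipped_coding).position_class

    def test_no_exons_rejected_at_construction(self):
        with pytest.raises(ValueError, match="no exons"):
            gene("l1", "lncRNA", "c1", "+", [])


def brute_force_mwu_p(x, y):
    """Exact two-sided p by direct enumeration (independent oracle)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = _u_statistic(np.asarray(x, float), np.asarray(y, float))
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        us.append(_u_statistic(pooled[mask], pooled[~mask]))
    us = np.array(us)
    lo = (us <= u_obs + 1e-9).mean()
    hi = (us >= u_obs - 1e-9).mean()
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitney:
    def test_identical_samples(self):
        u, p = sl.mann_whitney_u([1, 2], [1, 2])
        assert u == 2.0  # n1*n2/2
        assert p == 1.0

    def test_complete_separation_exact(self):
        u, p = sl.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(2 / comb(6, 3))

    @pytest.mark.parametrize("x,y", [
        ([1, 5, 9], [2, 3, 8, 10]),
        ([1.5, 2.5], [0.5, 3.5, 4.5]),
        ([1, 1, 2, 3], [1, 2, 2]),          # ties across groups
        ([10, 20, 30, 40, 50], [15, 25, 35, 45]),
        ([3, 3, 3], [3, 3, 3]),              # all tied
    ])
    def test_exact_p_matches_brute_force(self, x, y):
        _, p = sl.mann_whitney_u(x, y)
        assert p == pytest.approx(brute_force_mwu_p(x, y))

    @given(st.lists(st.integers(0, 5), min_size=2, max_size=5),
           st.lists(st.integers(0, 5), min_size=2, max_size=5))
    @settings(deadline=None, max_examples=40)
    def test_complement_identity(self, x, y):
        ux, _ = sl.mann_whitney_u(x, y)
        uy, _ = sl.mann_whitney_u(y, x)
        assert ux + uy == pytest.approx(len(x) * len(y))

    def test_large_sample_agrees_with_scipy_asymptotic(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.8, 1, 18)
        u, p = sl.mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_nan_input_errors(self):
        with pytest.raises(ValueError):
            sl.mann_whitney_u([1.0, np.nan], [2.0, 3.0])


def brute_force_fisher_p(table):
    """Enumerate all tables with the observed margins (independent oracle)."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    from math import comb as C

    def prob(k):
        return C(col1, k) * C(n - col1, row1 - k) / C(n, row1)

    p_obs = prob(a)
    return sum(prob(k) for k in range(max(0, row1 + col1 - n),
                                      min(row1, col1) + 1)
               if prob(k) <= p_obs * (1 + 1e-7))


class TestFisherExact:
    def test_symmetric_table(self):
        odds, p = sl.fisher_exact([[5, 5], [5, 5]])
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_diagonal_table(self):
        _, p = sl.fisher_exact([[3, 0], [0, 3]])
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("table", [
        [[1, 2], [3, 4]], [[5, 1], [2, 6]], [[0, 4], [7, 2]],
        [[2, 2], [8, 8]], [[6, 0], [1, 9]], [[3, 5], [5, 3]],
    ])
    def test_matches_brute_force_enumeration(self, table):
        _, p = sl.fisher_exact(table)
        assert p == pytest.approx(brute_force_fisher_p(table))

    def test_matches_scipy_two_sided(self):
        table = [[7, 3], [2, 9]]
        _, p = sl.fisher_exact(table)
        assert p == pytest.approx(stats.fisher_exact(table)[1])

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError, match="margin"):
            sl.fisher_exact([[0, 0], [3, 4]])


class TestStructuralComparison:
    def test_identical_sets_give_p_one(self):
        genes = [gene(f"l{i}", "lncRNA", "c1", "+", [(i * 100, i * 100 + 50)])
                 for i in range(4)]
        rep = sl.compare_structural_features(genes, genes)
        assert rep["features"]["length"]["p"] == 1.0
        assert rep["features"]["length"]["mean_a"] == \
               rep["features"]["length"]["mean_b"]

    def test_constant_lengths_sem_zero(self):
        genes = [gene(f"l{i}", "lncRNA", "c1", "+", [(0, 100)])
                 for i in range(4)]
        rep = sl.compare_structural_features(genes, genes)
        assert rep["features"]["length"]["sem_a"] == 0.0
        assert rep["features"]["length"]["mean_a"] == 100.0

    def test_sem_uses_n_minus_one(self):
        # lengths 1..10: sd = sqrt(82.5/9), SEM = sd/sqrt(10)
        a = [gene(f"a{i}", "lncRNA", "c1", "+", [(0, i)])
             for i in range(1, 11)]
        b = [gene("b0", "lncRNA", "c1", "+", [(0, 5)])]
        rep = sl.compare_structural_features(a, b)
        assert rep["features"]["length"]["sem_a"] == \
               pytest.approx(np.sqrt(82.5 / 9) / np.sqrt(10))

    def test_position_class_proportions(self, bundle):
        lncs = [g for g in bundle.annotation_a if g.biotype == "lncRNA"]
        coding = [g for g in bundle.annotation_a if g.biotype == "coding"]
        rep = sl.compare_structural_features(lncs[:20], lncs[20:], coding)
        total_a = sum(v["count_a"] for v in rep["position_classes"].values())
        assert total_a == 20
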