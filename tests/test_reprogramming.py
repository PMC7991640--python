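"""Peak decomposition, element annotation, strata, correlations, associations."""

import numpy as np
import pandas as pd
import pytest

from chiprx.enhancers import Enhancer, EnhancerTransition
from chiprx.genome import GeneModel, GenomeInterval
from chiprx.reprogramming import (
    DeltaRecord,
    annotate_elements,
    class_expression_summary,
    decompose_peaks,
    delta_correlation,
    inactivation_gene_association,
    log2_fold_change,
    stratify_expression,
)

from conftest import random_intervals
from naive import naive_decompose, naive_pearson


def iv(chrom, start, end):
    return GenomeInterval(chrom, start, end)


class TestDecompose:
    def test_disjoint_sets_are_all_unique(self):
        a = [iv("chr1", 0, 100)]
        b = [iv("chr1", 500, 600)]
        d = decompose_peaks(a, b)
        assert d.venn_counts() == {"a_only": 1, "b_only": 1,
                                   "common_a_perspective": 0,
                                   "common_b_perspective": 0}

    def test_identical_sets_are_all_common(self):
        a = [iv("chr1", 0, 100), iv("chr2", 0, 50)]
        d = decompose_peaks(a, list(a))
        assert len(d.common_a) == len(d.common_b) == 2
        assert not d.unique_a and not d.unique_b

    def test_randomized_matches_brute_force(self, toy_genome):
        rng = np.random.default_rng(12)
        a = random_intervals(rng, toy_genome, 300)
        b = random_intervals(rng, toy_genome, 300)
        d = decompose_peaks(a, b)
        ca, cb, ua, ub = naive_decompose(a, b)
        assert (d.common_a, d.common_b, d.unique_a, d.unique_b) == (ca, cb, ua, ub)

    def test_classification_is_symmetric(self, toy_genome):
        rng = np.random.default_rng(13)
        a = random_intervals(rng, toy_genome, 100)
        b = random_intervals(rng, toy_genome, 100)
        assert decompose_peaks(a, b).common_a == decompose_peaks(b, a).common_b


class TestAnnotateElements:
    @pytest.fixture()
    def annotation(self, toy_genome):
        g = GeneModel(
            gene_id="g1", chrom="chr1", strand="+", tss=10_000, tes=20_000,
            exons=[iv("chr1", 10_000, 12_000), iv("chr1", 18_000, 20_000)])
        from chiprx.enhancers import define_promoters
        return [g], define_promoters([g], toy_genome)

    @pytest.mark.parametrize("peak, element", [
        (iv("chr1", 10_500, 11_500), "exon"),
        (iv("chr1", 14_000, 15_000), "intron"),
        (iv("chr1", 8_500, 9_500), "promoter"),
        (iv("chr1", 50_000, 51_000), "intergenic"),
        (iv("chr2", 1_000, 2_000), "intergenic"),  # gene-free chromosome
    ])
    def test_midpoint_assignment(self, annotation, peak, element):
        genes, promoters = annotation
        tbl = annotate_elements([peak], genes, promoters).set_index("element")
        assert tbl.loc[element, "count"] == 1

    def test_promoter_beats_exon(self, annotation, toy_genome):
        genes, promoters = annotation
        # midpoint 10,250 is both in the first exon and in the promoter tail
        tbl = annotate_elements([iv("chr1", 10_000, 10_500)], genes,
                                promoters).set_index("element")
        assert tbl.loc["promoter", "count"] == 1

    def test_fractions_sum_to_one(self, annotation, toy_genome):
        genes, promoters = annotation
        rng = np.random.default_rng(14)
        peaks = random_intervals(rng, toy_genome, 200)
        tbl = annotate_elements(peaks, genes, promoters)
        assert tbl["fraction"].sum() == pytest.approx(1.0)
        assert tbl["count"].sum() == 200


class TestStratify:
    def test_tertiles_of_one_to_nine(self):
        fpkm = {f"g{i}": float(i) for i in range(1, 10)}
        strata = stratify_expression(fpkm)
        assert {g for g, s in strata.items() if s == "high"} == {"g7", "g8", "g9"}
        assert {g for g, s in strata.items() if s == "medium"} == {"g4", "g5", "g6"}
        assert {g for g, s in strata.items() if s == "low"} == {"g1", "g2", "g3"}

    def test_all_equal_splits_deterministically_by_gene_id(self):
        fpkm = {f"g{i}": 5.0 for i in range(6)}
        strata = stratify_expression(fpkm)
        assert [strata[f"g{i}"] for i in range(6)] == \
            ["low", "low", "medium", "medium", "high", "high"]

    def test_zero_fpkm_always_low(self):
        fpkm = {"a": 0.0, "b": 0.0, "c": 0.0, "d": 0.0, "e": 1.0, "f": 2.0}
        strata = stratify_expression(fpkm)
        assert all(strata[g] == "low" for g in "abcd")

    def test_too_few_genes_errors(self):
        with pytest.raises(ValueError):
            stratify_expression({"a": 1.0, "b": 2.0}, n_strata=3)


class TestDeltaCorrelation:
    def rec(self, x, y):
        return DeltaRecord(interval=iv("chr1", 0, 100), mark="m",
                           delta=y, occupancy=x)

    def test_perfect_linear(self):
        recs = [self.rec(x, 2 * x + 1) for x in (0.0, 1.0, 2.0, 3.0)]
        r, n = delta_correlation(recs)
        assert r == pytest.approx(1.0) and n == 4
        recs = [self.rec(x, -x) for x in (0.0, 1.0, 2.0)]
        assert delta_correlation(recs)[0] == pytest.approx(-1.0)

    def test_zero_variance_errors(self):
        recs = [self.rec(1.0, y) for y in (0.0, 1.0, 2.0)]
        with pytest.raises(ValueError, match="variance"):
            delta_correlation(recs)

    def test_too_few_records_errors(self):
        with pytest.raises(ValueError):
            delta_correlation([self.rec(0.0, 1.0), self.rec(1.0, 0.0)])

    def test_matches_textbook_formula_to_1e12(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            x = rng.normal(size=50)
            y = 0.3 * x + rng.normal(size=50)
            recs = [self.rec(a, b) for a, b in zip(x, y)]
            r, _ = delta_correlation(recs)
            assert r == pytest.approx(naive_pearson(list(x), list(y)),
                                      abs=1e-12)


class TestAssociations:
    def trans(self, gene, inactivated, start=0):
        e = Enhancer(interval=iv("chr1", start, start + 500),
                     state="active", assigned_gene=gene, tss_distance=1000)
        state = "primed" if inactivated else "active"
        return EnhancerTransition(wt_enhancer=e, mutant_state=state,
                                  inactivated=inactivated)

    def test_no_inactivated_enhancers_gives_zero_fractions(self):
        de = {"g1": "down", "g2": "up", "g3": "unchanged"}
        lfc = {g: 0.0 for g in de}
        res = inactivation_gene_association(
            [self.trans("g1", False)], de, lfc)
        assert (res.de_fractions["fraction"] == 0.0).all()

    def test_single_gene_single_inactivated(self):
        de = {"g1": "down"}
        res = inactivation_gene_association(
            [self.trans("g1", True)], de, {"g1": -2.0})
        frac = res.de_fractions.set_index("status")
        assert frac.loc["down", "fraction"] == 1.0
        bins = res.count_bins.set_index("bin")
        assert bins.loc["1", "n_genes"] == 1
        assert bins.loc["1", "median_log2fc"] == -2.0

    def test_count_bins_cover_zero_one_two_threeplus(self):
        de = {f"g{i}": "unchanged" for i in range(4)}
        lfc = {g: 0.0 for g in de}
        transitions = []
        for i, m in enumerate([0, 1, 2, 5]):
            for j in range(m):
                transitions.append(self.trans(f"g{i}", True, start=1000 * j))
        res = inactivation_gene_association(transitions, de, lfc)
        assert list(res.count_bins["bin"]) == ["0", "1", "2", ">=3"]
        assert list(res.count_bins["n_genes"]) == [1, 1, 1, 1]


class TestClassExpression:
    def make(self, state, gene):
        return Enhancer(interval=iv("chr1", 0, 500), state=state,
                        assigned_gene=gene, tss_distance=100)

    def test_same_gene_sets_are_null(self):
        fpkm = {f"g{i}": float(i) for i in range(10)}
        enhancers = [self.make(s, f"g{i}")
                     for s in ("active", "primed", "poised")
                     for i in range(10)]
        summary, contrasts = class_expression_summary(enhancers, fpkm)
        assert (contrasts["p_value"] > 0.9).all()
        assert len(summary) == 3

    def test_single_state_gives_no_contrasts(self):
        fpkm = {"g1": 3.0, "g2": 5.0}
        enhancers = [self.make("active", "g1"), self.make("active", "g2")]
        summary, contrasts = class_expression_summary(enhancers, fpkm)
        assert len(summary) == 1 and len(contrasts) == 0

    def test_seeded_ordering_recovered(self):
        rng = np.random.default_rng(16)
        fpkm = {}
        enhancers = []
        for state, base in (("active", 50.0), ("primed", 10.0), ("poised", 1.0)):
            for i in range(40):
                g = f"{state}_{i}"
                fpkm[g] = float(base * rng.lognormal(0, 0.3))
                enhancers.append(self.make(state, g))
        summary, contrasts = class_expression_summary(enhancers, fpkm)
        med = summary.set_index("state")["median_fpkm"]
        assert med["active"] > med["primed"] > med["poised"]
        assert (contrasts["p_adj"] < 0.001).all()


def test_log2_fold_change_uses_pseudocount():
    lfc = log2_fold_change({"g": 0.0, "h": 3.0}, {"g": 0.0, "h": 7.0})
    assert lfc["g"] == 0.0
    assert lfc["h"] == pytest.approx(1.0)
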