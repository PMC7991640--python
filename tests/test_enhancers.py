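"""Promoter windows, enhancer calling/classification, transitions, assignment."""

import numpy as np
import pytest

from chiprx.enhancers import (
    Enhancer,
    EnhancerTransition,
    assign_enhancers,
    call_enhancers,
    classify_enhancers,
    define_promoters,
    dual_mark_fraction,
    enhancer_stats,
    enhancer_transitions,
    inactivated_fraction,
)
from chiprx.genome import GeneModel, GenomeInterval, GenomeTable

from conftest import random_intervals
from naive import naive_overlap


def gene(gid, tss, strand="+", chrom="chr1"):
    tes = tss + 2000 if strand == "+" else tss - 2000
    return GeneModel(gene_id=gid, chrom=chrom, strand=strand, tss=tss, tes=tes)


def enh(chrom, start, end, state=None):
    return Enhancer(interval=GenomeInterval(chrom, start, end), state=state)


class TestPromoters:
    def test_plus_strand_window(self, toy_genome):
        (p,) = define_promoters([gene("g1", 10_000)], toy_genome)
        assert (p.start, p.end) == (8_000, 10_500)

    def test_minus_strand_window_is_mirrored(self, toy_genome):
        (p,) = define_promoters([gene("g1", 10_000, "-")], toy_genome)
        assert (p.start, p.end) == (9_500, 12_000)

    def test_clipped_at_chromosome_start(self, toy_genome):
        (p,) = define_promoters([gene("g1", 1_000)], toy_genome)
        assert (p.start, p.end) == (0, 1_500)


class TestCallEnhancers:
    def test_one_bp_promoter_overlap_excludes(self, toy_genome):
        promoters = define_promoters([gene("g1", 10_000)], toy_genome)
        k4me1 = [GenomeInterval("chr1", 10_499, 11_000),  # 1 bp into promoter
                 GenomeInterval("chr1", 10_500, 11_000)]  # book-ended: kept
        out = call_enhancers(k4me1, [], promoters)
        assert [e.interval for e in out] == [k4me1[1]]

    def test_k4me3_overlap_excludes(self):
        k4me1 = [GenomeInterval("chr1", 0, 1000)]
        k4me3 = [GenomeInterval("chr1", 900, 2000)]
        assert call_enhancers(k4me1, k4me3, []) == []

    def test_untouched_peak_becomes_enhancer(self):
        k4me1 = [GenomeInterval("chr1", 0, 1000)]
        out = call_enhancers(k4me1, [GenomeInterval("chr1", 5000, 6000)], [],
                             condition="WT")
        assert len(out) == 1 and out[0].condition == "WT"
        assert out[0].state is None

    def test_randomized_agrees_with_brute_force_filter(self, toy_genome):
        rng = np.random.default_rng(10)
        k4me1 = random_intervals(rng, toy_genome, 200)
        k4me3 = random_intervals(rng, toy_genome, 60)
        promoters = random_intervals(rng, toy_genome, 60)
        got = [e.interval for e in call_enhancers(k4me1, k4me3, promoters)]
        expected = [p for p in k4me1
                    if not any(naive_overlap(p, q) for q in k4me3 + promoters)]
        assert got == expected


class TestClassify:
    def test_three_states_and_precedence(self):
        enhancers = [enh("chr1", 0, 1000), enh("chr1", 2000, 3000),
                     enh("chr1", 4000, 5000), enh("chr1", 6000, 7000)]
        k27ac = [GenomeInterval("chr1", 500, 600),
                 GenomeInterval("chr1", 6500, 6600)]
        k27me3 = [GenomeInterval("chr1", 2500, 2600),
                  GenomeInterval("chr1", 6500, 6600)]
        out = classify_enhancers(enhancers, k27ac, k27me3)
        # dual-marked enhancer resolves to active (precedence active > poised)
        assert [e.state for e in out] == ["active", "poised", "primed", "active"]
        assert dual_mark_fraction(enhancers, k27ac, k27me3) == 0.25

    def test_states_partition(self, small_sim):
        cond = "WT"
        enhancers = [enh(e.chrom, e.start, e.end)
                     for e in small_sim.truth.enhancers
                     if e.cls in ("common", "wt_only")]
        out = classify_enhancers(
            enhancers, small_sim.peaks[("H3K27ac", cond)],
            small_sim.peaks[("H3K27me3", cond)])
        counts = {s: sum(1 for e in out if e.state == s)
                  for s in ("active", "primed", "poised")}
        assert sum(counts.values()) == len(out)
        assert all(e.state is not None for e in out)

    def test_adding_k27ac_only_moves_toward_active(self):
        enhancers = [enh("chr1", i * 1000, i * 1000 + 500) for i in range(20)]
        k27me3 = [GenomeInterval("chr1", 2100, 2300)]
        base = classify_enhancers(enhancers, [], k27me3)
        more = classify_enhancers(
            enhancers, [GenomeInterval("chr1", 0, 10_000)], k27me3)
        for b, m in zip(base, more):
            if b.state == "active":
                assert m.state == "active"
            assert (m.state == "active") >= (b.state == "active")


class TestTransitions:
    def test_identical_inputs_give_zero_inactivated(self):
        wt = [enh("chr1", 0, 1000, "active"), enh("chr1", 5000, 6000, "primed")]
        trans = enhancer_transitions(wt, wt)
        assert len(trans) == 1  # only WT-active enhancers considered
        assert not any(t.inactivated for t in trans)

    def test_poised_in_mutant_is_inactivated(self):
        wt = [enh("chr1", 0, 1000, "active")]
        mut = [enh("chr1", 500, 1500, "poised")]
        (t,) = enhancer_transitions(wt, mut)
        assert t.mutant_state == "poised" and t.inactivated

    def test_no_overlap_is_lost_and_inactivated(self):
        wt = [enh("chr1", 0, 1000, "active")]
        mut = [enh("chr1", 50_000, 51_000, "active")]
        (t,) = enhancer_transitions(wt, mut)
        assert t.mutant_state == "lost" and t.inactivated

    def test_largest_overlap_wins(self):
        wt = [enh("chr1", 0, 1000, "active")]
        mut = [enh("chr1", 900, 2000, "poised"),   # 100 bp overlap
               enh("chr1", 200, 900, "active")]    # 700 bp overlap
        (t,) = enhancer_transitions(wt, mut)
        assert t.mutant_state == "active" and not t.inactivated

    def test_unclassified_inputs_rejected(self):
        with pytest.raises(ValueError):
            enhancer_transitions([enh("chr1", 0, 1000)], [])

    def test_inconsistent_flag_rejected(self):
        with pytest.raises(ValueError):
            EnhancerTransition(wt_enhancer=enh("chr1", 0, 10, "active"),
                               mutant_state="poised", inactivated=False)

    def test_reporting_arithmetic(self):
        assert inactivated_fraction(3, 4) == 75.0
        with pytest.raises(ValueError):
            inactivated_fraction(5, 4)
        with pytest.raises(ValueError):
            inactivated_fraction(0, 0)


class TestAssignment:
    def test_within_and_beyond_max_dist(self, toy_genome):
        genes = [gene("g1", 50_000)]
        near = enh("chr1", 40_000, 41_000)
        out = assign_enhancers([near], genes, max_dist=500_000)
        assert out[0].assigned_gene == "g1"
        assert out[0].tss_distance == 50_000 - 40_500
        far = assign_enhancers([near], genes, max_dist=5_000)
        assert far[0].assigned_gene is None and far[0].tss_distance is None

    def test_randomized_matches_brute_force(self, toy_genome):
        rng = np.random.default_rng(11)
        genes = [gene(f"g{i:03d}", int(rng.integers(3000, 95_000)))
                 for i in range(60)]
        enhancers = [enh(iv.chrom, iv.start, iv.end)
                     for iv in random_intervals(rng, toy_genome, 300)]
        out = assign_enhancers(enhancers, genes, max_dist=20_000)
        for e in out:
            mid = e.interval.midpoint
            dists = sorted((abs(g.tss - mid), g.gene_id) for g in genes
                           if g.chrom == e.interval.chrom)
            if not dists or dists[0][0] > 20_000:
                assert e.assigned_gene is None
            else:
                assert (e.tss_distance, e.assigned_gene) == dists[0]


class TestStats:
    def test_single_enhancer_summary(self):
        df = enhancer_stats({"WT": [enh("chr1", 100, 500)]})
        row = df.set_index("group").loc["WT"]
        assert row["count"] == 1 and row["length_mean"] == 400.0

    def test_identical_conditions_identical_rows(self):
        group = [enh("chr1", 0, 1000), enh("chr1", 5000, 5400)]
        df = enhancer_stats({"a": group, "b": list(group)}).set_index("group")
        assert df.loc["a"].equals(df.loc["b"])

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="empty"):
            enhancer_stats({"a": []})
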