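"""Density and metagene profiling: closed-form oracles and symmetries."""

import numpy as np
import pytest

from chiprx.coverage import CoverageTrack
from chiprx.genome import GeneModel, GenomeInterval, GenomeTable
from chiprx.profiles import (
    group_mean_density,
    interval_density,
    interval_densities,
    metagene_profile,
)

from conftest import random_intervals
from naive import naive_base_density


@pytest.fixture()
def fine_genome():
    return GenomeTable({"chrA": 20_000})


class TestIntervalDensity:
    def test_constant_track_gives_constant(self, toy_genome):
        track = CoverageTrack.constant(toy_genome, 100, 3.25)
        d = interval_density(track, GenomeInterval("chr1", 137, 9_021))
        assert d.density == pytest.approx(3.25)

    def test_two_bin_average(self, toy_genome):
        track = CoverageTrack.zeros(toy_genome, 100)
        track.values["chr1"][0] = 1.0
        track.values["chr1"][1] = 3.0
        d = interval_density(track, GenomeInterval("chr1", 50, 150))
        assert d.density == pytest.approx(2.0)

    def test_off_genome_interval_errors(self, toy_genome):
        track = CoverageTrack.zeros(toy_genome, 100)
        with pytest.raises(ValueError):
            interval_density(track, GenomeInterval("chr1", 99_000, 101_000))
        with pytest.raises(ValueError):
            interval_density(track, GenomeInterval("chrZ", 0, 100))

    def test_matches_base_resolution_oracle(self, toy_genome):
        rng = np.random.default_rng(4)
        track = CoverageTrack(
            toy_genome, 100,
            {c: rng.gamma(2.0, 1.0, size=-(-L // 100))
             for c, L in toy_genome.items()})
        for iv in random_intervals(rng, toy_genome, 500):
            expected = naive_base_density(track, iv)
            assert interval_density(track, iv).density == pytest.approx(
                expected, abs=1e-9)

    def test_bin_aligned_density_invariant_to_refinement(self, toy_genome):
        rng = np.random.default_rng(5)
        coarse = CoverageTrack(
            toy_genome, 200,
            {c: rng.gamma(2.0, 1.0, size=-(-L // 200))
             for c, L in toy_genome.items()})
        fine = CoverageTrack(
            toy_genome, 100,
            {c: np.repeat(v, 2)[: -(-toy_genome[c] // 100)]
             for c, v in coarse.values.items()})
        iv = GenomeInterval("chr1", 1000, 5000)  # aligned to both grids
        assert interval_density(coarse, iv).density == pytest.approx(
            interval_density(fine, iv).density, abs=1e-12)


def make_gene(gid, chrom, start, end, strand="+"):
    tss, tes = (start, end) if strand == "+" else (end, start)
    return GeneModel(gene_id=gid, chrom=chrom, strand=strand, tss=tss, tes=tes)


class TestMetagene:
    def test_uniform_track_gives_flat_profile(self, fine_genome):
        track = CoverageTrack.constant(fine_genome, 50, 2.0)
        genes = [make_gene("g1", "chrA", 8000, 12_000)]
        pm = metagene_profile(track, genes, flank=1000, body_bins=20,
                              flank_bin_size=100)
        assert pm.matrix.shape == (1, 10 + 20 + 10)
        assert np.allclose(pm.matrix, 2.0)

    def test_body_restricted_signal_stays_out_of_flanks(self, fine_genome):
        track = CoverageTrack.zeros(fine_genome, 50)
        track.values["chrA"][8000 // 50: 12_000 // 50] = 5.0
        genes = [make_gene("g1", "chrA", 8000, 12_000)]
        pm = metagene_profile(track, genes, flank=1000, body_bins=20,
                              flank_bin_size=100)
        assert np.allclose(pm.matrix[0, 10:30], 5.0)
        assert np.allclose(pm.matrix[0, :9], 0.0)
        assert np.allclose(pm.matrix[0, 31:], 0.0)

    def test_linear_gradient_matches_analytic_bin_means(self, fine_genome):
        # base-resolution track: value x/L at base x of the body
        body_start, body_end = 5000, 7000
        L = body_end - body_start
        vals = np.zeros(20_000)
        x = np.arange(body_start, body_end)
        vals[x] = (x - body_start) / L
        track = CoverageTrack(fine_genome, 1, {"chrA": vals})
        genes = [make_gene("g1", "chrA", body_start, body_end)]
        pm = metagene_profile(track, genes, flank=500, body_bins=10,
                              flank_bin_size=100)
        body = pm.matrix[0, 5:15]
        # mean of (x - s)/L over each tenth of the body: midpoints of tenths
        expected = (np.arange(10) + 0.5) / 10 - 0.5 / L
        assert np.allclose(body, expected, atol=1e-6)
        assert np.all(np.diff(body) > 0)

    def test_minus_strand_gene_is_flipped(self, fine_genome):
        track = CoverageTrack.zeros(fine_genome, 50)
        track.values["chrA"][: 6000 // 50] = 1.0  # left half of the genome
        plus = [make_gene("g1", "chrA", 5000, 7000, "+")]
        minus = [make_gene("g1", "chrA", 5000, 7000, "-")]
        pm_p = metagene_profile(track, plus, flank=1000, body_bins=20,
                                flank_bin_size=100)
        pm_m = metagene_profile(track, minus, flank=1000, body_bins=20,
                                flank_bin_size=100)
        assert np.allclose(pm_m.matrix[0], pm_p.matrix[0][::-1])

    def test_aggregate_of_identical_genes_equals_single_profile(self, fine_genome):
        rng = np.random.default_rng(6)
        track = CoverageTrack(fine_genome, 50,
                              {"chrA": rng.gamma(2.0, 1.0, size=400)})
        gene = make_gene("g1", "chrA", 8000, 12_000)
        clones = [make_gene(f"g{i}", "chrA", 8000, 12_000) for i in range(5)]
        single = metagene_profile(track, [gene], flank=1000, body_bins=20,
                                  flank_bin_size=100)
        many = metagene_profile(track, clones, flank=1000, body_bins=20,
                                flank_bin_size=100)
        assert np.allclose(many.aggregate(), single.matrix[0])

    def test_short_and_out_of_bounds_genes_dropped(self, fine_genome):
        track = CoverageTrack.zeros(fine_genome, 50)
        genes = [
            make_gene("ok", "chrA", 8000, 12_000),
            make_gene("short", "chrA", 9000, 9010),       # < body_bins bp
            make_gene("edge", "chrA", 100, 5000),          # flank off chrom
        ]
        pm = metagene_profile(track, genes, flank=1000, body_bins=20,
                              flank_bin_size=100)
        assert pm.gene_ids == ["ok"]
        assert sorted(pm.dropped) == ["edge", "short"]

    def test_empty_gene_list_errors(self, fine_genome):
        track = CoverageTrack.zeros(fine_genome, 50)
        with pytest.raises(ValueError):
            metagene_profile(track, [], flank=1000, body_bins=20)


class TestGroupMeanDensity:
    def test_identical_groups_are_null(self):
        vals = list(np.arange(30.0))
        res = group_mean_density({"a": vals, "b": vals})
        assert res.contrasts["p_value"].iloc[0] > 0.9
        assert res.summary.loc[0, "mean"] == pytest.approx(
            res.summary.loc[1, "mean"])

    def test_small_group_errors(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            group_mean_density({"a": [1.0], "b": [1.0, 2.0]})

    def test_separated_groups_significant_and_bh_monotone(self):
        rng = np.random.default_rng(8)
        res = group_mean_density({
            "low": rng.gamma(2.0, 1.0, 200),
            "high": rng.gamma(2.0, 1.0, 200) + 5.0,
            "alsolow": rng.gamma(2.0, 1.0, 200),
        })
        c = res.contrasts.set_index(["group_a", "group_b"])
        assert c.loc[("low", "high"), "p_adj"] < 1e-6
        assert c.loc[("low", "alsolow"), "p_value"] > 0.01
        assert (res.contrasts["p_adj"] >= res.contrasts["p_value"] - 1e-12).all()

    def test_type_i_error_calibrated_under_label_permutation(self):
        """Permuting group labels on exchangeable data rejects at ~alpha."""
        rng = np.random.default_rng(9)
        data = rng.gamma(2.0, 1.0, 40)
        rejections = 0
        n_perm = 1000
        for _ in range(n_perm):
            perm = rng.permutation(data)
            res = group_mean_density({"a": perm[:20], "b": perm[20:]})
            if res.contrasts["p_value"].iloc[0] < 0.05:
                rejections += 1
        assert rejections / n_perm == pytest.approx(0.05, abs=0.02)
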