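"""Traveling ratios, metagene profiles, and the rank-sum comparison."""

import itertools

import numpy as np
import pytest
from scipy import stats

from txstress.pausing import (
    CoverageTrack,
    GeneModel,
    TravelingRatioAnalysis,
    call_active_genes,
    compare_distributions,
    cumulative_curve,
    interval_density,
    metagene_profile,
    ratio_of_traveling_ratios,
    traveling_ratio,
)


def constant_track(value, length=20_000, bin_width=10, chrom="chr1"):
    return CoverageTrack({chrom: np.full(length // bin_width, float(value))}, bin_width)


GENE = GeneModel("g", "chr1", "+", 5_000, 15_000)


class TestGeneModel:
    def test_strand_conventions_enforced(self):
        with pytest.raises(ValueError):
            GeneModel("g", "chr1", "+", 100, 50)
        with pytest.raises(ValueError):
            GeneModel("g", "chr1", "-", 50, 100)
        with pytest.raises(ValueError):
            GeneModel("g", "chr1", "*", 0, 100)

    def test_windows_are_mirror_symmetric(self):
        G = 100_000
        plus = GeneModel("p", "chr1", "+", 5_000, 15_000)
        minus = GeneModel("m", "chr1", "-", G - 5_000, G - 15_000)

        def mirror(win):
            return (G - win[1], G - win[0])

        assert mirror(plus.promoter_window()) == minus.promoter_window()
        assert mirror(plus.body_window()) == minus.body_window()


class TestIntervalDensity:
    def test_constant_track_any_interval(self):
        track = constant_track(4.0)
        assert interval_density(track, "chr1", 123, 4_567) == pytest.approx(4.0)

    def test_half_covered_interval(self):
        v = np.concatenate([np.full(500, 10.0), np.zeros(500)])
        track = CoverageTrack({"chr1": v}, bin_width=10)
        assert interval_density(track, "chr1", 0, 10_000) == pytest.approx(5.0)

    def test_zero_length_interval_rejected(self):
        with pytest.raises(ValueError):
            interval_density(constant_track(1.0), "chr1", 100, 100)

    def test_fractional_bins_match_per_bp_oracle(self):
        rng = np.random.default_rng(30)
        values = rng.random(100)
        coarse = CoverageTrack({"chr1": values}, bin_width=10)
        fine = CoverageTrack({"chr1": np.repeat(values, 10)}, bin_width=1)
        for _ in range(50):
            s = int(rng.integers(0, 999))
            e = int(rng.integers(s + 1, 1_000))
            assert coarse.interval_sum("chr1", s, e) == pytest.approx(
                fine.interval_sum("chr1", s, e)
            )


class TestTravelingRatio:
    def test_uniform_coverage_gives_unity(self):
        rec = traveling_ratio(constant_track(3.0), GENE)
        assert rec.tr == pytest.approx(1.0)
        assert rec.excluded is None

    def test_promoter_over_body_arithmetic(self):
        v = np.zeros(2_000)
        bw = 10
        v[:] = 2.0
        ps, pe = GENE.promoter_window()
        v[ps // bw: pe // bw] = 10.0
        track = CoverageTrack({"chr1": v}, bw)
        rec = traveling_ratio(track, GENE)
        assert rec.tr == pytest.approx(5.0)

    def test_short_gene_excluded(self):
        short = GeneModel("s", "chr1", "+", 1_000, 1_200)
        rec = traveling_ratio(constant_track(1.0), short)
        assert rec.excluded == "short_gene"
        assert np.isnan(rec.tr)

    def test_zero_body_density_excluded_without_pseudocount(self):
        track = CoverageTrack({"chr1": np.zeros(2_000)}, 10)
        rec = traveling_ratio(track, GENE)
        assert rec.excluded == "zero_body_density"

    def test_scale_invariance(self):
        rng = np.random.default_rng(31)
        track = CoverageTrack({"chr1": rng.random(2_000) + 0.1}, 10)
        r1 = traveling_ratio(track, GENE).tr
        r2 = traveling_ratio(track.scaled(7.5), GENE).tr
        assert r1 == pytest.approx(r2)

    def test_minus_strand_mirror_symmetry(self):
        rng = np.random.default_rng(32)
        values = rng.random(2_000) + 0.05
        track = CoverageTrack({"chr1": values}, 10)
        mirrored = track.mirrored()
        G = 20_000
        plus = GeneModel("p", "chr1", "+", 5_000, 15_000)
        minus = GeneModel("m", "chr1", "-", G - 5_000, G - 15_000)
        assert traveling_ratio(track, plus).tr == pytest.approx(
            traveling_ratio(mirrored, minus).tr
        )


class TestRoTR:
    def test_identical_chip_and_input_gives_unity(self):
        rng = np.random.default_rng(33)
        track = CoverageTrack({"chr1": rng.random(2_000) + 0.1}, 10)
        res = TravelingRatioAnalysis(track, track, [GENE]).fit()
        assert res.records["rotr"].iloc[0] == pytest.approx(1.0)

    def test_ratio_arithmetic(self):
        assert ratio_of_traveling_ratios(6.0, 2.0) == pytest.approx(3.0)
        assert np.isnan(ratio_of_traveling_ratios(np.nan, 2.0))

    def test_doubled_promoter_signal_in_chip_only(self):
        # chip = input everywhere except a doubled promoter window
        rng = np.random.default_rng(34)
        base = rng.poisson(50, size=2_000).astype(float)
        chip = base.copy()
        ps, pe = GENE.promoter_window()
        chip[ps // 10: pe // 10] *= 2
        res = TravelingRatioAnalysis(
            CoverageTrack({"chr1": chip}, 10), CoverageTrack({"chr1": base}, 10), [GENE]
        ).fit()
        assert res.records["rotr"].iloc[0] == pytest.approx(2.0, rel=0.05)


class TestActiveGenes:
    def test_chip_equal_input_not_active(self):
        track = constant_track(1.0)
        assert call_active_genes(track, track, [GENE], enrichment_threshold=2.0) == []

    def test_enriched_promoter_called(self):
        v = np.full(2_000, 1.0)
        ps, pe = GENE.promoter_window()
        v[ps // 10: pe // 10] = 5.0
        chip = CoverageTrack({"chr1": v}, 10)
        active = call_active_genes(chip, constant_track(1.0), [GENE], 2.0, 0.3)
        assert [g.gene_id for g in active] == ["g"]

    def test_active_set_shrinks_with_threshold(self):
        rng = np.random.default_rng(35)
        genes = [GeneModel(f"g{k}", "chr1", "+", 1_000 + 5_000 * k, 4_000 + 5_000 * k)
                 for k in range(10)]
        chip = CoverageTrack({"chr1": rng.random(6_000) * 4}, 10)
        inp = constant_track(1.0, length=60_000)
        sizes = [
            len(call_active_genes(chip, inp, genes, t, 0.1)) for t in (1.0, 2.0, 3.0, 4.0)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestMetagene:
    def test_constant_coverage_flat_profile(self):
        prof = metagene_profile(constant_track(2.5), [GENE], 50, 1_000, 10)
        np.testing.assert_allclose(prof, 2.5)
        assert len(prof) == 70

    def test_single_gene_profile_is_own_coverage(self):
        v = np.arange(2_000, dtype=float)
        track = CoverageTrack({"chr1": v}, 10)
        prof = metagene_profile(track, [GENE], n_body_bins=10, flank_bp=1_000, n_flank_bins=2)
        expected_body = [
            interval_density(track, "chr1", 5_000 + k * 1_000, 5_000 + (k + 1) * 1_000)
            for k in range(10)
        ]
        np.testing.assert_allclose(prof[2:12], expected_body)

    def test_two_constant_genes_average(self):
        g2 = GeneModel("h", "chr2", "+", 5_000, 15_000)
        track = CoverageTrack(
            {"chr1": np.full(2_000, 1.0), "chr2": np.full(2_000, 3.0)}, 10
        )
        prof = metagene_profile(track, [GENE, g2], 20, 500, 5)
        np.testing.assert_allclose(prof, 2.0)

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            metagene_profile(constant_track(1.0), [])


class TestCompareDistributions:
    def test_identical_samples_p_one(self):
        _, p = compare_distributions([2.0, 2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_fully_separated_small_samples(self):
        u, p = compare_distributions([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_exact_matches_independent_enumeration(self):
        # oracle: direct enumeration written independently of the implementation
        rng = np.random.default_rng(36)
        cases = [
            ([1, 1, 2], [2, 3]),
            ([1.5, 1.5], [1.5, 2.5, 3.5]),
            (rng.normal(size=4).tolist(), rng.normal(size=5).tolist()),
            (rng.integers(0, 3, size=6).tolist(), rng.integers(0, 3, size=6).tolist()),
        ]
        for a, b in cases:
            u_got, p_got = compare_distributions(a, b)
            pooled = np.concatenate([a, b])
            if np.all(pooled == pooled[0]):
                continue
            ranks = stats.rankdata(pooled)
            n1 = len(a)
            u_all = [
                sum(ranks[list(c)]) - n1 * (n1 + 1) / 2
                for c in itertools.combinations(range(len(pooled)), n1)
            ]
            u_obs = sum(ranks[:n1]) - n1 * (n1 + 1) / 2
            p_le = np.mean([u <= u_obs + 1e-9 for u in u_all])
            p_ge = np.mean([u >= u_obs - 1e-9 for u in u_all])
            assert u_got == pytest.approx(u_obs)
            assert p_got == pytest.approx(min(1.0, 2 * min(p_le, p_ge)))

    def test_large_sample_power(self):
        rng = np.random.default_rng(37)
        a = rng.normal(0.0, 1.0, size=5_000)
        b = rng.normal(0.5, 1.0, size=5_000)
        _, p = compare_distributions(a, b)
        assert p < 1e-6

    def test_large_sample_matches_scipy(self):
        rng = np.random.default_rng(38)
        a = rng.normal(size=40)
        b = rng.normal(0.3, size=50)
        u, p = compare_distributions(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestCumulativeCurve:
    def test_percent_at_median(self):
        curve = cumulative_curve([1, 2, 3, 4])
        as_dict = {v: p for v, p in curve}
        assert as_dict[2] == 50.0
        assert curve[-1, 1] == 100.0

    def test_single_value(self):
        curve = cumulative_curve([7.0])
        assert curve.tolist() == [[7.0, 100.0]]

    def test_monotone_nondecreasing(self):
        curve = cumulative_curve(np.random.default_rng(39).normal(size=200))
        assert np.all(np.diff(curve[:, 1]) >= 0)
        assert np.all(np.diff(curve[:, 0]) > 0)
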