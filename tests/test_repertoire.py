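"""Repertoire analytics: TMM, quantile classes, summits, clusters, profiles."""

import numpy as np
import pytest

from oriscan import (
    ActivityMatrix,
    CoverageTrack,
    GenomeSequence,
    GenomicInterval,
    call_summit,
    classify_quantiles,
    cluster_origins,
    composition_profile,
    distance_profile,
    normalize_activity,
    orient_origin,
    signal_fraction_by_class,
)


def iv(start, end, chrom="c", strand="."):
    return GenomicInterval(chrom, start, end, strand)


def matrix(counts, background=None):
    counts = np.asarray(counts, dtype=float)
    n, s = counts.shape
    origins = [iv(i * 1000, i * 1000 + 500) for i in range(n)]
    bg = np.zeros_like(counts) if background is None else np.asarray(background)
    return ActivityMatrix(origins, [f"s{j}" for j in range(s)], counts, bg)


class TestTmmNormalization:
    def test_identical_samples_factor_one(self):
        res = normalize_activity(matrix([[10, 10], [20, 20], [5, 5]]))
        assert np.allclose(res.tmm_factors, 1.0)
        assert np.allclose(res.scale_factors, 1.0)

    def test_pure_depth_doubling(self):
        counts = np.array([[10, 20], [30, 60], [5, 10]], dtype=float)
        res = normalize_activity(matrix(counts))
        assert np.allclose(res.tmm_factors, 1.0)
        assert np.allclose(res.scale_factors, [1.0, 2.0])
        assert np.allclose(res.matrix[:, 0], res.matrix[:, 1])

    def test_background_subtraction_clamped(self):
        counts = [[10.0, 10.0], [2.0, 2.0]]
        bg = [[3.0, 3.0], [5.0, 5.0]]
        res = normalize_activity(matrix(counts, bg))
        assert np.allclose(res.matrix[:, 0], [7.0, 0.0])

    def test_matches_edger_reference_implementation(self):
        # oracle from edgeR::calcNormFactors(x, method="TMM", refColumn=1)
        # on this exact seeded matrix (bioconductor-edger, R 4.x)
        rng = np.random.default_rng(42)
        means = rng.uniform(5, 200, size=300)
        depth = np.array([1.0, 1.6, 0.7, 1.2])
        counts = rng.poisson(means[:, None] * depth[None, :])
        res = normalize_activity(matrix(counts))
        assert res.reference_sample == 0
        assert np.allclose(
            res.tmm_factors, [1.001952, 0.996943, 1.003956, 0.997168], atol=5e-7
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            matrix([[-1.0, 2.0]])


class TestQuantileClasses:
    def test_even_partition_20_origins(self):
        act = np.arange(20, 0, -1, dtype=float)  # origin 0 most active
        res = classify_quantiles(act)
        assert np.bincount(res.quantile, minlength=11)[1:].tolist() == [2] * 10
        assert res.quantile[0] == 1 and res.quantile[19] == 10
        assert res.klass[0] == "core" and res.klass[5] == "stochastic"

    def test_remainder_goes_to_lowest_quantiles(self):
        act = np.arange(23, 0, -1, dtype=float)
        res = classify_quantiles(act)
        sizes = np.bincount(res.quantile, minlength=11)[1:].tolist()
        assert sizes == [2] * 7 + [3] * 3

    def test_large_repertoire_bookkeeping(self):
        # the 320,748 / 10 partition: 2 x 32,074 core + 8 x 32,075 stochastic
        n = 320_748
        rng = np.random.default_rng(0)
        res = classify_quantiles(rng.random(n))
        assert int((res.klass == "core").sum()) == 64_148
        assert int((res.klass == "stochastic").sum()) == 256_600

    def test_ties_break_by_genomic_order(self):
        act = np.array([5.0, 5.0, 5.0, 5.0, 1.0] * 2)
        origins = [iv(s * 100, s * 100 + 50) for s in range(10)]
        res = classify_quantiles(act, origins=origins)
        tied = [i for i in range(10) if act[i] == 5.0]
        # earlier genomic position -> higher quantile rank among ties
        quants = [res.quantile[i] for i in tied]
        assert quants == sorted(quants)

    def test_super_origin_overlay(self):
        act = np.array([60.0, 50.0] + [1.0] * 18)
        res = classify_quantiles(act)
        assert res.super_origin.tolist() == [True] + [False] * 19

    def test_too_few_origins_raises(self):
        with pytest.raises(ValueError):
            classify_quantiles(np.ones(5))


class TestSignalFractions:
    def test_hand_example(self):
        norm = np.array([[8.0, 6.0], [2.0, 4.0]])
        df = signal_fraction_by_class(norm, ["core", "stochastic"], ["a", "b"])
        assert df.loc["core", "a"] == pytest.approx(0.8)
        assert df.loc["stochastic", "b"] == pytest.approx(0.4)
        assert np.allclose(df.sum(axis=0), 1.0)

    def test_zero_total_sample_raises(self):
        with pytest.raises(ValueError):
            signal_fraction_by_class(np.zeros((2, 1)), ["core", "core"])


class TestSummits:
    def test_triangular_peak_recovered(self):
        # per-base coverage rising to a peak at 1000 then falling: the best
        # 50-bp bin is centred on the apex
        starts = np.arange(800, 1200)
        values = 200 - np.abs(starts - 1000)
        cov = CoverageTrack("c", starts, starts + 1, values)
        call = call_summit(cov, iv(800, 1200))
        assert call.from_signal
        assert abs(call.summit - 1000) <= 25

    def test_zero_coverage_reports_midpoint(self):
        cov = CoverageTrack("c", [0], [10], [5.0])
        call = call_summit(cov, iv(5000, 6000))
        assert call.summit == 5500 and not call.from_signal

    def test_tie_goes_leftmost(self):
        cov = CoverageTrack("c", [100, 300], [150, 350], [2.0, 2.0])
        call = call_summit(cov, iv(0, 500))
        assert call.summit == 125


class TestOrientation:
    def test_g_rich_left_is_plus(self):
        g = GenomeSequence("c", "G" * 500 + "A" * 500)
        assert orient_origin(g, 500) == "+"

    def test_g_rich_right_is_minus(self):
        g = GenomeSequence("c", "A" * 500 + "G" * 500)
        assert orient_origin(g, 500) == "-"

    def test_tie_is_plus(self):
        g = GenomeSequence("c", "A" * 1000)
        assert orient_origin(g, 500) == "+"


class TestClusters:
    def test_tight_isolated_loose(self):
        tight = [iv(k * 5000, k * 5000 + 100) for k in range(6)]
        lone = [iv(200_000, 200_100)]
        pair = [iv(300_000, 300_100), iv(310_000, 310_100)]
        out = cluster_origins(tight + lone + pair)
        classes = {o[0].start: o[2] for o in out}
        assert all(classes[t.start] == "tight" for t in tight)
        assert classes[200_000] == "isolated"
        assert classes[300_000] == "loose" and classes[310_000] == "loose"

    def test_cluster_ids_shared_within_chain(self):
        out = cluster_origins([iv(0, 100), iv(5000, 5100), iv(50_000, 50_100)])
        assert out[0][1] == out[1][1] != out[2][1]


class TestCompositionProfile:
    def test_flat_background_near_uniform(self):
        rng = np.random.default_rng(2)
        seq = bytes(rng.choice(np.frombuffer(b"ACGT", np.uint8), 1_000_000)).decode()
        genomes = {"c": GenomeSequence("c", seq)}
        # 300 summits with disjoint 3-kb flanks: each smoothed point pools
        # 300 x 100 independent draws, SD ~ 0.0025, so 0.02 is an 8-sigma bound
        summits = [
            GenomicInterval("c", p, p + 1, "+") for p in range(2000, 902_000, 3000)
        ]
        prof = composition_profile(genomes, summits)
        assert np.all(np.abs(prof.frequencies.to_numpy() - 0.25) < 0.02)

    def test_planted_g_block_upstream(self):
        seq = "A" * 2000 + "G" * 500 + "T" * 2000
        genomes = {"c": GenomeSequence("c", seq)}
        prof = composition_profile(
            genomes, [GenomicInterval("c", 2500, 2501, "+")], smooth=1
        )
        assert prof.frequencies.loc[-250, "G"] == 1.0
        assert prof.frequencies.loc[250, "T"] == 1.0

    def test_minus_strand_contributes_revcomp(self):
        seq = "A" * 2000 + "G" * 500 + "T" * 2000
        genomes = {"c": GenomeSequence("c", seq)}
        plus = composition_profile(
            genomes, [GenomicInterval("c", 2500, 2501, "+")], smooth=1
        )
        minus = composition_profile(
            genomes, [GenomicInterval("c", 2000, 2001, "-")], smooth=1
        )
        # in the minus frame, the G block (revcomp -> C upstream becomes
        # A-complement ...) : position -250 of the minus profile reads the
        # complement of position +249 relative to 2000 on the plus strand
        assert minus.frequencies.loc[-250, "C"] == 1.0

    def test_edge_summits_skipped(self):
        genomes = {"c": GenomeSequence("c", "ACGT" * 2000)}
        with pytest.raises(ValueError):
            composition_profile(genomes, [GenomicInterval("c", 10, 11, "+")])


class TestDistanceProfile:
    def test_upstream_feature_negative_distance(self):
        summits = [GenomicInterval("c", 1000, 1001, "+")]
        feats = [GenomicInterval("c", 700, 701)]
        prof = distance_profile(summits, feats)
        assert prof.distances.tolist() == [-300.0]
        assert prof.median_abs == 300.0

    def test_far_features_excluded(self):
        summits = [GenomicInterval("c", 1000, 1001, "+")]
        feats = [GenomicInterval("c", 500_000, 500_001)]
        prof = distance_profile(summits, feats, max_dist=10_000)
        assert prof.distances.size == 0 and np.isnan(prof.median_abs)

    def test_histogram_mass_equals_count(self):
        summits = [GenomicInterval("c", 10_000, 10_001, "+")]
        feats = [GenomicInterval("c", 10_000 + d, 10_001 + d) for d in (-300, 150, 900)]
        prof = distance_profile(summits, feats)
        assert prof.hist.sum() == 3
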