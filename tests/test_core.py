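"""Interval algebra, format IO and enrichment statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oriscan import (
    GenomicInterval,
    chisq_gof_enrichment,
    cluster_intervals,
    merge_intervals,
    nearest_distances,
    overlap_count,
    read_fasta,
    read_intervals,
    shuffle_intervals,
    total_covered,
    write_intervals,
)


def iv(start, end, chrom="c1", strand=".", score=None):
    return GenomicInterval(chrom, start, end, strand, score)


class TestFasta:
    def test_case_folding_and_length(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c1\nacgt\n")
        g = read_fasta(p)
        assert g["c1"].seq == "ACGT" and g["c1"].length == 4

    def test_multi_record(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c1\nACGT\n>c2\nNNNN\n")
        g = read_fasta(p)
        assert set(g) == {"c1", "c2"} and g["c2"].seq == "NNNN"

    def test_ambiguity_codes_become_n(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c1\nARGT\n")
        assert read_fasta(p)["c1"].seq == "ANGT"

    @pytest.mark.parametrize("text", ["", "ACGT\n"])
    def test_malformed_input_raises(self, tmp_path, text):
        p = tmp_path / "bad.fa"
        p.write_text(text)
        with pytest.raises(ValueError):
            read_fasta(p)


class TestIntervalIO:
    def test_bed3_and_sorting(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("c2\t0\t50\nc1\t10\t20\nc1\t0\t5\n")
        ivs = read_intervals(p, "BED3")
        assert [(i.chrom, i.start, i.end) for i in ivs] == [
            ("c1", 0, 5), ("c1", 10, 20), ("c2", 0, 50)
        ]
        assert all(i.strand == "." for i in ivs)

    def test_empty_interval_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("c1\t0\t10\nc1\t5\t5\n")
        with pytest.raises(ValueError, match=":2"):
            read_intervals(p, "BED3")

    def test_roundtrip_bit_exact(self, tmp_path):
        ivs = [iv(0, 100, strand="+", score=3.5), iv(250, 300, "c2", "-", 1.0)]
        p = tmp_path / "rt.bed"
        write_intervals(p, ivs, "BED6")
        again = read_intervals(p, "BED6")
        assert [(i.chrom, i.start, i.end, i.strand, i.score) for i in again] == [
            (i.chrom, i.start, i.end, i.strand, i.score) for i in sorted(ivs)
        ]
        first = p.read_text()
        write_intervals(p, again, "BED6")
        assert p.read_text() == first


class TestMerge:
    @pytest.mark.parametrize(
        "spans,gap,expected",
        [
            ([(0, 500), (100, 600)], 0, [(0, 600)]),
            ([(0, 100), (100, 200)], 0, [(0, 200)]),       # book-ended
            ([(0, 100), (200, 300)], 99, [(0, 100), (200, 300)]),
            ([(0, 100), (200, 300)], 100, [(0, 300)]),     # gap boundary
        ],
    )
    def test_examples(self, spans, gap, expected):
        merged = merge_intervals([iv(*s) for s in spans], max_gap=gap)
        assert [(m.start, m.end) for m in merged] == expected

    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 100)), min_size=1, max_size=30
        ),
        st.integers(0, 50),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_idempotent_and_coverage_preserving(self, pairs, gap):
        ivs = [iv(s, s + l) for s, l in pairs]
        once = merge_intervals(ivs, gap)
        assert merge_intervals(once, gap) == once
        # union of covered bases preserved when gap = 0
        assert total_covered(merge_intervals(ivs, 0)) == total_covered(ivs)
        # covered bases never decrease with gap
        assert total_covered(once) >= total_covered(merge_intervals(ivs, 0))


class TestCluster:
    def test_within_gap_shares_id(self):
        out = cluster_intervals([iv(0, 1000), iv(5000, 6000)], max_gap=7000)
        assert out[0][1] == out[1][1]

    def test_beyond_gap_splits(self):
        out = cluster_intervals([iv(0, 1000), iv(9000, 10000)], max_gap=7000)
        assert out[0][1] != out[1][1]

    def test_singleton(self):
        out = cluster_intervals([iv(0, 1000)], max_gap=7000)
        assert len(out) == 1


class TestShuffle:
    GENOME = {"c1": 100_000, "c2": 50_000}

    def test_deterministic_under_seed(self):
        ivs = [iv(0, 1000), iv(5000, 5500, "c2")]
        a = shuffle_intervals(ivs, self.GENOME, seed=7)
        b = shuffle_intervals(ivs, self.GENOME, seed=7)
        assert a == b

    def test_lengths_and_chromosomes_preserved(self):
        ivs = [iv(0, 1000), iv(2000, 2300), iv(0, 700, "c2")]
        out = shuffle_intervals(ivs, self.GENOME, seed=1)
        assert sorted(i.length for i in out) == sorted(i.length for i in ivs)
        assert sorted(i.chrom for i in out) == sorted(i.chrom for i in ivs)

    def test_mean_overlap_matches_binomial_expectation(self):
        # a fixed mask covering 10% of the chromosome: the expected fraction
        # of shuffled 1-kb intervals hitting it is ~ (mask + interval extent)
        genome = {"c1": 1_000_000}
        mask = [iv(k * 100_000, k * 100_000 + 10_000) for k in range(10)]
        ivs = [iv(0, 1000) for _ in range(20)]
        rng = np.random.default_rng(123)
        hits = [
            overlap_count(
                shuffle_intervals(ivs, genome, seed=int(s), no_overlap=False), mask
            )
            for s in rng.integers(0, 2**31 - 1, size=1000)
        ]
        # P(hit) for a uniformly placed 1-kb interval vs 10-kb mask blocks
        # every 100 kb: hit window is 10000+999 bp per block (clipped at 0)
        expect = 20 * (9 * 10_999 + 10_000) / (1_000_000 - 1000 + 1)
        assert np.mean(hits) == pytest.approx(expect, rel=0.06)


class TestOverlapAndEnrichment:
    def test_overlap_basic_and_slop(self):
        a = [iv(0, 100)]
        assert overlap_count(a, [iv(50, 60)]) == 1
        assert overlap_count(a, [iv(2090, 2100)], slop=2000) == 1
        assert overlap_count(a, [iv(200, 300)]) == 0

    def test_chisq_null_and_hand_oracle(self):
        chi2, p = chisq_gof_enrichment(20, 100, 20)
        assert chi2 == 0.0 and p == 1.0
        chi2, _ = chisq_gof_enrichment(30, 100, 20)
        assert chi2 == pytest.approx(6.25)
        # depletion uses the same formula
        chi2_dep, _ = chisq_gof_enrichment(10, 100, 20)
        assert chi2_dep == pytest.approx(100 / 20 + 100 / 80)

    def test_chisq_degenerate_expectation_raises(self):
        with pytest.raises(ValueError):
            chisq_gof_enrichment(5, 100, 0)


class TestNearestDistances:
    def test_strand_orientation(self):
        a_plus = [GenomicInterval("c1", 1000, 1001, "+")]
        a_minus = [GenomicInterval("c1", 1000, 1001, "-")]
        b = [GenomicInterval("c1", 700, 701)]
        assert nearest_distances(a_plus, b, 10_000) == [-300.0]
        assert nearest_distances(a_minus, b, 10_000) == [300.0]

    def test_max_dist_excludes(self):
        a = [GenomicInterval("c1", 1000, 1001, "+")]
        b = [GenomicInterval("c1", 13_000, 13_001)]
        assert nearest_distances(a, b, 10_000) == []

    def test_all_hits_within_range_reported(self):
        a = [GenomicInterval("c1", 1000, 1001, "+")]
        b = [GenomicInterval("c1", 700, 701), GenomicInterval("c1", 1300, 1301)]
        assert sorted(nearest_distances(a, b, 10_000)) == [-300.0, 300.0]
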