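"""Midpoint-distance overlap, multi-set intersection and the shuffle null."""

import numpy as np
import pytest

from peaklab.intervals import GenomicInterval, Genome, PeakSet
from peaklab.overlap import intersect_n, midpoint_overlap, permutation_test
from peaklab.synthetic import SyntheticConfig, generate


def ps(label, *triples, genome_id="g"):
    return PeakSet(
        label, tuple(GenomicInterval(c, s, e) for c, s, e in triples), genome_id
    )


def random_point_set(label, n, length, rng, chrom="chr1"):
    starts = rng.choice(length - 1, size=n, replace=False)
    return PeakSet(
        label,
        tuple(GenomicInterval(chrom, int(s), int(s) + 1) for s in starts),
        "g",
    )


def brute_force_pairs(a, b, max_dist):
    return tuple(sorted(
        (i, j)
        for i, x in enumerate(a)
        for j, y in enumerate(b)
        if x.chrom == y.chrom and abs(x.midpoint - y.midpoint) <= max_dist
    ))


class TestMidpointOverlap:
    def test_inclusive_distance_rule(self):
        a = ps("a", ("chr1", 100, 200))       # midpoint 150
        b = ps("b", ("chr1", 300, 500))       # midpoint 400
        assert midpoint_overlap(a, b, 300).observed == 1
        assert midpoint_overlap(a, b, 250).observed == 1  # distance exactly 250
        assert midpoint_overlap(a, b, 200).observed == 0

    def test_different_chromosomes_never_pair(self):
        a = ps("a", ("chr1", 100, 200))
        b = ps("b", ("chr2", 100, 200))
        assert midpoint_overlap(a, b, 10_000).observed == 0

    def test_genome_id_mismatch_rejected(self):
        a = ps("a", ("chr1", 1, 2), genome_id="x")
        b = ps("b", ("chr1", 1, 2), genome_id="y")
        with pytest.raises(ValueError):
            midpoint_overlap(a, b)

    def test_matches_quadratic_oracle_on_random_sets(self):
        rng = np.random.default_rng(17)
        a = random_point_set("a", 200, 100_000, rng)
        b = random_point_set("b", 200, 100_000, rng)
        result = midpoint_overlap(a, b, 300)
        expected = brute_force_pairs(a, b, 300)
        assert result.pairs == expected
        assert result.observed == len({i for i, _ in expected})

    def test_pair_list_transposes(self):
        rng = np.random.default_rng(23)
        a = random_point_set("a", 50, 20_000, rng)
        b = random_point_set("b", 80, 20_000, rng)
        ab = midpoint_overlap(a, b, 300)
        ba = midpoint_overlap(b, a, 300)
        assert sorted((j, i) for i, j in ab.pairs) == sorted(ba.pairs)


class TestIntersectN:
    def test_identical_sets_return_first_unchanged(self):
        a = ps("a", ("chr1", 0, 100), ("chr1", 5_000, 5_100), ("chr2", 9, 99))
        result = intersect_n([a, a, a])
        assert result.intervals == a.intervals

    def test_empty_second_set_gives_empty_result(self):
        a = ps("a", ("chr1", 0, 100))
        assert len(intersect_n([a, PeakSet("b", (), "g")])) == 0

    def test_recovers_planted_common_sites(self, bundle):
        common = intersect_n([bundle.partners, bundle.reference])
        n_planted = sum(bundle.truth.partner_planted)
        assert len(common) == n_planted
        planted_names = {
            name for name, flag
            in zip(bundle.truth.partner_names, bundle.truth.partner_planted)
            if flag
        }
        assert {iv.name for iv in common} == planted_names


class TestPermutationTest:
    @pytest.fixture
    def genome(self):
        return Genome({"chr1": 1_000_000}, genome_id="g")

    def test_single_peak_against_itself(self, genome):
        a = ps("a", ("chr1", 100, 200))
        result = permutation_test(a, a, genome, max_dist=300, n_perm=10, seed=1)
        assert result.observed == 1
        k = sum(1 for c in result.perm_counts if c >= 1)
        assert result.p_value == pytest.approx((1 + k) / 11)

    def test_pvalue_bounds_and_expected_mean(self, genome):
        rng = np.random.default_rng(2)
        a = random_point_set("a", 50, 1_000_000, rng)
        b = random_point_set("b", 50, 1_000_000, rng)
        result = permutation_test(a, b, genome, 300, n_perm=99, seed=4)
        assert 1 / 100 <= result.p_value <= 1.0
        assert result.expected == pytest.approx(np.mean(result.perm_counts))

    def test_expected_matches_uniform_closed_form(self, genome):
        rng = np.random.default_rng(7)
        a = random_point_set("a", 100, 1_000_000, rng)
        b = random_point_set("b", 100, 1_000_000, rng)
        result = permutation_test(a, b, genome, 300, n_perm=200, seed=3)
        analytic = 100 * (1 - (1 - 601 / 1_000_000) ** 100)
        se = np.std(result.perm_counts) / np.sqrt(200)
        assert abs(result.expected - analytic) <= 3 * se

    def test_planted_overlap_saturates_pvalue(self):
        b = generate(
            SyntheticConfig(
                n_chroms=2, chrom_length=800_000, n_genes=10, n_peaks=200,
                frac_promoter=0, frac_intronic=0, frac_intergenic=1,
                partner_overlap_frac=0.30, replicate_private=0,
                with_sequence=False, n_interactions=50, seed=9,
            )
        )
        genome = b.genome
        result = permutation_test(
            b.partners, b.reference, genome, 300, n_perm=999, seed=5
        )
        assert result.observed == 60
        assert result.p_value == pytest.approx(1 / 1000)

    def test_stream_prefix_reproducible(self, genome):
        rng = np.random.default_rng(31)
        a = random_point_set("a", 30, 1_000_000, rng)
        b = random_point_set("b", 30, 1_000_000, rng)
        short = permutation_test(a, b, genome, 300, n_perm=50, seed=8)
        long = permutation_test(a, b, genome, 300, n_perm=100, seed=8)
        assert long.perm_counts[:50] == short.perm_counts

    def test_interval_longer_than_chromosome_rejected(self):
        genome = Genome({"chr1": 500}, genome_id="g")
        b = ps("b", ("chr1", 0, 400))
        with pytest.raises(ValueError):
            permutation_test(ps("a", ("chr1", 0, 600)), b, genome)

    def test_exclusion_mask_respected(self, genome):
        rng = np.random.default_rng(12)
        a = random_point_set("a", 20, 1_000_000, rng)
        b = random_point_set("b", 20, 1_000_000, rng)
        mask = ps("mask", ("chr1", 0, 900_000))
        result = permutation_test(a, b, genome, 300, n_perm=20, seed=6, exclude=mask)
        assert result.n_perm == 20  # completed without placement failure


class TestPermutationInvariants:
    def test_lengths_and_counts_preserved_under_shuffle(self):
        # the null re-places intervals within their own chromosome, so a
        # partner set on an absent chromosome can never be hit
        genome = Genome({"chr1": 10_000, "chr2": 10_000}, genome_id="g")
        a = ps("a", ("chr1", 0, 100), ("chr1", 500, 900))
        b = ps("b", ("chr2", 0, 100))
        result = permutation_test(a, b, genome, 5_000, n_perm=50, seed=0)
        assert result.observed == 0
        assert all(c == 0 for c in result.perm_counts)
        assert result.p_value == 1.0
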