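"""Interval model, BED round-trips and replicate-consistency filtering."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from peaklab.intervals import (
    BedParseError,
    GenomicInterval,
    Genome,
    PeakSet,
    intersect_replicates,
    midpoint,
    read_bed,
    read_chrom_sizes,
    write_bed,
)


def ps(label, *triples, genome_id="g"):
    return PeakSet(
        label, tuple(GenomicInterval(c, s, e) for c, s, e in triples), genome_id
    )


class TestGenomicInterval:
    def test_rejects_inverted_and_negative_coordinates(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -5, 100)

    @pytest.mark.parametrize(
        "start,end,expected",
        [(100, 200, 150), (100, 201, 150), (56889725, 56889913, 56889819)],
    )
    def test_midpoint_floor_rule(self, start, end, expected):
        assert midpoint(GenomicInterval("chr7", start, end)) == expected

    @given(
        start=st.integers(min_value=0, max_value=10**6),
        length=st.integers(min_value=1, max_value=10**5),
    )
    @settings(max_examples=200, derandomize=True)
    def test_midpoint_always_inside_interval(self, start, length):
        iv = GenomicInterval("chr1", start, start + length)
        assert iv.start <= iv.midpoint < iv.end


class TestPeakSet:
    def test_iteration_sorted_and_duplicates_collapsed(self):
        ivs = (
            GenomicInterval("chr2", 50, 60),
            GenomicInterval("chr1", 100, 200),
            GenomicInterval("chr1", 100, 200),
            GenomicInterval("chr1", 10, 20),
        )
        peaks = PeakSet("x", ivs)
        assert [(iv.chrom, iv.start) for iv in peaks] == [
            ("chr1", 10), ("chr1", 100), ("chr2", 50)
        ]

    def test_validate_against_genome_bounds(self):
        genome = Genome({"chr1": 150})
        ps("a", ("chr1", 0, 100)).validate_against(genome)
        with pytest.raises(ValueError):
            ps("b", ("chr1", 100, 200)).validate_against(genome)
        with pytest.raises(ValueError):
            ps("c", ("chr9", 0, 10)).validate_against(genome)


class TestBedIO:
    def test_basic_line_and_skips(self, tmp_path):
        path = tmp_path / "x.bed"
        path.write_text(
            "track name=test\nbrowser position\n# comment\n"
            "chr1\t100\t200\tpk1\n\nchr2\t5\t50\n"
        )
        peaks = read_bed(path, "x")
        assert len(peaks) == 2
        assert peaks[0] == GenomicInterval("chr1", 100, 200, "pk1")

    def test_empty_file_gives_empty_set(self, tmp_path):
        path = tmp_path / "empty.bed"
        path.write_text("")
        assert len(read_bed(path, "x")) == 0

    @pytest.mark.parametrize(
        "line", ["chr1\tabc\t200", "chr1\t300\t200", "chr1\t100"]
    )
    def test_malformed_line_names_line_number(self, tmp_path, line):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t1\t2\n" + line + "\n")
        with pytest.raises(BedParseError, match=":2"):
            read_bed(path, "x")

    @given(
        triples=st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr2", "chrX"]),
                st.integers(min_value=0, max_value=10**6),
                st.integers(min_value=1, max_value=10**4),
            ),
            min_size=0,
            max_size=30,
        )
    )
    @settings(max_examples=50, derandomize=True)
    def test_roundtrip_preserves_coordinates(self, triples, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("bed")
        peaks = PeakSet(
            "rt",
            tuple(GenomicInterval(c, s, s + w) for c, s, w in triples),
        )
        write_bed(peaks, tmp / "rt.bed")
        again = read_bed(tmp / "rt.bed", "rt")
        assert again.intervals == peaks.intervals

    def test_bed6_roundtrip_keeps_name_score_strand(self, tmp_path):
        peaks = PeakSet(
            "x",
            (GenomicInterval("chr1", 1, 9, "pk", 3.5, "-"),
             GenomicInterval("chr1", 20, 30, "pk2", None, "+")),
        )
        write_bed(peaks, tmp_path / "six.bed")
        assert read_bed(tmp_path / "six.bed", "x").intervals == peaks.intervals

    def test_chrom_sizes_reader(self, tmp_path):
        path = tmp_path / "sizes"
        path.write_text("chr1\t1000\nchr2\t500\n")
        genome = read_chrom_sizes(path)
        assert genome.chrom_sizes == {"chr1": 1000, "chr2": 500}


class TestIntersectReplicates:
    def test_chained_overlap_keeps_first_replicate_interval(self):
        a = ps("a", ("chr1", 100, 200))
        b = ps("b", ("chr1", 150, 250))
        c = ps("c", ("chr1", 180, 300))
        result = intersect_replicates([a, b, c])
        assert result.intervals == a.intervals

    def test_one_failing_replicate_drops_the_peak(self):
        a = ps("a", ("chr1", 100, 200))
        b = ps("b", ("chr1", 400, 500))
        c = ps("c", ("chr1", 100, 200))
        assert len(intersect_replicates([a, b, c])) == 0

    def test_min_bp_threshold(self):
        a = ps("a", ("chr1", 100, 200))
        b = ps("b", ("chr1", 195, 300))  # 5 bp overlap
        assert len(intersect_replicates([a, b], min_bp=5)) == 1
        assert len(intersect_replicates([a, b], min_bp=6)) == 0

    def test_genome_id_mismatch_rejected(self):
        a = ps("a", ("chr1", 1, 10), genome_id="mm9")
        b = ps("b", ("chr1", 1, 10), genome_id="hg19")
        with pytest.raises(ValueError, match="genome_id"):
            intersect_replicates([a, b])

    def test_recovers_exactly_the_shared_peaks(self):
        from peaklab.synthetic import SyntheticConfig, generate

        b = generate(
            SyntheticConfig(
                n_chroms=2, chrom_length=600_000, n_genes=10, n_peaks=30,
                replicate_private=20, with_sequence=False, n_interactions=10,
                seed=3,
            )
        )
        assert all(len(rep) == 50 for rep in b.replicates)
        result = intersect_replicates(list(b.replicates))
        # brute-force all-pairs oracle over the same inputs
        def overlaps_somewhere(iv, rep):
            return any(iv.overlap_bp(other) >= 1 for other in rep)

        expected = tuple(
            iv for iv in b.replicates[0]
            if all(overlaps_somewhere(iv, rep) for rep in b.replicates[1:])
        )
        assert result.intervals == expected
        assert len(result) == 30
        assert all(iv.name.startswith("shared_") for iv in result)

    def test_idempotent_and_order_invariant_in_later_replicates(self):
        a = ps("a", ("chr1", 100, 200), ("chr1", 500, 600), ("chr2", 0, 50))
        b = ps("b", ("chr1", 150, 250), ("chr2", 10, 40))
        c = ps("c", ("chr1", 120, 130), ("chr2", 45, 90))
        result = intersect_replicates([a, b, c])
        assert set(result.intervals) <= set(a.intervals)
        assert intersect_replicates([result, b, c]).intervals == result.intervals
        swapped = intersect_replicates([a, c, b])
        assert swapped.intervals == result.intervals
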