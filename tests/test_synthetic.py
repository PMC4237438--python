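"""Generator determinism, unambiguous placement and bundle round-trips."""

import dataclasses

import pytest

from peaklab.annotation import read_gene_table
from peaklab.conservation import ConservationTrack, mean_score
from peaklab.intervals import read_bed, read_chrom_sizes, read_fasta
from peaklab.network import load_interactions
from peaklab.synthetic import (
    SyntheticConfig,
    SyntheticConfigError,
    generate,
    sox3_de_gene_list,
    sox3_target_table,
    write_bundle,
)


class TestConfigValidation:
    def test_category_fractions_must_sum_to_one(self):
        with pytest.raises(SyntheticConfigError):
            SyntheticConfig(frac_promoter=0.5, frac_intronic=0.5, frac_intergenic=0.5)

    def test_fraction_bounds(self):
        with pytest.raises(SyntheticConfigError):
            SyntheticConfig(motif_plant_frac=1.5)

    def test_jitter_must_preserve_overlap(self):
        with pytest.raises(SyntheticConfigError):
            SyntheticConfig(peak_width_range=(80, 100), replicate_jitter=50)

    def test_infeasible_layouts_rejected(self):
        # too many peaks for the desert space available
        with pytest.raises(SyntheticConfigError):
            generate(SyntheticConfig(
                n_chroms=1, chrom_length=100_000, n_genes=2, n_peaks=500,
                frac_promoter=0, frac_intronic=0, frac_intergenic=1,
                with_sequence=False, n_interactions=1,
                interaction_peak_frac=0.0,
            ))
        # more promoter peaks than genes
        with pytest.raises(SyntheticConfigError):
            generate(SyntheticConfig(
                n_chroms=1, chrom_length=900_000, n_genes=2, n_peaks=50,
                frac_promoter=1, frac_intronic=0, frac_intergenic=0,
                with_sequence=False,
            ))


class TestGenerate:
    def test_deterministic_given_seed(self):
        a = generate(SyntheticConfig(n_peaks=40, n_genes=12, seed=5,
                                     n_interactions=20))
        b = generate(SyntheticConfig(n_peaks=40, n_genes=12, seed=5,
                                     n_interactions=20))
        assert a.reference.intervals == b.reference.intervals
        assert a.partners.intervals == b.partners.intervals
        assert a.interactions == b.interactions
        assert a.truth == b.truth
        assert a.genome.sequence == b.genome.sequence

    def test_different_seeds_differ(self):
        a = generate(SyntheticConfig(seed=1, with_sequence=False))
        b = generate(SyntheticConfig(seed=2, with_sequence=False))
        assert a.reference.intervals != b.reference.intervals

    def test_truth_vectors_align_with_sorted_reference(self, bundle):
        assert len(bundle.truth.names) == len(bundle.reference)
        assert bundle.truth.names == tuple(iv.name for iv in bundle.reference)
        assert len(bundle.truth.partner_names) == len(bundle.partners)

    def test_category_counts_follow_config(self, bundle):
        from collections import Counter

        counts = Counter(bundle.truth.categories)
        assert sum(counts.values()) == 100
        assert counts["promoter"] == 11
        # largest-remainder split of 28.5/60.5
        assert counts["intronic"] + counts["intergenic"] == 89

    def test_intergenic_only_config(self):
        b = generate(SyntheticConfig(
            n_chroms=2, chrom_length=500_000, n_genes=4, n_peaks=40,
            frac_promoter=0, frac_intronic=0, frac_intergenic=1,
            with_sequence=False, n_interactions=10, seed=2,
        ))
        from peaklab.annotation import annotate_peaks

        anns = annotate_peaks(b.reference, b.genes)
        assert all(a.category == "intergenic" for a in anns)

    def test_conservation_plateaus_cover_peaks_exactly(self, bundle):
        for iv, value, cls in zip(
            bundle.reference, bundle.truth.cons_value, bundle.truth.cons_class
        ):
            score = mean_score(iv, bundle.track)
            assert score == pytest.approx(value, abs=1e-12)
            if cls == "high":
                assert score > 0.5
            elif cls == "moderate":
                assert 0.1 < score <= 0.5

    def test_sequences_match_chromosome_sizes(self, bundle):
        for chrom, seq in bundle.genome.sequence.items():
            assert len(seq) == bundle.genome.chrom_sizes[chrom]
            assert set(seq) <= set("ACGT")


class TestWriteBundle:
    def test_files_reparse_to_original_structures(self, tmp_path, small_bundle):
        paths = write_bundle(small_bundle, tmp_path / "bundle")
        ref = read_bed(paths["reference"], "reference", "synthetic")
        assert ref.intervals == small_bundle.reference.intervals
        for i, rep in enumerate(small_bundle.replicates, start=1):
            again = read_bed(paths[f"replicate_{i}"], rep.label, "synthetic")
            assert again.intervals == rep.intervals
        partners = read_bed(paths["partners"], "partners", "synthetic")
        assert partners.intervals == small_bundle.partners.intervals
        genes = read_gene_table(paths["genes"], "synthetic")
        assert genes.genes == small_bundle.genes.genes
        genome = read_chrom_sizes(paths["chrom_sizes"], "synthetic")
        assert genome.chrom_sizes == small_bundle.genome.chrom_sizes
        pairs = load_interactions(paths["interactions"])
        assert len(pairs) == len(small_bundle.interactions)
        assert all(
            p.anchor_a.start == q.anchor_a.start and p.anchor_b.end == q.anchor_b.end
            for p, q in zip(pairs, small_bundle.interactions)
        )
        track = ConservationTrack.from_bedgraph(paths["track"])
        for iv in small_bundle.reference:
            assert mean_score(iv, track) == pytest.approx(
                mean_score(iv, small_bundle.track), abs=1e-6
            )

    def test_fasta_roundtrip(self, tmp_path):
        b = generate(SyntheticConfig(
            n_chroms=2, chrom_length=250_000, n_genes=4, n_peaks=10,
            replicate_private=2, n_interactions=5, seed=4,
        ))
        paths = write_bundle(b, tmp_path / "bundle")
        seqs = read_fasta(paths["fasta"])
        assert seqs == dict(b.genome.sequence)

    def test_config_json_roundtrip(self, tmp_path, small_bundle):
        from peaklab.synthetic import load_config

        paths = write_bundle(small_bundle, tmp_path / "bundle")
        assert load_config(paths["config"]) == small_bundle.config


class TestCuratedFixture:
    def test_record_and_gene_counts(self):
        table = sox3_target_table()
        assert len(table.peaks) == 19
        assert len(table.genes) == 13

    def test_coordinates_converted_to_zero_based(self):
        table = sox3_target_table()
        first = table.peaks[0]
        assert (first.chrom, first.start, first.end) == ("chr1", 129472319, 129472556)
        assert first.name == "Tmem163"

    def test_fold_changes(self):
        table = sox3_target_table()
        assert table.fold_changes["Sox3"] == pytest.approx(-4.10)
        assert table.fold_changes["Dbx1"] == pytest.approx(-2.35)
        assert table.fold_changes["Slit1"] == pytest.approx(1.87)

    def test_locations_align_with_sorted_peaks(self):
        table = sox3_target_table()
        assert len(table.locations) == len(table.peaks)
        # the Dbx1 peak is the known intron-2 binding site
        idx = [iv.name for iv in table.peaks].index("Dbx1")
        assert table.locations[idx] == "intron"
        assert table.peaks[idx].midpoint == 56889818

    def test_de_gene_list_has_six_placeholders(self):
        genes = sox3_de_gene_list()
        table = sox3_target_table()
        assert len(genes) == 19
        assert set(table.genes) <= set(genes)
        placeholders = set(genes) - set(table.genes)
        assert len(placeholders) == 6
        assert all(g.startswith("synthetic_") for g in placeholders)
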