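"""End-to-end orchestration of the peak-analysis stages.

``run_all`` executes, in order: replicate intersection → nearest-TSS
annotation → conservation scoring → partner-set overlap with permutation
significance → consensus-motif occurrence → gene-list enrichment →
interaction-network assembly.  Stages whose optional inputs are absent are
skipped with a logged notice; every threshold and seed is echoed into the
summary so each stage is auditable.  Two runs with the same configuration
and seed produce byte-identical output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import annotation as anno
from . import conservation as cons
from . import enrichment as enr
from . import motif as mot
from . import network as net
from . import overlap as ovl
from .intervals import Genome, PeakSet, read_bed, read_chrom_sizes, read_fasta, \
    intersect_replicates, write_bed

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Input paths and parameters for one pipeline run.

    Only peaks (or >=2 replicates) are required; every other input is
    optional and gates its stage.
    """

    peaks: Path | None = None
    replicates: tuple[Path, ...] = ()
    genes: Path | None = None
    chrom_sizes: Path | None = None
    track: Path | None = None
    fasta: Path | None = None
    partners: Path | None = None
    interactions: Path | None = None
    gene_list: Path | None = None

    genome_id: str = "custom"
    min_bp: int = 1
    promoter_window: int = 2000
    max_dist: int = 300
    motif: str = mot.SOX_CONSENSUS
    n_background: int = 1000
    n_perm: int = 1000
    merge_dist: int = 500
    seed: int = 0

    def validate(self) -> None:
        if self.peaks is None and len(self.replicates) < 2:
            raise ValueError("need --peaks or at least two --replicate inputs")
        for path in (
            self.peaks, self.genes, self.chrom_sizes, self.track, self.fasta,
            self.partners, self.interactions, self.gene_list, *self.replicates,
        ):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(str(path))


def run_all(config: RunConfig, outdir: str | Path) -> dict[str, object]:
    """Run every stage the configuration enables; write tables and a summary.

    Returns the summary as a dict (the same key/value lines written to
    ``summary.txt``).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, object] = {
        "param.genome_id": config.genome_id,
        "param.min_bp": config.min_bp,
        "param.promoter_window": config.promoter_window,
        "param.max_dist": config.max_dist,
        "param.motif": config.motif,
        "param.n_background": config.n_background,
        "param.n_perm": config.n_perm,
        "param.merge_dist": config.merge_dist,
        "param.seed": config.seed,
        "param.cons_threshold_moderate": cons.MODERATE_THRESHOLD,
        "param.cons_threshold_high": cons.HIGH_THRESHOLD,
    }

    genome: Genome | None = None
    if config.chrom_sizes is not None:
        genome = read_chrom_sizes(config.chrom_sizes, config.genome_id)

    # --- working peak set ---------------------------------------------------
    if len(config.replicates) >= 2:
        reps = [
            read_bed(p, f"rep{i + 1}", config.genome_id)
            for i, p in enumerate(config.replicates)
        ]
        peaks = intersect_replicates(reps, config.min_bp)
        summary["intersect.n_replicates"] = len(reps)
        summary["intersect.n_input"] = len(reps[0])
        summary["intersect.n_retained"] = len(peaks)
        write_bed(peaks, outdir / "consistent_peaks.bed")
    else:
        peaks = read_bed(config.peaks, "peaks", config.genome_id)
    summary["peaks.n"] = len(peaks)

    # --- annotation ---------------------------------------------------------
    peak_genes: set[str] = set()
    gene_set: anno.GeneSet | None = None
    if config.genes is not None:
        gene_set = anno.read_gene_table(config.genes, config.genome_id)
        annotations = anno.annotate_peaks(peaks, gene_set, config.promoter_window)
        anno.write_annotation_table(annotations, outdir / "annotations.tsv")
        fractions = anno.category_fractions(annotations)
        for cat in anno.CATEGORIES:
            summary[f"annotation.frac_{cat}"] = round(fractions[cat], 6)
        peak_genes = anno.genes_with_peaks(annotations)
        summary["annotation.n_genes_with_peaks"] = len(peak_genes)
    else:
        log.info("no gene table: skipping annotation stage")
        summary["annotation.skipped"] = True

    # --- conservation -------------------------------------------------------
    if config.track is not None:
        track = cons.ConservationTrack.from_bedgraph(config.track)
        cons_summary = cons.summarize(peaks, track)
        cons.write_summary(cons_summary, outdir / "conservation.tsv")
        for cls in cons.CLASSES:
            summary[f"conservation.frac_{cls}"] = round(cons_summary.fractions[cls], 6)
    else:
        log.info("no conservation track: skipping conservation stage")
        summary["conservation.skipped"] = True

    # --- partner overlap + permutation significance --------------------------
    if config.partners is not None:
        partners = read_bed(config.partners, "partners", config.genome_id)
        if genome is not None:
            result = ovl.permutation_test(
                partners, peaks, genome, config.max_dist,
                config.n_perm, config.seed,
            )
            summary["overlap.expected"] = round(result.expected, 4)
            summary["overlap.p_value"] = round(result.p_value, 8)
        else:
            log.info("no chrom sizes: overlap reported without permutation null")
            result = ovl.midpoint_overlap(partners, peaks, config.max_dist)
        summary["overlap.n_partners"] = result.n_a
        summary["overlap.observed"] = result.observed
        summary["overlap.frac_partners_hit"] = round(result.observed / result.n_a, 6)
        ovl.write_overlap_summary(result, outdir / "overlap.tsv")
        common = ovl.intersect_n([partners, peaks], config.max_dist)
        write_bed(common, outdir / "common_peaks.bed")
    else:
        log.info("no partner set: skipping overlap stage")
        summary["overlap.skipped"] = True

    # --- motif occurrence ----------------------------------------------------
    if config.fasta is not None:
        seqs = read_fasta(config.fasta)
        sizes = genome.chrom_sizes if genome is not None else {
            c: len(s) for c, s in seqs.items()
        }
        seq_genome = Genome(sizes, seqs, config.genome_id)
        report = mot.motif_report(
            peaks, seq_genome, config.motif, config.n_background, config.seed
        )
        mot.write_motif_report(report, outdir / "motif.tsv")
        summary["motif.fraction_with_hit"] = round(report.fraction_with_hit, 6)
        summary["motif.background_fraction"] = round(report.background_fraction, 6)
    else:
        log.info("no genome FASTA: skipping motif stage")
        summary["motif.skipped"] = True

    # --- gene-list enrichment -------------------------------------------------
    if config.gene_list is not None and gene_set is not None and peak_genes:
        gene_list = enr.read_gene_list(config.gene_list)
        rate = enr.background_gene_rate(gene_set, peak_genes)
        if 0.0 < rate < 1.0:
            result = enr.gene_list_enrichment(gene_list, peak_genes, rate)
            enr.write_enrichment_report(result, outdir / "enrichment.txt")
            summary["enrichment.n_list"] = result.n_list
            summary["enrichment.k_with_peak"] = result.k_with_peak
            summary["enrichment.observed_fraction"] = round(result.observed_fraction, 6)
            summary["enrichment.background_rate"] = round(rate, 6)
            summary["enrichment.p_value"] = f"{result.p_value:.6g}"
        else:
            log.info("degenerate background rate %.3f: skipping enrichment", rate)
            summary["enrichment.skipped"] = True
    else:
        if config.gene_list is not None:
            log.info("enrichment needs a gene table: skipping")
        else:
            log.info("no gene list: skipping enrichment stage")
        summary["enrichment.skipped"] = True

    # --- interaction network ---------------------------------------------------
    if config.interactions is not None:
        pairs = net.load_interactions(config.interactions)
        overlap = net.peak_anchor_overlap(peaks, pairs, config.max_dist)
        summary["network.n_pairs"] = len(pairs)
        summary["network.n_anchors_bound"] = overlap.n_anchors_bound
        summary["network.n_peaks_hit"] = overlap.n_peaks_hit
        if genome is not None and pairs:
            anchors = net.anchors_to_peakset(pairs, genome_id=peaks.genome_id)
            sig = ovl.permutation_test(
                peaks, anchors, genome, config.max_dist, config.n_perm, config.seed
            )
            summary["network.expected_peaks_hit"] = round(sig.expected, 4)
            summary["network.p_value"] = round(sig.p_value, 8)
        graph = net.build_graph(pairs, overlap.bound_flags, config.merge_dist)
        summary["network.n_nodes"] = graph.n_nodes
        summary["network.n_edges"] = graph.n_edges
        sizes = graph.component_sizes()
        summary["network.n_components"] = len(sizes)
        summary["network.largest_component"] = sizes[0] if sizes else 0
        net.write_edge_list(graph, outdir / "network_edges.tsv")
        hubs = graph.hub_table()
        hubs.to_csv(outdir / "hubs.tsv", sep="\t", index=False)
        if len(hubs):
            summary["network.max_hub_linked"] = int(hubs["n_linked"].max())
    else:
        log.info("no interactions file: skipping network stage")
        summary["network.skipped"] = True

    with open(outdir / "summary.txt", "w") as fh:
        for key in summary:
            fh.write(f"{key}\t{summary[key]}\n")
    return summary
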