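"""Synthetic genomes, gene models, tracks, peak sets and interactions.

The generator builds a toy genome whose statistical structure mirrors the
inputs of an integrative ChIP-seq peak analysis — replicate peak sets with
positional jitter, a partner (coactivator-like) peak set with a controlled
fraction of midpoints within the overlap distance of the reference set, a
conservation track elevated over designated peaks, chromosome sequences
with a consensus motif planted in a controlled fraction of peaks (and
scrubbed everywhere else), and paired-anchor interaction records with a
controlled fraction of anchors hitting peaks.  Every planted feature is
recorded in a :class:`GroundTruth` object so each pipeline stage has a
closed-loop test with an exact expected answer.

Placement is deliberately *unambiguous*: genes are spaced far apart,
promoter/intronic/intergenic peaks sit deep inside their designated zones,
and all decoys (replicate-private peaks, non-overlapping partners, unbound
anchors) are laid out on a coarse grid of "desert" slots far from every
other feature.  This makes every ground-truth label exactly recoverable —
and means the generator does not emulate the collisions, ambiguous nearest
genes or background motif matches of real data.

Also hosted here: the curated table of SOX3 ChIP peaks near genes
differentially expressed in Sox3-null neural progenitors (19 peaks across
13 genes), and the matching 19-gene differential-expression list in which
the 6 genes without peaks are synthetic placeholder identifiers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .annotation import GeneModel, GeneSet, write_gene_table
from .conservation import ConservationTrack
from .intervals import (
    GenomicInterval,
    Genome,
    PeakSet,
    write_bed,
    write_chrom_sizes,
    write_fasta,
)
from .motif import ConsensusMotif, SOX_CONSENSUS, scan
from .network import InteractionPair, write_interactions

GENOME_ID = "synthetic"

# Layout constants (bp). Genes occupy fixed territories; every decoy feature
# is placed on a grid of desert slots so that any two distinct features are
# at least DESERT_PITCH apart and conservation plateaus never collide.
GENE_TERRITORY = 30_000
GENE_REGION_START = 10_000
GENE_SPAN = 12_000
GENE_EXONS = ((0, 300), (5_700, 6_000), (11_700, 12_000))  # relative to span
DESERT_GAP = 20_000  # between the last gene territory and the first slot
DESERT_PITCH = 2_000
PLATEAU_MARGIN = 200
EDGE_MARGIN = 2_000


class SyntheticConfigError(ValueError):
    """Raised when a configuration cannot be laid out unambiguously."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the headline structure of a SOX3-style NP-cell ChIP
    experiment at desk scale: three replicates sharing one truth peak set,
    a partner set overlapping ~29% of its peaks (the midbrain P300-like
    condition), 20% highly / 36% moderately conserved peaks, the SOX
    consensus planted in 70% of peak sequences, and ~19% of peaks carrying
    an interaction anchor.
    """

    n_chroms: int = 4
    chrom_length: int = 1_000_000
    n_genes: int = 40
    n_peaks: int = 100
    peak_width_range: tuple[int, int] = (150, 400)
    frac_promoter: float = 0.11
    frac_intronic: float = 0.285
    frac_intergenic: float = 0.605
    frac_high_cons: float = 0.20
    frac_mod_cons: float = 0.36
    partner_overlap_frac: float = 0.2885
    n_partners: int | None = None
    replicate_jitter: int = 50
    replicate_private: int = 20
    n_replicates: int = 3
    motif: str = SOX_CONSENSUS
    motif_plant_frac: float = 0.70
    with_sequence: bool = True
    n_interactions: int = 200
    interaction_peak_frac: float = 0.194
    anchor_width: int = 200
    promoter_window: int = 2_000
    max_dist: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "frac_promoter": self.frac_promoter,
            "frac_intronic": self.frac_intronic,
            "frac_intergenic": self.frac_intergenic,
            "frac_high_cons": self.frac_high_cons,
            "frac_mod_cons": self.frac_mod_cons,
            "partner_overlap_frac": self.partner_overlap_frac,
            "motif_plant_frac": self.motif_plant_frac,
            "interaction_peak_frac": self.interaction_peak_frac,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise SyntheticConfigError(f"{name}={value} outside [0, 1]")
        cat_sum = self.frac_promoter + self.frac_intronic + self.frac_intergenic
        if abs(cat_sum - 1.0) > 1e-9:
            raise SyntheticConfigError(
                f"category fractions sum to {cat_sum}, expected 1"
            )
        if self.frac_high_cons + self.frac_mod_cons > 1.0 + 1e-9:
            raise SyntheticConfigError("conservation fractions exceed 1")
        wmin, wmax = self.peak_width_range
        if not 1 <= wmin <= wmax:
            raise SyntheticConfigError("invalid peak_width_range")
        if 2 * self.replicate_jitter >= wmin:
            raise SyntheticConfigError(
                "replicate_jitter too large: jittered copies must still overlap"
            )
        if self.replicate_jitter >= self.max_dist:
            raise SyntheticConfigError(
                "replicate_jitter must be smaller than max_dist so planted "
                "partners stay within range of jittered replicate peaks"
            )
        if self.n_chroms < 1 or self.n_peaks < 1:
            raise SyntheticConfigError("need >=1 chromosome and >=1 peak")
        ConsensusMotif(self.motif)  # validates the pattern

    @property
    def partner_count(self) -> int:
        return self.n_partners if self.n_partners is not None else self.n_peaks


@dataclass(frozen=True)
class GroundTruth:
    """Planted labels, aligned 1:1 with the sorted generated records."""

    names: tuple[str, ...]
    categories: tuple[str, ...]
    nearest_gene: tuple[str | None, ...]
    cons_class: tuple[str, ...]
    cons_value: tuple[float, ...]
    motif_planted: tuple[bool, ...]
    anchor_bound: tuple[bool, ...]
    partner_names: tuple[str, ...]
    partner_planted: tuple[bool, ...]


@dataclass(frozen=True)
class SyntheticBundle:
    """Everything one generator run produces, plus its ground truth."""

    config: SyntheticConfig
    genome: Genome
    genes: GeneSet
    track: ConservationTrack
    reference: PeakSet
    replicates: tuple[PeakSet, ...]
    partners: PeakSet
    interactions: tuple[InteractionPair, ...]
    gene_list: tuple[str, ...]
    expected_gene_hits: int
    truth: GroundTruth


def _largest_remainder(fractions: list[float], total: int) -> list[int]:
    """Integer counts summing to ``total`` with largest-remainder rounding."""
    raw = [f * total for f in fractions]
    counts = [int(x) for x in raw]
    remainders = sorted(
        range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i)
    )
    for i in range(total - sum(counts)):
        counts[remainders[i % len(raw)]] += 1
    return counts


class _DesertAllocator:
    """Round-robin allocator of well-separated midpoint slots per chromosome."""

    def __init__(self, chrom_names: list[str], desert_bounds: dict[str, tuple[int, int]]):
        self.chroms = chrom_names
        self.cursor = {c: desert_bounds[c][0] + DESERT_PITCH // 2 for c in chrom_names}
        self.end = {c: desert_bounds[c][1] for c in chrom_names}
        self._rr = 0

    def _take(self, chrom: str) -> int | None:
        mid = self.cursor[chrom]
        if mid >= self.end[chrom]:
            return None
        self.cursor[chrom] += DESERT_PITCH
        return mid

    def allocate(self, chrom: str | None = None) -> tuple[str, int]:
        """Next free slot, on ``chrom`` if given else round-robin."""
        if chrom is not None:
            mid = self._take(chrom)
            if mid is None:
                raise SyntheticConfigError(
                    f"infeasible config: desert space exhausted on {chrom}"
                )
            return chrom, mid
        for _ in range(len(self.chroms)):
            c = self.chroms[self._rr % len(self.chroms)]
            self._rr += 1
            mid = self._take(c)
            if mid is not None:
                return c, mid
        raise SyntheticConfigError("infeasible config: desert space exhausted")

    def allocate_not_on(self, chrom: str) -> tuple[str, int]:
        """Next free slot on any chromosome other than ``chrom`` (if possible)."""
        for _ in range(len(self.chroms)):
            c = self.chroms[self._rr % len(self.chroms)]
            self._rr += 1
            if c == chrom and len(self.chroms) > 1:
                continue
            mid = self._take(c)
            if mid is not None:
                return c, mid
        return self.allocate()


def _random_interval(mid: int, rng: np.random.Generator,
                     width_range: tuple[int, int]) -> tuple[int, int]:
    """Start/end of a peak of random width whose midpoint is exactly ``mid``."""
    width = int(rng.integers(width_range[0], width_range[1] + 1))
    start = mid - width // 2
    return start, start + width


def _expand_motif(pattern: str, rng: np.random.Generator) -> str:
    from .motif import IUPAC_CODES

    return "".join(
        IUPAC_CODES[c][int(rng.integers(len(IUPAC_CODES[c])))] for c in pattern
    )


def generate(config: SyntheticConfig) -> SyntheticBundle:
    """Generate a full synthetic dataset with recorded ground truth.

    Deterministic given ``config.seed``: one master seed fans out into
    independent per-component streams (layout, conservation, sequence,
    replicates, partners, interactions), so components do not perturb each
    other's draws.
    """
    cfg = config
    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_layout, rng_cons, rng_seq, rng_rep, rng_part, rng_int = (
        np.random.default_rng(s) for s in streams
    )

    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    genome_sizes = {c: cfg.chrom_length for c in chrom_names}

    # --- gene layout: fixed territories, alternating strand -----------------
    genes: list[GeneModel] = []
    genes_per_chrom = {c: 0 for c in chrom_names}
    for g in range(cfg.n_genes):
        chrom = chrom_names[g % cfg.n_chroms]
        j = genes_per_chrom[chrom]
        genes_per_chrom[chrom] += 1
        base = GENE_REGION_START + j * GENE_TERRITORY
        if base + GENE_SPAN + DESERT_GAP + EDGE_MARGIN > cfg.chrom_length:
            raise SyntheticConfigError(
                "infeasible config: gene territories exceed chromosome length"
            )
        strand = "+" if g % 2 == 0 else "-"
        exons = tuple((base + s, base + e) for s, e in GENE_EXONS)
        genes.append(GeneModel(f"gene{g:04d}", chrom, strand, base, base + GENE_SPAN, exons))
    gene_set = GeneSet(tuple(genes), GENOME_ID)
    genes_by_chrom: dict[str, list[GeneModel]] = {c: [] for c in chrom_names}
    for g in genes:
        genes_by_chrom[g.chrom].append(g)

    desert_bounds = {}
    for c in chrom_names:
        start = GENE_REGION_START + genes_per_chrom[c] * GENE_TERRITORY + DESERT_GAP
        desert_bounds[c] = (start, cfg.chrom_length - EDGE_MARGIN)
        if start >= cfg.chrom_length - EDGE_MARGIN:
            raise SyntheticConfigError("infeasible config: no desert space left")
    allocator = _DesertAllocator(chrom_names, desert_bounds)

    # --- reference peaks per category ---------------------------------------
    n_prom, n_intr, n_inter = _largest_remainder(
        [cfg.frac_promoter, cfg.frac_intronic, cfg.frac_intergenic], cfg.n_peaks
    )
    if n_prom > len(genes) or n_intr > len(genes):
        raise SyntheticConfigError(
            "infeasible config: more promoter/intronic peaks than genes"
        )

    records: list[dict] = []  # one dict per reference peak, pre-sort

    for i in range(n_prom):
        gene = genes[i]
        offset = int(rng_layout.integers(500, 1501))
        mid = gene.tss - offset if gene.strand == "+" else gene.tss + offset
        start, end = _random_interval(mid, rng_layout, cfg.peak_width_range)
        records.append(dict(chrom=gene.chrom, start=start, end=end,
                            category="promoter", gene=gene.gene_id))
    for i in range(n_intr):
        gene = genes[i]
        if gene.strand == "+":  # intron far from the TSS: second intron
            lo, hi = gene.span_start + 6_000, gene.span_start + 11_700
        else:  # minus-strand TSS sits at span end: first intron is far
            lo, hi = gene.span_start + 300, gene.span_start + 5_700
        mid = int(rng_layout.integers(lo + 500, hi - 500))
        start, end = _random_interval(mid, rng_layout, cfg.peak_width_range)
        records.append(dict(chrom=gene.chrom, start=start, end=end,
                            category="intronic", gene=gene.gene_id))
    for _ in range(n_inter):
        chrom, mid = allocator.allocate()
        start, end = _random_interval(mid, rng_layout, cfg.peak_width_range)
        on_chrom = genes_by_chrom[chrom]
        nearest = None
        if on_chrom:
            nearest = min(on_chrom, key=lambda g: (abs(mid - g.tss), g.gene_id)).gene_id
        records.append(dict(chrom=chrom, start=start, end=end,
                            category="intergenic", gene=nearest))

    records.sort(key=lambda r: (r["chrom"], r["start"], r["end"]))
    for i, rec in enumerate(records):
        rec["name"] = f"peak{i:04d}"

    # --- conservation plateaus ----------------------------------------------
    n_high, n_mod, _ = _largest_remainder(
        [cfg.frac_high_cons, cfg.frac_mod_cons,
         1.0 - cfg.frac_high_cons - cfg.frac_mod_cons],
        cfg.n_peaks,
    )
    order = rng_cons.permutation(cfg.n_peaks)
    segments = []
    for rank, idx in enumerate(order):
        rec = records[int(idx)]
        if rank < n_high:
            rec["cons_class"] = "high"
            rec["cons_value"] = float(rng_cons.uniform(0.6, 1.0))
        elif rank < n_high + n_mod:
            rec["cons_class"] = "moderate"
            rec["cons_value"] = float(rng_cons.uniform(0.15, 0.45))
        else:
            rec["cons_class"] = "low"
            rec["cons_value"] = 0.0
            continue
        segments.append((
            rec["chrom"], rec["start"] - PLATEAU_MARGIN,
            rec["end"] + PLATEAU_MARGIN, rec["cons_value"],
        ))
    track = ConservationTrack.from_segments(segments, default_value=0.0)

    # --- sequence with scrubbed background and planted motifs ---------------
    sequence: dict[str, str] | None = None
    n_motif = int(round(cfg.motif_plant_frac * cfg.n_peaks))
    planted_idx = set(int(i) for i in rng_seq.permutation(cfg.n_peaks)[:n_motif])
    for i, rec in enumerate(records):
        rec["motif_planted"] = i in planted_idx
    if cfg.with_sequence:
        motif = ConsensusMotif(cfg.motif)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        sequence = {}
        for chrom in chrom_names:
            arr = rng_seq.integers(0, 4, size=cfg.chrom_length)
            seq = list(b"".join(bases[arr]).decode())
            # scrub every background occurrence of the motif (both strands)
            for _ in range(100):
                hits = scan("".join(seq), motif)
                if not hits:
                    break
                for pos, _strand in hits:
                    for k in range(motif.length):
                        seq[pos + k] = "ACGT"[int(rng_seq.integers(4))]
            else:  # pragma: no cover - vanishingly unlikely
                raise SyntheticConfigError("could not scrub motif background")
            sequence[chrom] = "".join(seq)
        for i, rec in enumerate(records):
            if not rec["motif_planted"]:
                continue
            instance = _expand_motif(cfg.motif, rng_seq)
            mid = (rec["start"] + rec["end"]) // 2
            pos = mid - motif.length // 2
            chrom_seq = sequence[rec["chrom"]]
            sequence[rec["chrom"]] = (
                chrom_seq[:pos] + instance + chrom_seq[pos + motif.length:]
            )

    genome = Genome(genome_sizes, sequence, GENOME_ID)

    # --- replicates: jittered copies of the truth plus private decoys -------
    replicates = []
    for r in range(cfg.n_replicates):
        ivs = []
        for rec in records:
            shift = int(rng_rep.integers(-cfg.replicate_jitter, cfg.replicate_jitter + 1))
            ivs.append(GenomicInterval(
                rec["chrom"], rec["start"] + shift, rec["end"] + shift,
                f"shared_{rec['name']}",
            ))
        for p in range(cfg.replicate_private):
            chrom, mid = allocator.allocate()
            start, end = _random_interval(mid, rng_rep, cfg.peak_width_range)
            ivs.append(GenomicInterval(chrom, start, end, f"private{p:03d}"))
        replicates.append(PeakSet(f"rep{r + 1}", tuple(ivs), GENOME_ID))

    # --- partner set: planted near-reference peaks plus distant decoys ------
    n_partner = cfg.partner_count
    n_plant = int(round(cfg.partner_overlap_frac * n_partner))
    if n_plant > cfg.n_peaks:
        raise SyntheticConfigError(
            "infeasible config: more planted partners than reference peaks"
        )
    targets = rng_part.permutation(cfg.n_peaks)[:n_plant]
    # offsets leave headroom for replicate jitter: a planted partner stays
    # within max_dist of the truth peak even after the copy shifts by +-jitter
    max_offset = cfg.max_dist - cfg.replicate_jitter
    partner_records = []
    for j, t in enumerate(targets):
        rec = records[int(t)]
        ref_mid = (rec["start"] + rec["end"]) // 2
        mid = ref_mid + int(rng_part.integers(-max_offset, max_offset + 1))
        start, end = _random_interval(mid, rng_part, cfg.peak_width_range)
        partner_records.append(dict(chrom=rec["chrom"], start=start, end=end,
                                    planted=True))
    for _ in range(n_partner - n_plant):
        chrom, mid = allocator.allocate()
        start, end = _random_interval(mid, rng_part, cfg.peak_width_range)
        partner_records.append(dict(chrom=chrom, start=start, end=end,
                                    planted=False))
    partner_records.sort(key=lambda r: (r["chrom"], r["start"], r["end"]))
    for j, rec in enumerate(partner_records):
        rec["name"] = f"partner{j:04d}"
    partners = PeakSet(
        "partners",
        tuple(GenomicInterval(r["chrom"], r["start"], r["end"], r["name"])
              for r in partner_records),
        GENOME_ID,
    )

    # --- interaction pairs ---------------------------------------------------
    n_bound = int(round(cfg.interaction_peak_frac * cfg.n_peaks))
    if n_bound > cfg.n_interactions:
        raise SyntheticConfigError(
            "infeasible config: more bound peaks than interaction pairs"
        )
    bound_idx = [int(i) for i in rng_int.permutation(cfg.n_peaks)[:n_bound]]
    for i, rec in enumerate(records):
        rec["anchor_bound"] = i in set(bound_idx)
    pairs = []
    half = cfg.anchor_width // 2
    for k, i in enumerate(bound_idx):
        rec = records[i]
        mid = (rec["start"] + rec["end"]) // 2
        anchor_a = GenomicInterval(rec["chrom"], mid - half, mid - half + cfg.anchor_width)
        chrom_b, mid_b = allocator.allocate_not_on(rec["chrom"])
        anchor_b = GenomicInterval(chrom_b, mid_b - half, mid_b - half + cfg.anchor_width)
        pairs.append(InteractionPair(anchor_a, anchor_b, f"pair{k:05d}"))
    for k in range(n_bound, cfg.n_interactions):
        chrom_a, mid_a = allocator.allocate()
        chrom_b, mid_b = (
            allocator.allocate_not_on(chrom_a) if k % 2 else allocator.allocate(chrom_a)
        )
        pairs.append(InteractionPair(
            GenomicInterval(chrom_a, mid_a - half, mid_a - half + cfg.anchor_width),
            GenomicInterval(chrom_b, mid_b - half, mid_b - half + cfg.anchor_width),
            f"pair{k:05d}",
        ))

    # --- reference PeakSet + aligned truth vectors ---------------------------
    reference = PeakSet(
        "reference",
        tuple(GenomicInterval(r["chrom"], r["start"], r["end"], r["name"])
              for r in records),
        GENOME_ID,
    )
    truth = GroundTruth(
        names=tuple(r["name"] for r in records),
        categories=tuple(r["category"] for r in records),
        nearest_gene=tuple(r["gene"] for r in records),
        cons_class=tuple(r["cons_class"] for r in records),
        cons_value=tuple(r["cons_value"] for r in records),
        motif_planted=tuple(r["motif_planted"] for r in records),
        anchor_bound=tuple(r["anchor_bound"] for r in records),
        partner_names=tuple(r["name"] for r in partner_records),
        partner_planted=tuple(r["planted"] for r in partner_records),
    )

    # --- a DE-like gene list for the enrichment stage ------------------------
    peak_genes = sorted({r["gene"] for r in records if r["gene"] is not None})
    no_peak_genes = sorted(gene_set.gene_ids - set(peak_genes))
    listed_hits = peak_genes[: min(10, len(peak_genes))]
    listed_misses = no_peak_genes[: min(5, len(no_peak_genes))]
    gene_list = tuple(listed_hits + listed_misses)

    return SyntheticBundle(
        config=cfg, genome=genome, genes=gene_set, track=track,
        reference=reference, replicates=tuple(replicates), partners=partners,
        interactions=tuple(pairs), gene_list=gene_list,
        expected_gene_hits=len(listed_hits), truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as a standard-format file set; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["chrom_sizes"] = outdir / "genome.chrom.sizes"
    write_chrom_sizes(bundle.genome, paths["chrom_sizes"])
    if bundle.genome.sequence is not None:
        paths["fasta"] = outdir / "genome.fa"
        write_fasta(bundle.genome.sequence, paths["fasta"])
    paths["genes"] = outdir / "genes.tsv"
    write_gene_table(bundle.genes, paths["genes"])
    paths["track"] = outdir / "conservation.bedgraph"
    bundle.track.to_bedgraph(paths["track"])
    paths["reference"] = outdir / "reference.bed"
    write_bed(bundle.reference, paths["reference"])
    for i, rep in enumerate(bundle.replicates, start=1):
        paths[f"replicate_{i}"] = outdir / f"replicate_{i}.bed"
        write_bed(rep, paths[f"replicate_{i}"])
    paths["partners"] = outdir / "partners.bed"
    write_bed(bundle.partners, paths["partners"])
    paths["interactions"] = outdir / "interactions.bedpe"
    write_interactions(bundle.interactions, paths["interactions"])
    paths["gene_list"] = outdir / "gene_list.txt"
    with open(paths["gene_list"], "w") as fh:
        for g in bundle.gene_list:
            fh.write(g + "\n")
    paths["ground_truth"] = outdir / "ground_truth.tsv"
    with open(paths["ground_truth"], "w") as fh:
        fh.write("name\tcategory\tnearest_gene\tcons_class\tcons_value\t"
                 "motif_planted\tanchor_bound\n")
        t = bundle.truth
        for i in range(len(t.names)):
            fh.write(
                f"{t.names[i]}\t{t.categories[i]}\t{t.nearest_gene[i] or '.'}\t"
                f"{t.cons_class[i]}\t{t.cons_value[i]:.6g}\t"
                f"{int(t.motif_planted[i])}\t{int(t.anchor_bound[i])}\n"
            )
    paths["config"] = outdir / "config.json"
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(bundle.config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def load_config(path: str | Path) -> SyntheticConfig:
    with open(path) as fh:
        raw = json.load(fh)
    raw["peak_width_range"] = tuple(raw["peak_width_range"])
    return SyntheticConfig(**raw)


# ---------------------------------------------------------------------------
# Curated fixture: SOX3 peaks near differentially expressed genes
# ---------------------------------------------------------------------------


class TargetPeakTable(NamedTuple):
    """The curated DE-target peak table.

    ``peaks`` hold the 19 records in 0-based half-open coordinates (the
    source table is 1-based inclusive; starts are shifted by −1 on load),
    with the gene symbol as interval name.  ``locations`` aligns 1:1 with
    the sorted ``peaks``; ``genes`` are the 13 distinct symbols in table
    order; ``fold_changes`` maps each gene to its expression fold change in
    Sox3-null versus wild-type neural progenitors.
    """

    peaks: PeakSet
    genes: tuple[str, ...]
    locations: tuple[str, ...]
    fold_changes: dict[str, float]


def sox3_target_table() -> TargetPeakTable:
    """Load the curated SOX3 DE-target peak table (19 peaks, 13 genes)."""
    text = (
        resources.files("peaklab").joinpath("data/sox3_target_peaks.tsv").read_text()
    )
    rows = []
    genes_in_order: list[str] = []
    fold_changes: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("gene\t"):
            continue
        gene, fold, _refseq, chrom, start, end, location = line.split("\t")
        if gene not in genes_in_order:
            genes_in_order.append(gene)
        fold_changes[gene] = float(fold)
        # source coordinates are 1-based inclusive
        rows.append((GenomicInterval(chrom, int(start) - 1, int(end), gene),
                     location.lower()))
    rows.sort(key=lambda r: r[0].sort_key())
    peaks = PeakSet("sox3_de_targets", tuple(r[0] for r in rows), "mm9")
    locations = tuple(r[1] for r in rows)
    return TargetPeakTable(peaks, tuple(genes_in_order), locations, fold_changes)


def sox3_de_gene_list() -> tuple[str, ...]:
    """The 19-gene differential-expression list matching the target table.

    Thirteen entries are the peak-bearing genes of the curated table; the
    remaining six DE genes are not individually identified in the source
    material, so they appear here as synthetic placeholder identifiers that
    are guaranteed absent from any peak-gene set.
    """
    table = sox3_target_table()
    placeholders = tuple(f"synthetic_de_gene_{i}" for i in range(1, 7))
    return table.genes + placeholders
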