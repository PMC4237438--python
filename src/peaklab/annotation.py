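"""Nearest-gene assignment and genomic classification of peaks.

Each peak is assigned the gene whose transcription start site (TSS) is
closest to the peak midpoint on the same chromosome, then classified as
``promoter`` (midpoint within the promoter window of the TSS), ``intronic``
(midpoint inside the gene span but outside every exon) or ``intergenic``
(everything else).  The three categories partition the peak set, mirroring
the promoter/intron/intergenic breakdown conventionally reported for
ChIP-seq peak sets.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .intervals import BedParseError, GenomicInterval, PeakSet

log = logging.getLogger(__name__)

CATEGORIES = ("promoter", "intronic", "intergenic")


@dataclass(frozen=True)
class GeneModel:
    """A gene as TSS + transcript span + exon blocks (0-based half-open).

    The TSS is derived from strand: ``span_start`` for ``+`` genes and
    ``span_end - 1`` for ``-`` genes.
    """

    gene_id: str
    chrom: str
    strand: str
    span_start: int
    span_end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.span_start < self.span_end):
            raise ValueError(f"gene {self.gene_id}: invalid span")
        prev_end = self.span_start
        for start, end in self.exons:
            if start < prev_end or end > self.span_end or start >= end:
                raise ValueError(
                    f"gene {self.gene_id}: exons must be sorted, disjoint and "
                    "contained in the span"
                )
            prev_end = end

    @property
    def tss(self) -> int:
        return self.span_start if self.strand == "+" else self.span_end - 1

    def contains(self, pos: int) -> bool:
        return self.span_start <= pos < self.span_end

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)


@dataclass(frozen=True)
class GeneSet:
    """A deterministic, id-sorted collection of gene models."""

    genes: tuple[GeneModel, ...]
    genome_id: str = "custom"

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.genes, key=lambda g: (g.chrom, g.span_start, g.gene_id)))
        ids = [g.gene_id for g in ordered]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene_id in GeneSet")
        object.__setattr__(self, "genes", ordered)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(g.gene_id for g in self.genes)


@dataclass(frozen=True)
class PeakAnnotation:
    """One peak's nearest gene, signed TSS distance, and category.

    ``tss_distance`` is midpoint − TSS, orientation-corrected so that a
    positive value means downstream of the TSS in the gene's direction of
    transcription; ``None`` when no gene shares the chromosome.
    """

    peak: GenomicInterval
    nearest_gene: str | None
    tss_distance: int | None
    category: str


def read_gene_table(path: str | Path, genome_id: str = "custom") -> GeneSet:
    """Read a tab-separated gene table.

    Columns: gene_id, chrom, strand, span_start, span_end, exon_starts,
    exon_ends (the last two comma-separated, possibly empty).
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 5:
                raise BedParseError(f"{path}:{lineno}: expected >=5 columns")
            try:
                starts = [int(x) for x in f[5].split(",") if x] if len(f) > 5 else []
                ends = [int(x) for x in f[6].split(",") if x] if len(f) > 6 else []
                genes.append(
                    GeneModel(
                        f[0], f[1], f[2], int(f[3]), int(f[4]),
                        tuple(zip(starts, ends)),
                    )
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return GeneSet(tuple(genes), genome_id)


def write_gene_table(genes: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            starts = ",".join(str(s) for s, _ in g.exons)
            ends = ",".join(str(e) for _, e in g.exons)
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.span_start}\t"
                f"{g.span_end}\t{starts}\t{ends}\n"
            )


def _nearest_gene(mid: int, tss_sorted: list[tuple[int, str, GeneModel]]) -> GeneModel:
    # tss_sorted is sorted by (tss, gene_id); candidates are the insertion
    # neighbours; equidistant TSSs tie-break on lexicographic gene_id.
    positions = [t[0] for t in tss_sorted]
    i = bisect_left(positions, mid)
    candidates = []
    if i < len(tss_sorted):
        candidates.append(tss_sorted[i])
    if i > 0:
        candidates.append(tss_sorted[i - 1])
    best_dist = min(abs(mid - t) for t, _, _ in candidates)
    tied = [
        entry
        for entry in tss_sorted
        if abs(mid - entry[0]) == best_dist
    ]
    return min(tied, key=lambda entry: entry[1])[2]


def annotate_peaks(
    peaks: PeakSet,
    genes: GeneSet | Iterable[GeneModel],
    promoter_window: int = 2000,
    include_exonic: bool = False,
) -> list[PeakAnnotation]:
    """Annotate every peak with its nearest gene and genomic category.

    Classification precedence is promoter > intronic > intergenic, evaluated
    on the peak midpoint against the nearest gene (minimal |midpoint − TSS|
    over genes on the same chromosome).  A midpoint inside an exon (outside
    the promoter window) falls through to ``intergenic`` unless
    ``include_exonic`` enables a fourth ``exonic`` category.  Peaks on a
    chromosome with no genes are annotated ``nearest_gene=None`` /
    ``intergenic`` and counted in a log notice.
    """
    if promoter_window <= 0:
        raise ValueError("promoter_window must be > 0")
    gene_list = list(genes)
    by_chrom: dict[str, list[tuple[int, str, GeneModel]]] = {}
    for g in gene_list:
        by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id, g))
    for entries in by_chrom.values():
        entries.sort(key=lambda t: (t[0], t[1]))

    annotations: list[PeakAnnotation] = []
    n_orphan = 0
    for peak in peaks:
        entries = by_chrom.get(peak.chrom)
        if not entries:
            n_orphan += 1
            annotations.append(PeakAnnotation(peak, None, None, "intergenic"))
            continue
        mid = peak.midpoint
        gene = _nearest_gene(mid, entries)
        raw = mid - gene.tss
        signed = raw if gene.strand == "+" else -raw
        if abs(signed) <= promoter_window:
            category = "promoter"
        elif gene.contains(mid):
            if gene.in_exon(mid):
                category = "exonic" if include_exonic else "intergenic"
            else:
                category = "intronic"
        else:
            category = "intergenic"
        annotations.append(PeakAnnotation(peak, gene.gene_id, signed, category))
    if n_orphan:
        log.warning(
            "annotate_peaks: %d peak(s) on chromosomes without genes; "
            "classified intergenic with no nearest gene", n_orphan,
        )
    return annotations


def category_fractions(annotations: Sequence[PeakAnnotation]) -> dict[str, float]:
    """Fraction of peaks per category; keys always include the three classes."""
    if not annotations:
        raise ValueError("empty annotation list")
    counts = {c: 0 for c in CATEGORIES}
    for ann in annotations:
        counts[ann.category] = counts.get(ann.category, 0) + 1
    total = len(annotations)
    return {c: n / total for c, n in counts.items()}


def genes_with_peaks(annotations: Sequence[PeakAnnotation]) -> set[str]:
    """Distinct nearest-gene ids over the annotations (orphans excluded)."""
    return {a.nearest_gene for a in annotations if a.nearest_gene is not None}


def annotations_to_frame(annotations: Sequence[PeakAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [a.peak.chrom for a in annotations],
            "start": [a.peak.start for a in annotations],
            "end": [a.peak.end for a in annotations],
            "name": [a.peak.name for a in annotations],
            "midpoint": [a.peak.midpoint for a in annotations],
            "nearest_gene": [a.nearest_gene or "." for a in annotations],
            "tss_distance": [
                a.tss_distance if a.tss_distance is not None else pd.NA
                for a in annotations
            ],
            "category": [a.category for a in annotations],
        }
    )


def write_annotation_table(annotations: Sequence[PeakAnnotation], path: str | Path) -> None:
    annotations_to_frame(annotations).to_csv(path, sep="\t", index=False)
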