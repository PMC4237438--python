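"""Core genomic-interval data model, BED I/O and replicate-consistency filtering.

Coordinates are 0-based half-open throughout (UCSC BED convention): an
interval ``(start, end)`` covers bases ``start .. end-1``.  The interval
*midpoint* — the reference point for all distance-based overlap rules in
this package — is ``floor((start + end) / 2)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from intervaltree import IntervalTree

log = logging.getLogger(__name__)

_STRANDS = frozenset({"+", "-", "."})


class BedParseError(ValueError):
    """Raised when a BED/BEDPE-like line cannot be parsed."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named chromosome.

    Parameters
    ----------
    chrom
        Chromosome name, e.g. ``"chr7"``.
    start, end
        0-based half-open coordinates in bp; ``0 <= start < end``.
    name
        Free-form label (BED column 4).
    score
        Optional real score (BED column 5); ``None`` when absent.
    strand
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        """``floor((start + end) / 2)``; always within ``[start, end)``."""
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def sort_key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.name)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def midpoint(iv: GenomicInterval) -> int:
    """Midpoint of an interval: ``floor((start + end) / 2)``."""
    return iv.midpoint


@dataclass(frozen=True)
class PeakSet:
    """An ordered, de-duplicated collection of peaks on one coordinate system.

    Intervals are kept sorted by ``(chrom, start, end, name)`` so iteration
    order is deterministic.  Exact duplicate intervals are collapsed on
    construction and the collapsed count is logged.
    """

    label: str
    intervals: tuple[GenomicInterval, ...]
    genome_id: str = "custom"

    def __post_init__(self) -> None:
        ordered = sorted(self.intervals, key=GenomicInterval.sort_key)
        deduped: list[GenomicInterval] = []
        for iv in ordered:
            if not deduped or iv != deduped[-1]:
                deduped.append(iv)
        n_dup = len(ordered) - len(deduped)
        if n_dup:
            log.info("PeakSet %r: collapsed %d duplicate interval(s)", self.label, n_dup)
        object.__setattr__(self, "intervals", tuple(deduped))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def chroms(self) -> tuple[str, ...]:
        return tuple(sorted({iv.chrom for iv in self.intervals}))

    def validate_against(self, genome: "Genome") -> None:
        """Raise if any interval exceeds the recorded chromosome length."""
        for iv in self.intervals:
            size = genome.chrom_sizes.get(iv.chrom)
            if size is None:
                raise ValueError(f"chromosome {iv.chrom} absent from genome")
            if iv.end > size:
                raise ValueError(
                    f"interval {iv} exceeds chromosome length {size}"
                )


@dataclass(frozen=True)
class Genome:
    """Chromosome sizes plus (optionally) the DNA sequence of each chromosome."""

    chrom_sizes: Mapping[str, int]
    sequence: Mapping[str, str] | None = None
    genome_id: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom_sizes", dict(self.chrom_sizes))
        if self.sequence is not None:
            object.__setattr__(self, "sequence", dict(self.sequence))
            for chrom, seq in self.sequence.items():
                size = self.chrom_sizes.get(chrom)
                if size is None:
                    raise ValueError(f"sequence for unknown chromosome {chrom}")
                if len(seq) != size:
                    raise ValueError(
                        f"sequence length {len(seq)} != recorded size {size} "
                        f"for {chrom}"
                    )

    @classmethod
    def from_fasta(cls, path: str | Path, genome_id: str = "custom") -> "Genome":
        seqs = read_fasta(path)
        return cls({c: len(s) for c, s in seqs.items()}, seqs, genome_id)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (small) FASTA file into a chrom → uppercase sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in seqs:
            fh.write(f">{chrom}\n")
            seq = seqs[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_chrom_sizes(path: str | Path, genome_id: str = "custom") -> Genome:
    """Read a two-column ``name<TAB>length`` chromosome-sizes table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: bad length {fields[1]!r}") from exc
    return Genome(sizes, genome_id=genome_id)


def write_chrom_sizes(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome.chrom_sizes):
            fh.write(f"{chrom}\t{genome.chrom_sizes[chrom]}\n")


_BED_SKIP_PREFIXES = ("track", "browser", "#")


def _parse_bed_line(line: str, lineno: int, path: str | Path) -> GenomicInterval:
    fields = line.split("\t") if "\t" in line else line.split()
    if len(fields) < 3:
        raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(
            f"{path}:{lineno}: non-integer coordinates {fields[1]!r}/{fields[2]!r}"
        ) from exc
    name = fields[3] if len(fields) > 3 else ""
    score: float | None = None
    if len(fields) > 4 and fields[4] not in (".", ""):
        try:
            score = float(fields[4])
        except ValueError as exc:
            raise BedParseError(f"{path}:{lineno}: bad score {fields[4]!r}") from exc
    strand = fields[5] if len(fields) > 5 else "."
    try:
        return GenomicInterval(chrom, start, end, name, score, strand)
    except ValueError as exc:
        raise BedParseError(f"{path}:{lineno}: {exc}") from exc


def read_bed(path: str | Path, label: str, genome_id: str = "custom") -> PeakSet:
    """Read a BED3/BED6 file into a sorted :class:`PeakSet`.

    Lines starting with ``track``, ``browser`` or ``#`` and blank lines are
    skipped.  Malformed lines raise :class:`BedParseError` naming the line
    number.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_BED_SKIP_PREFIXES):
                continue
            intervals.append(_parse_bed_line(line, lineno, path))
    return PeakSet(label, tuple(intervals), genome_id)


def write_bed(peaks: PeakSet | Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED; BED6 when any name/score/strand is set, else BED3."""
    ivs = list(peaks)
    bed6 = any(iv.name or iv.score is not None or iv.strand != "." for iv in ivs)
    with open(path, "w") as fh:
        for iv in ivs:
            if bed6:
                score = "." if iv.score is None else format(iv.score, "g")
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def _overlap_trees(peaks: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in peaks:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def intersect_replicates(replicates: Sequence[PeakSet], min_bp: int = 1) -> PeakSet:
    """Retain peaks of the first replicate supported by every other replicate.

    A replicate-1 peak is kept when it shares at least ``min_bp`` bases with
    at least one peak of *each* other replicate.  The retained coordinates are
    the replicate-1 intervals (no merging), so the result is a subset of the
    first replicate and the operation is idempotent.
    """
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates")
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    first = replicates[0]
    for rep in replicates[1:]:
        if rep.genome_id != first.genome_id:
            raise ValueError(
                f"genome_id mismatch: {rep.label}={rep.genome_id!r} vs "
                f"{first.label}={first.genome_id!r}"
            )
    other_trees = [_overlap_trees(rep) for rep in replicates[1:]]

    def supported(iv: GenomicInterval, trees: dict[str, IntervalTree]) -> bool:
        tree = trees.get(iv.chrom)
        if tree is None:
            return False
        return any(
            min(iv.end, hit.end) - max(iv.start, hit.begin) >= min_bp
            for hit in tree.overlap(iv.start, iv.end)
        )

    kept = tuple(
        iv for iv in first if all(supported(iv, trees) for trees in other_trees)
    )
    log.info(
        "intersect_replicates: %d/%d peaks of %r supported by all %d replicates",
        len(kept), len(first), first.label, len(replicates),
    )
    return PeakSet(first.label, kept, first.genome_id)
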