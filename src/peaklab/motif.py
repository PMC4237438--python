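"""IUPAC consensus-motif scanning and background occurrence rates.

Consensus motifs are written in the degenerate IUPAC nucleotide alphabet
(e.g. the SOX factor consensus ``ACAAWR``, where W = A/T and R = A/G).
Scanning reports every match position on the forward strand plus every
position where the reverse-complement of the motif matches (a site on the
opposite strand); overlapping matches are all reported, and ``N`` bases in
the subject sequence never match any code.

The expected background rate of a motif is estimated empirically: draw
length-matched windows uniformly from the genome and count the fraction
containing at least one hit on either strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Seq import reverse_complement

from .intervals import GenomicInterval, Genome, PeakSet

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: The SOXB1 consensus used by default throughout the package.
SOX_CONSENSUS = "ACAAWR"


@dataclass(frozen=True)
class ConsensusMotif:
    """A degenerate consensus pattern over the IUPAC nucleotide alphabet."""

    pattern: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", self.pattern.upper())
        bad = [c for c in self.pattern if c not in IUPAC_CODES]
        if bad or not self.pattern:
            raise ValueError(
                f"invalid IUPAC character(s) {bad!r} in motif {self.pattern!r}"
            )

    @property
    def length(self) -> int:
        return len(self.pattern)

    @property
    def reverse_pattern(self) -> str:
        return str(reverse_complement(self.pattern))

    def _regex(self, pattern: str) -> re.Pattern[str]:
        # zero-width lookahead so overlapping matches are all found; IUPAC
        # classes expand to ACGT subsets only, so a subject N never matches
        body = "".join(
            c if len(IUPAC_CODES[c]) == 1 else f"[{IUPAC_CODES[c]}]"
            for c in pattern
        )
        return re.compile(f"(?={body})")

    @property
    def forward_regex(self) -> re.Pattern[str]:
        return self._regex(self.pattern)

    @property
    def reverse_regex(self) -> re.Pattern[str]:
        return self._regex(self.reverse_pattern)


@dataclass(frozen=True)
class MotifReport:
    """Per-peak occurrence counts plus observed and background hit fractions."""

    motif: ConsensusMotif
    per_peak: tuple[tuple[GenomicInterval, int], ...]
    fraction_with_hit: float
    background_fraction: float | None = None
    n_background: int | None = None
    seed: int | None = None


def scan(seq: str, motif: ConsensusMotif | str) -> list[tuple[int, str]]:
    """All motif match positions in ``seq``, as (position, strand) tuples.

    Positions index the given sequence; a ``-`` hit at position ``p`` means
    the reverse complement of ``seq[p:p+len]`` matches the motif.
    """
    if isinstance(motif, str):
        motif = ConsensusMotif(motif)
    seq = seq.upper()
    hits = [(m.start(), "+") for m in motif.forward_regex.finditer(seq)]
    hits += [(m.start(), "-") for m in motif.reverse_regex.finditer(seq)]
    return sorted(hits)


def peak_sequences(peaks: PeakSet, genome: Genome) -> list[str]:
    """Extract the genomic sequence under each peak (errors on overflow)."""
    if genome.sequence is None:
        raise ValueError("genome carries no sequence")
    seqs = []
    for iv in peaks:
        chrom_seq = genome.sequence.get(iv.chrom)
        if chrom_seq is None:
            raise ValueError(f"no sequence for chromosome {iv.chrom}")
        if iv.end > len(chrom_seq):
            raise ValueError(f"peak {iv} outside sequence bounds")
        seqs.append(chrom_seq[iv.start : iv.end])
    return seqs


def peak_hit_fraction(
    peaks: PeakSet, genome: Genome, motif: ConsensusMotif | str
) -> MotifReport:
    """Fraction of peaks whose sequence contains >=1 hit on either strand.

    A peak counts once however many hits it contains ("at least one
    occurrence" semantics).
    """
    if isinstance(motif, str):
        motif = ConsensusMotif(motif)
    if not len(peaks):
        raise ValueError("empty PeakSet")
    counts = [len(scan(seq, motif)) for seq in peak_sequences(peaks, genome)]
    per_peak = tuple(zip(peaks.intervals, counts))
    fraction = sum(1 for c in counts if c > 0) / len(counts)
    return MotifReport(motif, per_peak, fraction)


def background_fraction(
    genome: Genome,
    peak_lengths: Sequence[int],
    n_draws: int,
    motif: ConsensusMotif | str,
    seed: int = 0,
) -> float:
    """Empirical background hit rate from random length-matched windows.

    Draws ``n_draws`` windows: each takes a length sampled (with
    replacement) from ``peak_lengths`` and a uniform position among all
    placements of that length across the genome.  Returns the fraction of
    windows containing at least one hit on either strand.
    """
    if isinstance(motif, str):
        motif = ConsensusMotif(motif)
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if genome.sequence is None:
        raise ValueError("genome carries no sequence")
    if not peak_lengths:
        raise ValueError("peak_lengths is empty")
    rng = np.random.default_rng(seed)
    chroms = sorted(genome.sequence)
    lengths = np.asarray(peak_lengths, dtype=np.int64)
    n_hit = 0
    for _ in range(n_draws):
        length = int(rng.choice(lengths))
        # weight chromosomes by the number of valid placements of this length
        weights = np.array(
            [max(genome.chrom_sizes[c] - length + 1, 0) for c in chroms],
            dtype=np.float64,
        )
        if weights.sum() == 0:
            raise ValueError("window length exceeds every chromosome")
        chrom = chroms[int(rng.choice(len(chroms), p=weights / weights.sum()))]
        start = int(rng.integers(0, genome.chrom_sizes[chrom] - length + 1))
        window = genome.sequence[chrom][start : start + length]
        if scan(window, motif):
            n_hit += 1
    return n_hit / n_draws


def motif_report(
    peaks: PeakSet,
    genome: Genome,
    motif: ConsensusMotif | str,
    n_background: int = 1000,
    seed: int = 0,
) -> MotifReport:
    """Observed per-peak occurrence plus a length-matched background rate."""
    report = peak_hit_fraction(peaks, genome, motif)
    bg = background_fraction(
        genome, [iv.length for iv in peaks], n_background, report.motif, seed
    )
    return MotifReport(
        report.motif, report.per_peak, report.fraction_with_hit,
        background_fraction=bg, n_background=n_background, seed=seed,
    )


def write_motif_report(report: MotifReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#motif\t{report.motif.pattern}\n")
        fh.write(f"#fraction_with_hit\t{report.fraction_with_hit:.6g}\n")
        if report.background_fraction is not None:
            fh.write(f"#background_fraction\t{report.background_fraction:.6g}\n")
            fh.write(f"#n_background\t{report.n_background}\n")
            fh.write(f"#seed\t{report.seed}\n")
        fh.write("chrom\tstart\tend\tname\tn_hits\n")
        for iv, count in report.per_peak:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{count}\n")
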