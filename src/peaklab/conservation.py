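"""Per-peak evolutionary conservation from a phastCons-like track.

A conservation track holds sparse, disjoint segments of per-base scores in
[0, 1] (e.g. phastCons probabilities from a placental-mammal alignment);
bases not covered by any segment take a configurable default (0.0 by
convention, since phastCons tracks leave unalignable bases unscored).  A
peak's conservation is the length-weighted mean over its bases, and peaks
are binned as ``low`` (mean <= 0.1), ``moderate`` (0.1 < mean <= 0.5) or
``high`` (mean > 0.5) — strict "greater than" at both cut-offs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .intervals import BedParseError, GenomicInterval, PeakSet

CLASSES = ("low", "moderate", "high")

#: Class thresholds: score > 0.5 is highly conserved, score > 0.1 shows
#: some conservation, anything else is unconserved.
HIGH_THRESHOLD = 0.5
MODERATE_THRESHOLD = 0.1


@dataclass(frozen=True)
class _ChromSegments:
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray


@dataclass(frozen=True)
class ConservationTrack:
    """Sparse per-base conservation scores with an implicit default.

    Parameters
    ----------
    segments
        Mapping chromosome → arrays of sorted, disjoint (start, end, value).
    default_value
        Score assumed for uncovered bases.  ``None`` makes uncovered bases
        (or absent chromosomes) an error rather than a value.
    """

    segments: dict[str, _ChromSegments]
    default_value: float | None = 0.0

    def __post_init__(self) -> None:
        if self.default_value is not None and not 0.0 <= self.default_value <= 1.0:
            raise ValueError("default_value must be in [0, 1]")
        for chrom, seg in self.segments.items():
            if np.any(seg.values < 0) or np.any(seg.values > 1):
                raise ValueError(f"{chrom}: track values must lie in [0, 1]")
            if np.any(seg.starts >= seg.ends):
                raise ValueError(f"{chrom}: empty or inverted segment")
            if np.any(seg.ends[:-1] > seg.starts[1:]):
                raise ValueError(f"{chrom}: segments must be sorted and disjoint")

    @classmethod
    def from_segments(
        cls,
        segments: Iterable[tuple[str, int, int, float]],
        default_value: float | None = 0.0,
    ) -> "ConservationTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in segments:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        packed = {}
        for chrom, segs in by_chrom.items():
            segs.sort()
            packed[chrom] = _ChromSegments(
                np.array([s for s, _, _ in segs], dtype=np.int64),
                np.array([e for _, e, _ in segs], dtype=np.int64),
                np.array([v for _, _, v in segs], dtype=np.float64),
            )
        return cls(packed, default_value)

    @classmethod
    def from_bedgraph(
        cls, path: str | Path, default_value: float | None = 0.0
    ) -> "ConservationTrack":
        """Read a 4-column bedGraph (chrom, start, end, value; 0-based half-open)."""
        segs: list[tuple[str, int, int, float]] = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                f = line.split("\t") if "\t" in line else line.split()
                if len(f) < 4:
                    raise BedParseError(f"{path}:{lineno}: expected 4 columns")
                try:
                    segs.append((f[0], int(f[1]), int(f[2]), float(f[3])))
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: {exc}") from exc
        return cls.from_segments(segs, default_value)

    @classmethod
    def from_wig(
        cls, path: str | Path, default_value: float | None = 0.0
    ) -> "ConservationTrack":
        """Read a fixed-step WIG track (1-based starts, converted on load)."""
        segs: list[tuple[str, int, int, float]] = []
        chrom, pos, step, span = None, 0, 1, 1
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                if line.startswith("fixedStep"):
                    fields = dict(
                        kv.split("=", 1) for kv in line.split()[1:] if "=" in kv
                    )
                    try:
                        chrom = fields["chrom"]
                        pos = int(fields["start"]) - 1  # WIG is 1-based
                        step = int(fields.get("step", 1))
                        span = int(fields.get("span", 1))
                    except (KeyError, ValueError) as exc:
                        raise BedParseError(f"{path}:{lineno}: bad fixedStep header") from exc
                    continue
                if chrom is None:
                    raise BedParseError(f"{path}:{lineno}: value before fixedStep header")
                try:
                    value = float(line)
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: bad value {line!r}") from exc
                segs.append((chrom, pos, pos + span, value))
                pos += step
        return cls.from_segments(segs, default_value)

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.segments):
                seg = self.segments[chrom]
                for s, e, v in zip(seg.starts, seg.ends, seg.values):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


@dataclass(frozen=True)
class ConservationSummary:
    """Per-peak mean scores/classes and the class fractions of a peak set."""

    per_peak: tuple[tuple[GenomicInterval, float, str], ...]
    fractions: dict[str, float]


def mean_score(peak: GenomicInterval, track: ConservationTrack) -> float:
    """Length-weighted mean conservation over ``[start, end)`` of a peak.

    Uncovered bases contribute ``track.default_value``; if the default is
    ``None``, any uncovered base (including a chromosome absent from the
    track) raises ``ValueError``.
    """
    seg = track.segments.get(peak.chrom)
    if seg is None:
        if track.default_value is None:
            raise ValueError(f"chromosome {peak.chrom} absent from track")
        return track.default_value
    i0 = int(np.searchsorted(seg.ends, peak.start, side="right"))
    i1 = int(np.searchsorted(seg.starts, peak.end, side="left"))
    ov_start = np.maximum(seg.starts[i0:i1], peak.start)
    ov_end = np.minimum(seg.ends[i0:i1], peak.end)
    ov = np.maximum(ov_end - ov_start, 0)
    covered = int(ov.sum())
    total = float((ov * seg.values[i0:i1]).sum())
    uncovered = peak.length - covered
    if uncovered:
        if track.default_value is None:
            raise ValueError(f"peak {peak} has {uncovered} uncovered base(s)")
        total += uncovered * track.default_value
    return total / peak.length


def classify(score: float) -> str:
    """Bin a mean conservation score: > 0.5 high, > 0.1 moderate, else low."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    if score > HIGH_THRESHOLD:
        return "high"
    if score > MODERATE_THRESHOLD:
        return "moderate"
    return "low"


def summarize(peaks: PeakSet, track: ConservationTrack) -> ConservationSummary:
    """Score and classify every peak; report class fractions (summing to 1)."""
    if not len(peaks):
        raise ValueError("empty PeakSet")
    per_peak = tuple(
        (peak, (s := mean_score(peak, track)), classify(s)) for peak in peaks
    )
    counts = {c: 0 for c in CLASSES}
    for _, _, cls_ in per_peak:
        counts[cls_] += 1
    fractions = {c: n / len(peaks) for c, n in counts.items()}
    return ConservationSummary(per_peak, fractions)


def write_summary(summary: ConservationSummary, path: str | Path) -> None:
    """Tab-separated per-peak table plus a trailing fractions block."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tname\tmean_score\tclass\n")
        for peak, score, cls_ in summary.per_peak:
            fh.write(
                f"{peak.chrom}\t{peak.start}\t{peak.end}\t{peak.name or '.'}\t"
                f"{score:.2f}\t{cls_}\n"
            )
        fh.write("#fractions")
        for c in CLASSES:
            fh.write(f"\t{c}={summary.fractions[c]:.6g}")
        fh.write("\n")
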