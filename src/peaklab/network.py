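"""Interaction networks from paired-end (ChIA-PET-like) anchor records.

Each interaction record links two genomic anchors (BEDPE-style).  Peaks are
matched to anchors by the same midpoint-distance rule used for peak-peak
overlap; anchors recurring with positional jitter are merged into nodes by
midpoint proximity, and the resulting graph yields connected components and
per-hub counts of linked nodes split into inter- and intrachromosomal
partners.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .intervals import BedParseError, GenomicInterval, PeakSet
from .overlap import DEFAULT_MAX_DIST, _mids_by_chrom

DEFAULT_MERGE_DIST = 500


@dataclass(frozen=True)
class InteractionPair:
    """One paired-anchor interaction record."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    pair_id: str

    @property
    def interchromosomal(self) -> bool:
        return self.anchor_a.chrom != self.anchor_b.chrom


@dataclass(frozen=True)
class AnchorOverlap:
    """Peak-anchor overlap: per-pair (a, b) bound flags and distinct-peak count."""

    bound_flags: tuple[tuple[bool, bool], ...]
    n_anchors_bound: int
    n_peaks_hit: int


@dataclass(frozen=True)
class InteractionGraph:
    """Merged-anchor interaction graph with component and hub summaries.

    Nodes are ``"chrom:midpoint"`` strings for merged anchor clusters,
    carrying ``chrom``, ``mid`` and ``peak_bound`` attributes; edges carry
    the list of pair_ids connecting two clusters.
    """

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def component_sizes(self) -> list[int]:
        return sorted(
            (len(c) for c in nx.connected_components(self.graph)), reverse=True
        )

    def hub_table(self, peak_bound_only: bool = True) -> pd.DataFrame:
        """Per-node linked-partner counts split inter- vs intrachromosomal.

        Linked nodes are distinct neighbours (self-loops excluded), so
        ``n_inter + n_intra`` equals the node's degree in the merged graph.
        """
        rows = []
        for node, data in sorted(self.graph.nodes(data=True)):
            if peak_bound_only and not data["peak_bound"]:
                continue
            neighbours = [n for n in self.graph.neighbors(node) if n != node]
            inter = sum(
                1 for n in neighbours if self.graph.nodes[n]["chrom"] != data["chrom"]
            )
            rows.append(
                {
                    "node": node,
                    "chrom": data["chrom"],
                    "mid": data["mid"],
                    "peak_bound": data["peak_bound"],
                    "n_linked": len(neighbours),
                    "n_inter": inter,
                    "n_intra": len(neighbours) - inter,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["node", "chrom", "mid", "peak_bound", "n_linked",
                     "n_inter", "n_intra"],
        )


def load_interactions(path: str | Path) -> list[InteractionPair]:
    """Read BEDPE-style records: chromA startA endA chromB startB endB [id]."""
    pairs: list[InteractionPair] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 6:
                raise BedParseError(f"{path}:{lineno}: expected >=6 columns")
            try:
                a = GenomicInterval(f[0], int(f[1]), int(f[2]))
                b = GenomicInterval(f[3], int(f[4]), int(f[5]))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            pair_id = f[6] if len(f) > 6 else f"pair{lineno}"
            pairs.append(InteractionPair(a, b, pair_id))
    return pairs


def write_interactions(pairs: Sequence[InteractionPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(
                f"{p.anchor_a.chrom}\t{p.anchor_a.start}\t{p.anchor_a.end}\t"
                f"{p.anchor_b.chrom}\t{p.anchor_b.start}\t{p.anchor_b.end}\t"
                f"{p.pair_id}\n"
            )


def anchors_to_peakset(
    pairs: Sequence[InteractionPair], label: str = "anchors", genome_id: str = "custom"
) -> PeakSet:
    """Flatten both anchors of every pair into one PeakSet (for permutation
    significance of peak-anchor overlap via :func:`peaklab.overlap.permutation_test`)."""
    ivs = []
    for p in pairs:
        ivs.append(GenomicInterval(
            p.anchor_a.chrom, p.anchor_a.start, p.anchor_a.end, f"{p.pair_id}/A"
        ))
        ivs.append(GenomicInterval(
            p.anchor_b.chrom, p.anchor_b.start, p.anchor_b.end, f"{p.pair_id}/B"
        ))
    return PeakSet(label, tuple(ivs), genome_id)


def peak_anchor_overlap(
    peaks: PeakSet,
    pairs: Sequence[InteractionPair],
    max_dist: int = DEFAULT_MAX_DIST,
) -> AnchorOverlap:
    """Flag anchors bound by a peak and count distinct peaks hitting anchors.

    An anchor is peak-bound iff some peak midpoint lies within ``max_dist``
    of the anchor midpoint; ``n_peaks_hit`` counts distinct peaks bound to
    at least one anchor.
    """
    peak_mids = _mids_by_chrom(peaks)

    def bound(anchor: GenomicInterval) -> bool:
        entry = peak_mids.get(anchor.chrom)
        if entry is None:
            return False
        mids = entry[0]
        lo = np.searchsorted(mids, anchor.midpoint - max_dist, side="left")
        hi = np.searchsorted(mids, anchor.midpoint + max_dist, side="right")
        return bool(hi > lo)

    flags = tuple((bound(p.anchor_a), bound(p.anchor_b)) for p in pairs)
    n_anchors = sum(fa + fb for fa, fb in flags)

    # distinct peaks with >=1 anchor within max_dist
    anchor_mids = _mids_by_chrom(anchors_to_peakset(pairs, genome_id=peaks.genome_id))
    n_peaks = 0
    for iv in peaks:
        entry = anchor_mids.get(iv.chrom)
        if entry is None:
            continue
        mids = entry[0]
        lo = np.searchsorted(mids, iv.midpoint - max_dist, side="left")
        hi = np.searchsorted(mids, iv.midpoint + max_dist, side="right")
        if hi > lo:
            n_peaks += 1
    return AnchorOverlap(flags, int(n_anchors), n_peaks)


def build_graph(
    pairs: Sequence[InteractionPair],
    bound_flags: Sequence[tuple[bool, bool]] | None = None,
    merge_dist: int = DEFAULT_MERGE_DIST,
) -> InteractionGraph:
    """Merge jittered anchors into nodes and connect them per interaction.

    Anchors on the same chromosome whose midpoints chain within
    ``merge_dist`` (single linkage) collapse to one node; ``merge_dist=0``
    keeps one node per distinct anchor midpoint.  A node is ``peak_bound``
    when any merged anchor was flagged bound.
    """
    if bound_flags is None:
        bound_flags = [(False, False)] * len(pairs)
    if len(bound_flags) != len(pairs):
        raise ValueError("bound_flags must align with pairs")

    # collect (chrom, mid, bound) for both anchors of every pair
    anchors: list[tuple[str, int, bool]] = []
    for p, (fa, fb) in zip(pairs, bound_flags):
        anchors.append((p.anchor_a.chrom, p.anchor_a.midpoint, fa))
        anchors.append((p.anchor_b.chrom, p.anchor_b.midpoint, fb))

    # single-linkage clustering of midpoints per chromosome
    by_chrom: dict[str, list[int]] = {}
    for i, (chrom, mid, _) in enumerate(anchors):
        by_chrom.setdefault(chrom, []).append(i)
    node_of_anchor: dict[int, str] = {}
    node_attrs: dict[str, dict] = {}
    for chrom, idxs in by_chrom.items():
        idxs.sort(key=lambda i: anchors[i][1])
        cluster: list[int] = []
        clusters: list[list[int]] = []
        prev_mid: int | None = None
        for i in idxs:
            mid = anchors[i][1]
            if prev_mid is not None and mid - prev_mid > merge_dist:
                clusters.append(cluster)
                cluster = []
            cluster.append(i)
            prev_mid = mid
        if cluster:
            clusters.append(cluster)
        for cluster in clusters:
            mids = [anchors[i][1] for i in cluster]
            rep = int(np.median(mids))
            node = f"{chrom}:{rep}"
            node_attrs[node] = {
                "chrom": chrom,
                "mid": rep,
                "peak_bound": any(anchors[i][2] for i in cluster),
            }
            for i in cluster:
                node_of_anchor[i] = node

    graph = nx.Graph()
    for node, attrs in sorted(node_attrs.items()):
        graph.add_node(node, **attrs)
    for j, p in enumerate(pairs):
        u = node_of_anchor[2 * j]
        v = node_of_anchor[2 * j + 1]
        if graph.has_edge(u, v):
            graph.edges[u, v]["pair_ids"].append(p.pair_id)
        else:
            graph.add_edge(u, v, pair_ids=[p.pair_id])
    return InteractionGraph(graph)


def write_edge_list(igraph: InteractionGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tpair_ids\n")
        for u, v, data in sorted(igraph.graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{','.join(sorted(data['pair_ids']))}\n")
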