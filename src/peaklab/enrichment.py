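"""Gene-list enrichment for peak-bearing genes, plus the ChIP-qPCR call rule.

A candidate gene list (e.g. genes differentially expressed after knocking
out the profiled transcription factor) is tested for over-representation of
peak-associated genes against a stated background rate — the genome-wide
fraction of genes that carry a peak.  The test is a one-sided exact
binomial tail, matching the framing of an "expected random frequency"; a
seeded permutation alternative drawing random gene lists from the gene
universe is provided as a cross-check.

The qPCR rule converts IgG-normalised threshold-cycle differences between a
peak region and a non-enriched control region into a fold change (each Ct
unit is a two-fold difference in template) and a positive/negative call.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Collection, Iterable

import numpy as np
from scipy.stats import binom

from .annotation import GeneModel, GeneSet


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of the binomial gene-list enrichment test."""

    n_list: int
    k_with_peak: int
    observed_fraction: float
    background_rate: float
    p_value: float


@dataclass(frozen=True)
class QpcrMeasurement:
    """Threshold cycles for a peak/non-enriched region pair, sample and IgG."""

    ct_peak: float
    ct_nonenriched: float
    ct_igg_peak: float = 0.0
    ct_igg_nonenriched: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ct_peak", "ct_nonenriched"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("ct_igg_peak", "ct_igg_nonenriched"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def gene_list_enrichment(
    gene_list: Collection[str],
    peak_genes: Collection[str],
    background_rate: float,
) -> EnrichmentResult:
    """One-sided exact binomial test for peak-bearing genes in a gene list.

    ``p_value = P(X >= k)`` for ``X ~ Binomial(n_list, background_rate)``
    where ``k`` is the number of list genes found in ``peak_genes``.
    """
    genes = set(gene_list)
    if not genes:
        raise ValueError("empty gene list")
    if not 0.0 < background_rate < 1.0:
        raise ValueError("background_rate must lie in (0, 1)")
    n = len(genes)
    k = len(genes & set(peak_genes))
    # survival function at k-1 gives the inclusive upper tail P(X >= k)
    p_value = float(binom.sf(k - 1, n, background_rate))
    return EnrichmentResult(n, k, k / n, background_rate, p_value)


def permutation_enrichment(
    gene_list: Collection[str],
    peak_genes: Collection[str],
    universe: Collection[str],
    n_perm: int = 10000,
    seed: int = 0,
) -> float:
    """Empirical enrichment p-value from random same-size gene lists.

    Draws ``n_perm`` lists of the same size uniformly without replacement
    from ``universe`` and returns the add-one tail probability that a random
    list contains at least as many peak-bearing genes as the observed one.
    """
    genes = set(gene_list)
    if not genes:
        raise ValueError("empty gene list")
    uni = sorted(set(universe))
    if len(uni) < len(genes):
        raise ValueError("universe smaller than gene list")
    peak_mask = np.array([g in set(peak_genes) for g in uni])
    k_obs = len(genes & set(peak_genes))
    rng = np.random.default_rng(seed)
    k_null = np.array(
        [peak_mask[rng.choice(len(uni), size=len(genes), replace=False)].sum()
         for _ in range(n_perm)]
    )
    return (1 + int(np.count_nonzero(k_null >= k_obs))) / (n_perm + 1)


def background_gene_rate(
    all_genes: GeneSet | Iterable[GeneModel] | Collection[str],
    peak_genes: Collection[str],
) -> float:
    """Fraction of all genes that carry at least one peak."""
    if isinstance(all_genes, GeneSet):
        ids = set(all_genes.gene_ids)
    else:
        items = list(all_genes)
        ids = {g.gene_id if isinstance(g, GeneModel) else str(g) for g in items}
    if not ids:
        raise ValueError("empty gene set")
    return len(set(peak_genes)) / len(ids)


def qpcr_call(
    m: QpcrMeasurement, threshold: float = 2.0
) -> tuple[float, bool]:
    """IgG-normalised ChIP-qPCR enrichment call.

    ``dCt = (Ct_nonenriched - Ct_peak) - (Ct_IgG_nonenriched - Ct_IgG_peak)``;
    the fold change is ``2**dCt`` and the signal is positive when dCt is
    strictly greater than ``threshold`` cycles (default 2, i.e. >4-fold).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    dct = (m.ct_nonenriched - m.ct_peak) - (m.ct_igg_nonenriched - m.ct_igg_peak)
    return 2.0 ** dct, dct > threshold


def read_gene_list(path: str | Path) -> list[str]:
    """One gene identifier per line; blanks and ``#`` comments skipped."""
    out: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def read_qpcr_table(path: str | Path) -> dict[str, QpcrMeasurement]:
    """Tab-separated Ct table: name, ct_peak, ct_nonenriched[, igg_peak, igg_ne]."""
    out: dict[str, QpcrMeasurement] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.lower().startswith("name\t"):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns")
            vals = [float(x) for x in f[1:5]]
            while len(vals) < 4:
                vals.append(0.0)
            out[f[0]] = QpcrMeasurement(*vals)
    return out


def write_enrichment_report(result: EnrichmentResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"n_list\t{result.n_list}\n")
        fh.write(f"k_with_peak\t{result.k_with_peak}\n")
        fh.write(f"observed_fraction\t{result.observed_fraction:.6g}\n")
        fh.write(f"background_rate\t{result.background_rate:.6g}\n")
        fh.write(f"p_value\t{result.p_value:.6g}\n")
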