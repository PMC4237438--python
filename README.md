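# peaklab

Integrative analysis of transcription-factor ChIP-seq peak sets, built for
the kind of study that asks what a neural transcription factor such as SOX3
is doing genome-wide: which binding sites are reproducible across
replicates, where they sit relative to genes, how evolutionarily conserved
they are, whether they coincide with enhancer marks (P300-like coactivator
peaks), whether they carry the factor's consensus motif, whether the
factor's direct targets are over-represented in a differential-expression
gene list, and how binding sites participate in long-range (ChIA-PET-style)
interaction networks.

`peaklab` is a library first (plain BED/bedGraph/FASTA/BEDPE in, pandas
tables out) with a thin `peaklab` command-line wrapper, and it ships a
synthetic-data generator that records ground truth for every planted
feature, so the whole pipeline is testable end to end with exact expected
answers.

## The statistics at the core

* **Replicate consistency.** A peak is retained when it shares ≥ `min_bp`
  bases (default 1) with a peak in *every* other biological replicate; the
  retained coordinates are the first replicate's intervals.
* **Genomic classification.** Each peak is assigned the gene with minimal
  |midpoint − TSS| on its chromosome and classified with precedence
  promoter (|d| ≤ 2 kb of the TSS) > intronic (midpoint inside the gene
  span, outside exons) > intergenic.
* **Conservation.** Per-peak mean of a phastCons-like track (scores in
  [0, 1], uncovered bases scored 0): mean > 0.5 is *highly* conserved,
  mean > 0.1 *moderately*, both strict.
* **Midpoint overlap and its null.** Two peaks overlap when their midpoints
  are within `max_dist` bp (default 300, inclusive). Significance comes
  from shuffling set A uniformly within its own chromosomes (lengths
  preserved) and the add-one empirical p-value
  `p = (1 + #{perm ≥ obs}) / (n_perm + 1)`, with the chance expectation
  reported as the null mean.
* **Consensus motifs.** IUPAC degenerate patterns (the SOX consensus
  `ACAAWR` by default) scanned on both strands, N never matching; a peak
  counts once however many hits it holds. Background rates come from random
  length-matched windows.
* **Gene-list enrichment.** One-sided exact binomial tail
  `P(X ≥ k | n, p₀)` for `k` peak-bearing genes in a list of `n` against a
  background rate `p₀` (the genome-wide fraction of genes with a peak).
* **qPCR validation calls.** `ΔCt = (Ct_nonenriched − Ct_peak)` normalised
  against the IgG control; fold change `2^ΔCt`, positive when ΔCt > 2.
* **Interaction networks.** Paired anchors merged by midpoint proximity
  into nodes; per-hub counts of linked nodes split inter- vs
  intrachromosomal.

## Worked example

The package ships a curated table of 19 SOX3 ChIP peaks (mm9) near the 13
peak-bearing genes among 19 genes differentially expressed in Sox3-null
neural progenitors:

```python
import peaklab as pl

table = pl.sox3_target_table()
print(f"peaks: {len(table.peaks)}  distinct genes: {len(table.genes)}")
counts = {c: table.locations.count(c) for c in ("intron", "intergenic", "promoter")}
print("locations:", counts)

result = pl.gene_list_enrichment(pl.sox3_de_gene_list(), set(table.genes), 0.24)
print(f"enrichment: {result.k_with_peak}/{result.n_list} "
      f"({100*result.observed_fraction:.1f}%), p = {result.p_value:.3g}")
```

prints

```
peaks: 19  distinct genes: 13
locations: {'intron': 9, 'intergenic': 7, 'promoter': 3}
enrichment: 13/19 (68.4%), p = 5.27e-05
```

i.e. 68.4% of the differentially expressed genes carry a SOX3 peak, against
an expected random frequency of 24% of genes genome-wide — an exact
binomial p ≈ 5.3 × 10⁻⁵, far beyond chance. The 9/7/3
intron/intergenic/promoter split shows the binding sites are mostly distal,
the signature of enhancer-mediated regulation.

The same workflow runs end to end on synthetic data:

```bash
peaklab simulate --outdir bundle --seed 42
peaklab run-all --bundle-dir bundle --outdir out --seed 42 --n-perm 200
```

The summary echoes every threshold and then, for the default conditions,
reports `intersect.n_retained 100` (the 100 planted peaks survive all three
jittered replicates while 20 private peaks per replicate are dropped),
category fractions `0.11 / 0.28 / 0.61`, conservation fractions
`0.44 / 0.36 / 0.20`, a partner-set overlap of 29% with permutation
p ≈ 0.005 at 200 shuffles, and a motif hit fraction of 0.70 over a
motif-scrubbed background — each number equal to the generator's recorded
ground truth.

## Layout

```
src/peaklab/
  intervals.py     interval model, BED I/O, replicate intersection
  annotation.py    gene models, nearest-TSS classification
  conservation.py  bedGraph/WIG tracks, mean scores, classes
  overlap.py       midpoint overlap, n-way intersection, shuffle null
  motif.py         IUPAC consensus scanning, background rates
  enrichment.py    binomial gene-list test, qPCR calls
  network.py       BEDPE interactions, anchor merging, hubs
  synthetic.py     ground-truthed generator + curated fixture
  pipeline.py      run-all orchestration
  cli.py           click command-line interface
```

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
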