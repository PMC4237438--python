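# Methods

This note records the models, conventions and design choices behind
`peaklab`, what the synthetic-data generator does and does not emulate, and
the numerical details a user re-implementing or auditing the pipeline
would need.

## Coordinate conventions

All coordinates are 0-based half-open (UCSC BED). The curated peak table
shipped with the package is stored as printed in its source material —
1-based inclusive — and the loader subtracts 1 from every start. The
midpoint of an interval is `floor((start + end) / 2)`, which always lies
inside the interval; every distance rule in the package (overlap,
peak–anchor matching) operates on midpoints.

Chromosomes sort lexicographically, and intervals by
(chrom, start, end, name), so every container iterates deterministically.
Exact duplicate intervals are collapsed on construction with a logged
count.

## Replicate consistency

A first-replicate peak is retained when it shares at least `min_bp`
overlapping bases with at least one peak in each other replicate. The
criterion the original analyses used for "present in all replicates" is
typically unstated in the literature, so the threshold is a parameter with
the weakest sensible default (`min_bp = 1`). The retained interval is the
replicate-1 interval — no union or merge — which makes the operation
idempotent and its output a strict subset of replicate 1, and leaves the
result invariant under permutation of replicates 2..k.

## Nearest-TSS annotation

The TSS is `span_start` for + genes and `span_end − 1` for − genes. The
nearest gene minimises |midpoint − TSS| over genes on the peak's
chromosome only; equidistant TSSs tie-break on lexicographic gene id so
output is deterministic. The signed distance is orientation-corrected
(positive = downstream in the gene's reading direction).

Classification precedence is promoter > intronic > intergenic:

* promoter: |signed distance| ≤ `promoter_window` (default ±2,000 bp; the
  usual "proximal promoter" is not precisely defined in the field, so the
  window is a logged parameter);
* intronic: midpoint inside the nearest gene's span but outside all exons;
* everything else, including exonic midpoints, falls to intergenic —
  three-class outputs match how ChIP peak distributions are conventionally
  reported. An optional `exonic` category can be enabled.

Classification uses the peak midpoint rather than any-overlap, for
consistency with the midpoint-based overlap rule used everywhere else.

## Conservation

A track is a set of sorted, disjoint per-chromosome segments with values
in [0, 1]; the per-peak score is the length-weighted mean over the peak's
bases. Uncovered bases contribute `default_value`, 0.0 by default — the
convention matching sparse phastCons distributions, where unalignable
bases carry no score; pass `default_value=None` to make uncovered bases an
error instead. Classes use strict inequalities: mean > 0.5 high,
mean > 0.1 moderate, else low; scores of exactly 0.1 or 0.5 fall to the
lower class. Reports print two decimals; internal values are full
precision.

## Midpoint overlap and the permutation null

Peaks a and b overlap when on the same chromosome and
|mid(a) − mid(b)| ≤ `max_dist` (inclusive ≤; default 300 bp). The observed
statistic counts distinct set-A peaks with at least one partner, so the
a→b and b→a counts can differ and both directions are reported by the CLI.
N-way intersection keeps set-1 peaks with a partner in every other set.

The null model re-places every set-A interval uniformly at random within
its own chromosome, preserving interval lengths and per-chromosome counts
— an assumption-light null for "expected overlap by chance" that ignores
genome structure (no GC or TSS-distance matching; an optional exclusion
mask supports blacklists via rejection sampling). The p-value uses the
add-one rule, `(1 + #{perm ≥ obs}) / (n_perm + 1)`, so it is never zero
and is bounded below by `1/(n_perm+1)`. Draws come sequentially from one
seeded NumPy generator, so increasing `n_perm` under the same seed
reproduces the shorter run's counts as a prefix, and the seed is recorded
in the result object.

For uniform point-like sets on one chromosome of length L the null mean
has the closed form `n_a · (1 − (1 − (2·max_dist + 1)/L)^{n_b})`; the test
suite checks the sampler against it within three Monte-Carlo standard
errors.

## Consensus motifs

Motifs are IUPAC strings (default the SOX consensus `ACAAWR`; the
SOX/POU composite can be expressed as a gapped consensus with an `N`
spacer). Scanning compiles the pattern into a zero-width-lookahead regular
expression so overlapping matches are all reported, and runs both the
pattern and its reverse complement against the forward sequence; the
IUPAC classes expand to ACGT subsets only, so an N base in the subject
never matches any code. Position-weight-matrix scoring is out of scope —
occurrence statistics here are presence/absence ("at least one
occurrence"), with a peak counted once regardless of multiplicity.

The background rate is estimated from random length-matched windows drawn
uniformly from the genome (lengths sampled with replacement from the
observed peak lengths, chromosomes weighted by the number of valid
placements). Shuffling peak sequences would be an alternative background;
random regions were chosen because they need no sequence model and match
the "expected background occurrence" framing. For i.i.d. uniform sequence
the per-window hit probability has the closed form
`1 − (1 − p_match)^(2·(w − m + 1))`, used as an independent oracle in the
tests.

## Gene-list enrichment and qPCR calls

"Gene g has a peak" means g is some peak's nearest gene — a deliberate
simplification of looser "peak within the gene or flanks" definitions,
kept because it is the only relation the annotation stage defines. The
background rate is the fraction of all genes with a peak. The test is the
one-sided exact binomial tail `P(X ≥ k)` via `scipy.stats.binom.sf`; a
seeded permutation alternative (random same-size lists from the gene
universe) is provided as a cross-check. Under null lists drawn at the
background rate the binomial test is slightly conservative (the
hypergeometric truth has smaller variance), which the calibration test
allows for: type-I error at α = 0.05 must not exceed α + 2 Monte-Carlo SE.

qPCR: `ΔCt = (Ct_nonenriched − Ct_peak) − (Ct_IgG,nonenriched −
Ct_IgG,peak)`, fold change `2^ΔCt`, positive strictly above 2 cycles
(>4-fold); a ΔCt of exactly 2 is negative.

## Interaction networks

Anchors are matched to peaks with the same midpoint ≤ `max_dist` rule used
for peak–peak overlap (the matching rule for anchor data is rarely stated;
using one rule keeps the pipeline coherent). Because anchors recur with
positional jitter across pairs, anchors on one chromosome whose midpoints
chain within `merge_dist` (single linkage; default 500 bp, `merge_dist=0`
keeps one node per distinct midpoint) collapse into one graph node,
flagged peak-bound when any merged anchor was. Edges carry the pair ids
connecting two nodes; parallel pairs merge into one edge, so a hub's
inter- plus intrachromosomal linked-node counts equal its degree.
Significance of peak–anchor overlap reuses the permutation machinery with
the anchors flattened to a peak set.

## Synthetic data: what it emulates and what it does not

The generator lays out `n_chroms` equal-length chromosomes with genes in
fixed 30-kb territories (12-kb spans, three exons, alternating strand) and
a downstream "desert" divided into 2-kb slots. Reference peaks are planted
per the category fractions: promoter peaks 0.5–1.5 kb upstream of a TSS,
intronic peaks deep inside the intron far from the TSS (second intron for
+ genes, first for − genes, always > promoter window from the TSS), and
intergenic peaks on desert slots. All decoys — replicate-private peaks,
non-overlapping partners, unbound anchors — also take desert slots, so any
two distinct features are ≥ 1.5 kb apart and every label is exactly
recoverable. Conservation plateaus extend 200 bp beyond each designated
peak with values drawn U(0.6, 1.0) (high) or U(0.15, 0.45) (moderate) so
the per-peak mean equals the plateau value even after replicate jitter.
Sequences are i.i.d. uniform ACGT with every background motif occurrence
scrubbed by iterative re-randomisation, then exact consensus instances
planted at the centres of the designated fraction of peaks. Partner peaks
are placed within `max_dist − replicate_jitter` of their target midpoints
so planted overlaps survive the jittered replicate-consistent peak set.
One master seed fans out into independent per-component streams
(layout, conservation, sequence, replicates, partners, interactions), so
the whole bundle is reproducible and regenerating one component does not
perturb the others.

Default conditions: 100 peaks of width 150–400 bp on 4 × 1 Mb
chromosomes with 40 genes; category fractions 0.11 / 0.285 / 0.605
(promoter/intronic/intergenic) and conservation fractions 0.20 high /
0.36 moderate, mirroring the genome-wide proportions reported for
SOX3-class datasets; three replicates with ±50 bp jitter and 20 private
peaks each; a partner set overlapping 28.85% of its peaks (the midbrain
P300-like condition); the SOX consensus planted in 70% of peaks; and
19.4% of peaks carrying an interaction anchor (the 97-of-500 condition at
desk scale — genome-scale counts such as 8,067 peaks depend on external
datasets and are deliberately not reproduced).

What passing the closed-loop tests shows is that each stage recovers
exactly what was planted **under unambiguous placement**. Real data
violate those assumptions — overlapping genes, ambiguous nearest genes,
background motif matches, conservation gradients rather than plateaus,
collision between features — so the tests validate the algorithms, not
their biological error rates.

## Problem sizes and numerical details

The test-suite and acceptance-script problem sizes — 200×200-peak overlap
oracles, 999-shuffle permutation tests on 561-peak sets, 2,000-draw
background and calibration simulations, 1-to-4-Mb genomes — were chosen so
each check has enough resolution for its tolerance (3 Monte-Carlo SEs for
stochastic comparisons, exact equality for planted counts, 1e-12 for the
per-base conservation oracle) while the full suite stays fast.

Degenerate inputs are errors, not silent defaults: empty peak sets for
fractions, scores outside [0, 1], inverted intervals, peaks beyond
chromosome or sequence bounds, gene lists that are empty, background rates
of exactly 0 or 1. Fractions of peak categories and conservation classes
always sum to 1 by construction (counts over a partition).

## Known limitations

* The shuffle null ignores chromatin accessibility, GC content and
  distance-to-TSS structure; empirical "expected by chance" values are
  only as good as the uniform-placement assumption.
* Nearest-gene assignment ignores regulatory domains (no basal-plus-
  extension rules) and annotates each peak to exactly one gene.
* Consensus scanning has no mismatch tolerance or PWM scores; degenerate
  consensus strings over- and under-call relative to a trained model.
* The binomial enrichment treats genes as exchangeable; gene length and
  peak density biases are not modelled.
* The generator's unambiguous-placement guarantees do not extend to
  configurations with overlapping features; infeasible layouts raise
  rather than degrade.
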