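# Methods

This note records the models, conventions and design choices behind
`coregrn`, in the order the pipeline runs them.

## Coordinate and normalization conventions

All coordinates are 0-based half-open (BED). A peak's centre is
`floor((start + end) / 2)`. "Normalized tag counts" means tags per 10
million (`raw × 1e7 / library_size`): depth-only normalization, no quantile
step — the simplest contract that makes counts comparable across
libraries; the scale is arbitrary but fixed and documented. Promoters are
TSS ± 2000 bp, strand-agnostic; the window is a config parameter
everywhere it is used.

## Chromatin contrast

Peaks are ranked by `log2((a + c)/(b + c))` with pseudocount c = 1 on
normalized window counts (200 bp ranking windows; 2 kb windows for density
panels). Ties break by (log2FC desc, chrom asc, start asc) so output order
is deterministic. Condition-specific sites use |log2FC| ≥ 1, boundary
inclusive — mirroring the volcano convention used for expression, since
accessibility thresholds are rarely stated explicitly in this literature.
The A-specific/B-specific/shared partition is asserted exhaustive and
disjoint on every call. Two peaks are "shared" between sets at ≥ 1 bp
overlap (configurable); counts are peak-wise on each set's own intervals,
so asymmetric counts are expected. Interval merging treats book-ended
intervals as one; merge, overlap and density are tested against per-base
boolean-mask oracles on toy chromosomes.

## Motif model and scanning

A PWM is an L × 4 column-stochastic matrix scored as log2(p/background)
summed over positions; N bases contribute 0 bits. The reverse strand is
scored by the reverse-complement matrix on the forward sequence, which
equals scoring the PWM on the reverse-complement — asserted as a strand-
duality test. The default hit threshold is 80% of each PWM's maximum
achievable score: with the synthetic PWM shape (one dominant base at 0.85
per column, L = 10) this admits zero mismatches from consensus and keeps
the random-sequence hit rate near 0.25^L per position, separating planted
from spurious hits cleanly. The threshold fraction and absolute bit
thresholds are configurable.

Enrichment uses presence/absence per site (not hit counts), a one-sided
Fisher exact test, BH correction over the library, and Haldane–Anscombe
+0.5 odds ratios when a cell is zero. Background sites that also appear in
the target set are excluded before testing. Composite motifs (heterodimer
sites) are ordinary library entries, not a special construct.

## Motif-pair geometry

Colocalization: observed = number of A-hits whose centre is within
`window_bp` (default 50) of some B-hit centre in the same peak — an
asymmetric count by design (swapping A and B changes the unit from A-hits
to B-hits). The null re-places only B's hits, uniformly within their own
peaks, preserving each peak's B-hit count: this conditions on
accessibility and per-peak hit abundance and asks only whether the
*relative placement* is closer than chance. Re-placing within peaks rather
than shuffling peak labels is a deliberate choice; the alternative answers
a different (co-occurrence) question and is easy to add on top of the same
hit tables.

Spacing: centre-to-centre distances of all same-peak A-B pairs (all-pairs,
not nearest-pair) in 1 bp bins up to 100 bp; self-pairs are excluded. The
periodicity statistic is the mean count on bins ≡ 0 (mod period) ± 1 bp
over the mean count elsewhere; the ±1 bp tolerance absorbs motif-centre
rounding. The permutation null resamples the same number of distances
uniformly over [0, max_dist]; because the statistic depends on the
distances only through the on-lattice total, each permutation reduces to a
binomial draw, making the test O(n_perm) regardless of pair count.
Histograms with fewer than 50 pairs are flagged underpowered (p = NaN)
rather than tested. All empirical p-values use the add-one convention
(1 + #{null ≥ obs}) / (n + 1), so p is never 0 and the minimal attainable
p is 1/(n + 1).

## Element-to-gene assignment

Priority order per element: (1) promoter — the element overlaps a promoter
window and is assigned to that gene directly; (2) chic — an interaction
whose bait overlaps ≥ 1 promoter window has its other end overlapping the
element; every bait gene is assigned, since capture baits genuinely
multi-map and the network tolerates multi-edges; (3) nearest — the gene
minimizing |element centre − TSS| on the same chromosome, ties broken by
lexicographically smaller gene id. Every element receives ≥ 1 assignment
and exactly one provenance; both properties are asserted at run time.
Interaction "presence" between samples requires both anchors (bait with
bait, other end with other end) to overlap by ≥ 1 bp (configurable).

## Differential expression

CPM per sample, log2FC on mean CPM with pseudocount 0.5, Welch t-test on
log2(CPM + 0.5) per gene, BH across genes, and the volcano classes
(up: log2FC > 1 ∧ p_adj < 0.05; down symmetric; else unchanged — the
class invariant is checked exhaustively in tests). The Welch-on-log-CPM
test is a transparent stand-in for the empirical-Bayes moderated linear
models commonly fitted to real RNA-seq; it forgoes variance shrinkage, so
at very small replicate counts or very low counts it is less powerful and
slightly less calibrated than those fits. At the regimes the tests use
(n = 5 per group, NB dispersion 0.1, baseline means ≥ 30) its null raw
p < 0.05 rate sits in the 3–7% band and sensitivity exceeds 0.9 at an
observed FDR below 0.1.

## Network assembly

Nodes are composite TF families; member TF genes, their mean CPM in the
AML condition (the node-colour value; the mean is the aggregation chosen
for multi-member families) and DE classes annotate each node. Edge
family → gene requires ≥ 1 hit of a family PWM in ≥ 1 element assigned to
the gene; the edge records the distinct (element, hit) support count, the
supporting element ids and the provenance mix. Edges are unsigned —
regulatory direction is never inferred. Referential integrity (every
supporting element assigned to the edge's target) is checked on every
build, and raising the scan threshold can only remove edges or support,
never add (tested). The default target universe is all genes; the core
(TF → TF) view is a filter on targets. A target counts as ChIP-"bound"
when one of its assigned elements or its promoter window overlaps a ChIP
peak.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the pipeline assumes:

* genome — i.i.d. bases at a configurable GC content (default 0.41),
  genes on evenly spaced jittered slots with non-overlapping promoter
  windows; default 4 × 1.5 Mb chromosomes, 200 genes.
* network — default 10 families × edge density 0.1 over 200 genes
  (≈ 200 edges); every family keeps ≥ 1 target at any density. PWMs are
  synthesized with one 0.85-dominant base per column and pairwise
  consensus Hamming distance ≥ L/2 so scanning separates families.
* peaks — default 500 per condition: half shared, half condition-specific;
  specific peaks carry the planted accessibility log2FC (default 2.0,
  split symmetrically across conditions) on negative-binomial tag counts.
  Accessibility uses its own dispersion (default 0.05) — merged-library
  ATAC tag counts are less dispersed than per-sample RNA-seq, and the
  expression default (0.1) would blur a 2-unit accessibility effect into
  the calling threshold. AML-specific elements sit 2.5–9.5 kb from their
  intended target's TSS, which makes the nearest-TSS fallback informative
  but fallible, as in real genomes.
* motif instances are embedded as the PWM consensus string (random
  strand). Sampling instances from the PWM columns would leave ~80% of
  planted instances below any threshold tight enough to keep random
  sequence quiet (one mismatch costs more bits than the 20% slack), so
  consensus embedding is what makes planted recovery a property of the
  pipeline rather than of luck. Geometry-controlled pairs of the two
  designated families are added with probability 0.4 per specific peak at
  lattice (period × 1..5) or uniform [0, 100] bp spacings; distances
  shorter than the motif length are skipped because two instances cannot
  physically co-occupy the sequence. Pair embeds register as planted
  network edges, keeping the manifest the single source of truth.
* interactions — exactly round(frac × n) elements (default 0.7) get a
  bait (TSS ± 500 bp of the target) / other-end (the element) pair; decoy
  interactions to random wrong genes are added at 5% of the true count,
  and attach only to already-linked elements so the linked/unlinked
  manifest partition stays exact.
* expression — negative-binomial (gamma–Poisson) counts, lognormal
  baseline means clipped at 30, per-sample library scale uniform in
  [0.7, 1.4], planted ±2 log2FC on 10% of genes (up-set drawn from network
  targets); dispersion 0 degenerates to Poisson.
* ChIP — each motif-bearing element becomes a peak with probability 0.8
  (default sensitivity); false peaks at 0.1 × the true count land in
  peak-free regions.

Not emulated: read-level noise (mappability, GC bias, duplicates), peak
width/shape variation, correlated fragile sites, linkage between
accessibility and expression beyond the planted network, genuine 3D
contact-frequency decay (interactions are constructed, not sampled from a
polymer model), and cross-sample biological variability. Passing tests
therefore demonstrate the pipeline's statistical machinery is correct and
calibrated under its stated assumptions — not that those assumptions hold
in any particular real dataset.

## Numerical and reproducibility choices

One RNG stream per output file, derived from the master seed via CRC-32 of
the stream name through a SeedSequence — regenerating one file never
perturbs another, and the end-to-end pipeline is hash-reproducible (tested
by running it twice). Negative-binomial draws use the gamma–Poisson
mixture with var = μ + φμ². Fisher p-values are exact (hypergeometric
tail, verified against an independent implementation to 1e-10). Zero
probability PWM cells map to a −1e9-bit penalty rather than −inf to keep
arithmetic finite. Degenerate inputs are flagged, not guessed at: empty
hit sets give p = 1 with a degenerate flag, empty modules give NaN
fractions, sub-50-pair spacing histograms give p = NaN.

## Problem sizes used in tests

The default fixture (4 × 1.5 Mb, 200 genes, 10 families, 500 peaks per
condition) is the standard recovery condition; assignment accounting uses
1000 distal elements at frac 0.7; ChIP validation uses single-family,
500-target modules (one element per target, so the bound fraction
estimates the planted sensitivity directly) over 20 seeds; DE uses 2000
genes × 5 replicates; geometry calibration uses 200 null datasets and
power 100 replicates at the planted regimes. These sizes give the
binomial bands quoted in the tests reasonable resolution while keeping the
whole suite fast on a single CPU.

## Known limitations

* The DE stand-in is not an empirical-Bayes fit; totals from real studies
  fitted with moderated models will not be reproduced exactly.
* Enrichment assumes sites are exchangeable between target and background;
  no GC- or width-matching of backgrounds is performed.
* The colocalization null conditions on per-peak hit counts; motif pairs
  whose co-occurrence (rather than spacing) is the signal need the
  peak-label-shuffling null instead.
* Nearest-TSS fallback ignores gene bodies and regulatory domains; with
  dense gene annotations its error rate rises accordingly.
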