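# coregrn

Gene-regulatory-network (GRN) inference from open chromatin, motif geometry
and promoter-capture interaction data, built for studies that contrast a
leukemic blast population (e.g. *CEBPA*-mutant AML) against normal
progenitors. The package implements the full analysis chain as a tested
library plus CLI, and ships a synthetic-data generator with planted ground
truth so every stage — and the pipeline end to end — can be validated
without any external downloads.

## What it computes

Given two-condition open-chromatin peak sets, a genome, a PWM motif library,
promoter-capture interactions (BEDPE) and expression counts:

1. **Chromatin contrast** — peaks are depth-normalized (tags per 10
   million), ranked by `log2((a + c) / (b + c))` of window counts, and
   partitioned into condition-specific (|log2FC| ≥ 1, boundary inclusive)
   and shared sites. Peak-set overlaps and signal-density matrices around
   ranked sites support the usual density-panel views.
2. **Motif scanning and enrichment** — PWMs are scored as log-odds bits
   against background on both strands (default threshold: 80% of each
   PWM's maximum score); enrichment of target vs background site sets uses
   presence/absence counts, a one-sided Fisher exact test and
   Benjamini–Hochberg correction across the library.
3. **Motif geometry** — two statistics for a motif pair: a bootstrap
   colocalization test (observed = A-hits with a B-hit within 50 bp in the
   same peak; null re-places B-hits uniformly within their own peaks) and a
   spacing-periodicity test (centre-to-centre distance histogram;
   lattice statistic = mean count on multiples of the period ±1 bp over the
   mean elsewhere; permutation null resamples distances uniformly). Both
   use add-one empirical p-values.
4. **Element-to-gene assignment** — distal elements are linked to genes
   through interactions whose bait overlaps a promoter window (TSS ± 2 kb)
   and whose other end overlaps the element; elements without interaction
   support fall back to the nearest TSS (ties broken lexicographically).
5. **Differential expression** — CPM normalization, Welch t-test on
   log2(CPM + 0.5), BH correction, and the volcano convention
   (up: log2FC > 1 and adjusted p < 0.05; down symmetric).
6. **GRN assembly and validation** — nodes are composite TF families (all
   TFs binding the same motif); an edge family → gene exists when an
   element assigned to the gene carries a hit of that family's PWM, with
   the motif count as edge weight and per-edge provenance. Modules
   (per-family target sets) are validated against ChIP peaks (a target is
   "bound" when one of its elements or its promoter overlaps a ChIP peak)
   and against DE classes. Export: GraphML, JSON graph, SIF, TSV.

The synthetic generator plants all of this: a TF-family → gene network with
separable PWMs, condition-specific peaks with a chosen accessibility
log2FC, embedded (consensus) motif instances including geometry-controlled
pairs, interactions covering a chosen fraction of elements (plus decoys),
negative-binomial expression with planted effects, and ChIP peaks at a
chosen sensitivity and false-peak rate. Every record carries a manifest
row, and one config + seed reproduces every output byte for byte.

## Worked example

```bash
printf 'spacing_mode: lattice\nn_peaks_per_condition: 500\n' > cfg.yaml
coregrn run --config cfg.yaml --outdir demo --seed 1
```

runs the whole pipeline on a synthetic dataset (4 × 1.5 Mb chromosomes,
200 genes, 10 TF families, 500 peaks per condition, 20 bp-lattice motif
pairs) and prints the recovery metrics it computed:

```
{
 "chip_bound_fraction_FAM00": 0.8666666666666667,
 "coloc_observed": 46,
 "coloc_p": 0.009950248756218905,
 "de_fdr": 0.09523809523809523,
 "de_sensitivity": 0.95,
 "grn_edge_precision": 0.9606557377049181,
 "grn_edge_recall": 0.9965986394557823,
 "grn_n_edges": 305,
 "interaction_cis_fraction": 0.9619565217391305,
 "n_elements_chic": 172,
 "n_elements_nearest": 76,
 "n_elements_promoter": 0,
 "spacing_p": 0.001996007984031936,
 "spacing_statistic": 38.958333333333336,
 "specific_peak_recall_aml": 0.976,
 "specific_peak_recall_normal": 0.984
}
```

Reading this: 97.6% of the planted AML-specific peaks were recalled at the
|log2FC| ≥ 1 threshold; 172 of 250 distal elements were assigned through
interactions and 76 through the nearest-TSS fallback; the assembled network
recovered the planted family → gene edges with precision 0.96 and recall
1.00; the planted 20 bp spacing lattice was detected at permutation
p ≈ 0.002 (statistic ≈ 39, i.e. on-lattice distance bins are ~39× denser
than off-lattice bins); DE classification reached 95% sensitivity at an
observed FDR below 0.1; and 87% of the validation family's network targets
were bound by its simulated ChIP peaks (planted sensitivity 0.8). `demo/`
holds every intermediate table (ranked contrast, hits, enrichment,
assignments, GraphML network, module validation) plus a provenance manifest
with per-file hashes.

The same stages are available piecemeal (`coregrn simulate`, `coregrn
chromatin rank|specific|overlap`, `coregrn motifs scan|enrich`, `coregrn
geometry coloc|spacing`, `coregrn link assign|share`, `coregrn expr de`)
and as plain library calls.

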