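# hic3state

Analysis of the three-dimensional epigenome across normal and cancer cell
lines from binned Hi-C contact maps: ICE normalization, TAD calling and
cross-cell-line TAD classification, histone-mark TAD-state annotation,
distance-stratified chromatin-loop significance, regulatory anchor
annotation, cell-type-specific enhancer–promoter loops, and their
expression consequences.  A synthetic-data module plants every structure
the pipeline looks for, so the whole analysis is verifiable end to end
without any external download.

The package is aimed at computational genomicists comparing chromatin
architecture between conditions — typically one normal and two cancer
lines profiled with in situ Hi-C, histone-mark ChIP-seq and RNA-seq.

## The models in brief

**Matrix balancing (ICE).** Raw intra-chromosomal contact counts `K_ij`
carry multiplicative per-bin biases. Iterative correction finds `b` with
`K_ij/(b_i b_j)` having equal row marginals (square-root-damped symmetric
scaling, tolerance 1e-4); bins below the 2nd percentile of coverage are
masked.

**TAD calling (diamond statistic).** At 40 kb resolution the boundary
signal of bin *i* is the mean of the w×w diamond between bins
`(i−w+1..i)` and `(i+1..i+w)` (w = 5). Local minima against a local linear
trend are candidate boundaries; each is retained when a one-sided rank-sum
test finds cross-boundary contacts depleted relative to within-side
contacts on the observed/expected scale (p < 0.05). TADs from three cell
lines are matched when both boundaries agree within 80 kb or the TADs
reciprocally overlap ≥ 80%; the three-way match logic yields common,
normal-specific and cancer-specific TADs, and a geometric rule detects
normal TADs split into ≥ 2 cancer TADs.

**TAD states.** A TAD is enriched for a histone mark (H3K36me3, H3K27me3,
H3K9me3, H3K27ac) when it intersects a top-ranked peak of that mark *and*
its mean signal is in the top quartile across TADs; the state label uses
the precedence H3K36me3 > H3K27me3 > H3K9me3. Gene-density classes:
desert (0 genes), poor (1–5), enriched (> 5). A 100-set random-TAD
empirical null tests whether mark-enriched TADs exceed chance, with the
add-one convention p = (1 + #{null ≥ obs})/101.

**Loop significance.** At 10 kb resolution, every intra-chromosomal bin
pair at 50 kb–10 Mb separation is tested against a distance-decay null:
the raw pair count `k` versus `X ~ Binomial(N, β_i β_j λ_d / N)`, where
`λ_d` is the per-distance expected count (isotonically smoothed,
non-increasing) and `β` is the decay-decoupled per-bin bias.  p-values are
BH-adjusted over all in-range pairs; q < 0.05 defines loops.  Anchors are
labeled sequentially promoter (±2 kb TSS of expressed genes) > enhancer
(top H3K27ac peaks > 2 kb from any TSS) > insulator (top CTCF peaks
overlapping neither) > other; enhancer–promoter (PE) loops present in both
cancer lines but absent from normal are cancer-specific, and vice versa.
Differentially frequent E-P loops are found with Fisher exact tests of
per-loop counts against chromosome-wide totals, and looped enhancers are
intersected with transcription-factor peaks to get the TF-bound fraction
and target genes.

**Expression.** RPKM = counts / (length/1e3) / (total/1e6); expressed
genes have mean log2(RPKM+1) > 1.5 across replicates; fold changes use a
pseudocount of 1 RPKM; group comparisons are Wilcoxon rank-sum tests
(exact by enumeration for small groups) with BH adjustment.

## Worked example

Simulate a three-line study (normal + two cancer lines, 2 chromosomes ×
20 Mb) and run the full pipeline:

```bash
hic3state run-all --outdir results/demo --seed 1
```

prints

```json
{"n_tads": {"normal": 57, "cancerA": 69, "cancerB": 70},
 "tad_classes": {"common": 129, "cancer_specific": 48, "normal_specific": 13, "other": 6},
 "n_loops": {"normal": 21, "cancerA": 32, "cancerB": 29},
 "ep_classes": {"normal_specific": 9, "cancer_specific": 16, "common": 11},
 "tf_bound_fraction": 0.3125}
```

so the cancer lines gained TADs (57 → ~70, reflecting planted TAD splits),
16 enhancer–promoter loops are cancer-specific, and 31% of the
cancer-specific looped enhancers are bound by the simulated transcription
factor.  `results/demo/tad_size_tests.tsv` holds the TAD-size comparison:

```
group_a            group_b          n_a  n_b  median_a  median_b  p            adj_p
common             normal_specific  129  13   720000    920000    0.00389925   0.00389925
common             cancer_specific  129  48   720000    480000    2.56326e-14  7.68978e-14
normal_specific    cancer_specific  13   48   920000    480000    0.000788667  0.001183
```

— normal-specific TADs (median 920 kb) are significantly larger than
cancer-specific TADs (median 480 kb), the signature of large normal
domains splitting in cancer.  Because the run is synthetic,
`results/demo/truth_comparison.json` scores every stage against the
planted ground truth (boundary recovery 94–98% with ≤ 2% spurious calls,
loop recovery 91–100%, cancer-specific E-P classification sensitivity
0.94 with zero normal-specific mislabels in this run).

The same stages are available individually (`hic3state simulate`,
`normalize`, `call-tads`, `compare-tads`, `call-loops`) and as library
functions (`hic3state.ice_normalize`, `call_tads`, `match_tads`,
`call_significant_loops`, `classify_ep_loops`, ...), reading and writing
HiC-Pro-style triplet matrices + bin BEDs, BED peak files, BEDPE loop
files and gene/expression TSVs.

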