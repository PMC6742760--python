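# Methods

This note documents the statistical models, defaults and numerical
choices behind `hic3state`, and what the synthetic-data generator does and
does not emulate.

## Data model and conventions

Coordinates are 0-based half-open everywhere in memory; BED/BEDPE are
written natively and any 1-based convention is converted at the boundary.
Contact matrices are symmetric and stored as the upper triangle;
bin id ↔ coordinate mapping always follows the companion bin BED file
(HiC-Pro dialect, 1-based ids on disk), never arithmetic on chromosome
sizes, so short terminal bins are handled exactly. Strand is carried on
genes only; peaks and loop anchors are strandless, because no analysis
step here is strand-dependent.

## ICE normalization

Iterative correction removes multiplicative per-bin bias by equalizing
row marginals. The update is the square-root-damped symmetric scaling
step `b ← b · (m/mean(m))^(1/2)` where `m` are the marginals of the
currently corrected matrix. The damping matters: the undamped step
oscillates between two fixed points on symmetric matrices and stalls
around 1e-2 relative deviation, while the damped step converges
geometrically (≈ 20 iterations to 1e-6 on a 4,000-bin matrix). Defaults:
tolerance 1e-4 on the maximum relative marginal deviation, 200 iterations
maximum, bins below the 2% quantile of positive marginals masked (bias
NaN, entries dropped downstream). The returned bias has mean 1 over
unmasked bins.

One consequence worth understanding: on a *bias-free* finite chromosome
the ICE bias is not 1. Expected marginals fall off toward chromosome
ends (a center bin has close partners on both sides), so balancing
absorbs a smooth positional profile `u_i` and the ICE vector estimates
`b_i · u_i`, not `b_i`. `loops.decoupled_bias` divides out `u`, obtained
by balancing the distance-decay kernel itself, and is the quantity to
compare against a planted bias (r > 0.999 on a dense matrix; the raw ICE
vector caps near 0.988 at any depth).

## Distance decay

The decay profile is the distance-stratified expected contact
probability: for stratum *d*, `p̂_d = (Σ counts at d)/(N_total · M_d)`
with `M_d` the number of unmasked locus pairs at that distance,
zero-count pairs included — the correct null denominator for sparse
matrices. Strata are exact per-bin-distance up to 1,024 bins (which
covers the whole 50 kb–10 Mb loop window at 10 kb) and log-spaced (step
1.08) beyond. We deliberately do not pool nearby distances inside the
main window: at high sequencing depth the expected count varies across a
pooled stratum by more than the Poisson standard deviation, which makes
pooled nulls anti-conservative at the near edge of each stratum. The
profile is made non-increasing by weighted isotonic regression (weights
`M_d`), which also fills empty strata from their neighbours and preserves
the normalization identity `Σ_d p̂_d · M_d = 1`.

## Loop significance

Loops are called at 10 kb on intra-chromosomal pairs separated by
50 kb–10 Mb (q < 0.05). The test statistic is the *raw* pair count —
Poisson by construction — against a two-factor expected model

```
μ_ij = β_i · β_j · λ_d ,    p = P(X ≥ k),  X ~ Binomial(N_raw, μ_ij/N_raw)
```

with `β` the decoupled per-bin bias (above) and `λ_d` the per-stratum
expected raw count re-estimated with `β` weights and isotonic smoothing.
Two alternatives were evaluated and rejected on calibration grounds,
measured on synthetic data with planted log-normal bias (sd 0.3):

* testing rounded *normalized* counts against a flat binomial null
  inflates the variance of pairs whose bins have small bias (normalized
  counts are Poisson scaled by `1/(b_i b_j)`), producing empirical FDRs
  near 100%;
* using the raw ICE bias per pair (without decoupling the positional
  factor) mis-scales expectations near the diagonal, inflating z-scores
  severalfold at short range.

With the two-factor model, null p-values over 1.4 million pairs are
uniform to Kolmogorov–Smirnov distance ≈ 0.013 on a deep structure-free
matrix, and seeded null runs at the study depth call zero loops in
≥ 18/20 runs. p-values are Benjamini–Hochberg-adjusted with the family
size equal to *all* in-range pairs (zero-count pairs enter the
denominator as implicit p = 1 tests).

Calibration is assessed in two regimes on purpose: the KS-uniformity
check runs on a deep matrix (expected counts ≳ 100 across the whole
window) because binomial tail p-values are discrete and only approach
uniformity in the large-count regime; the false-call and FDR checks run
at the default study depth, where discreteness makes the test
conservative — the direction one wants in production.

## TAD calling

TopDom-style, at 40 kb, window w = 5, boundary p < 0.05. The boundary
signal of bin *i* is the mean of the w×w diamond spanning the putative
boundary, truncated at segment edges. Candidates are local minima of the
signal judged against a least-squares linear trend over ±w bins (strict
inequality, so flat signal yields no candidates). Each candidate is
tested by a one-sided Mann–Whitney comparison of cross-boundary diamond
entries versus pooled within-side upper-triangle entries, computed on
**observed/expected** values (each entry divided by the segment's mean
count at its bin distance). The O/E scale is essential: cross-boundary
entries sit at larger genomic distances than within-side entries, so on
raw counts distance decay alone drives the one-sided test to
significance at every candidate once matrices are deep — measured ~40%
spurious boundaries versus ~3% on O/E. Masked bins break chromosomes
into segments processed independently; domains shorter than 2 bins are
dropped. When scoring against planted truth, domain edges abutting
masked bins are excluded from the spurious count and planted boundaries
falling in masked bins are excluded from the recovery denominator — a
coverage gap is neither a boundary claim nor an observable boundary.

## TAD matching, classes and splits

Two TADs match when both boundary shifts are ≤ 80 kb (two 40 kb bins) or
when their reciprocal overlap is ≥ 80% of *both* lengths — the
reciprocal reading prevents a small TAD from matching a containing large
one, which would contradict the size analyses. Best matches maximize the
minimum reciprocal-overlap fraction, ties broken by coordinate. A TAD is
*common* when it sits on a chain matched across all three lines (its two
partners also match each other), *normal-specific* when a normal TAD is
unmatched in both cancer lines, *cancer-specific* when a cancer TAD
matches the other cancer line but not normal, else *other*; every TAD
gets exactly one label. A normal TAD is *split* when ≥ 2 cancer TADs
each lie ≥ 80% of their own length inside it and jointly cover ≥ 80% of
it. Size comparisons use two-sided rank-sum tests (exact enumeration for
group sizes summing to ≤ 16) with BH adjustment.

## TAD states and the random-TAD null

Peaks are ranked by score and the top `min(30000, ⌈25%⌉)` retained —
honouring both the absolute and the fractional clause when peak totals
differ. A TAD is enriched for a mark iff it intersects ≥ 1 top peak
*and* its length-weighted mean signal is at or above the 75th percentile
of per-TAD means for that mark; when several marks are enriched the state
label follows H3K36me3 > H3K27me3 > H3K9me3 (the active mark wins; raw
flags are kept alongside so no information is lost). The random-TAD null
generates 100 seeded sets of contiguous intervals with sizes uniform in a
range, recomputes the enriched count per set with the same rule, and
reports the add-one empirical p `(1 + #{null ≥ obs})/101`, which cannot
reach zero and matches the "< 0.01 at 100 shuffles" reporting convention.
At pipeline level the size range is scaled to the observed mean
enriched-TAD size (ratios 280/350 and 440/350 of it) so null sets are
comparable in cardinality to the real ones regardless of the genome's
TAD scale; the operation's own default range stays (280 kb, 440 kb).

## Regulatory sets, anchors and E-P loop classes

Element sets are sequential by construction: promoters are ±2 kb TSS
windows of expressed genes; enhancers are top-25k H3K27ac peaks whose
interval lies > 2 kb from *any* annotated TSS (not only expressed ones);
insulators are top-50k CTCF peaks overlapping neither. Anchors are full
10 kb bins; an anchor takes the first label in P > E > I > O whose
element set it overlaps by ≥ 1 bp, and the loop category is the
unordered label pair. For per-element loop-fate fractions a multi-looped
element is assigned once by partner priority E > I > P > O, so the
fractions partition each element class.

Loops are matched across lines by exact anchor-bin equality (the
conservative, deterministic choice; no tolerance is defined by the
matching rule upstream). "Present" means called significant in a line;
the E-P category is required in the line(s) that define each class:
normal-specific (E-P in normal, absent from both cancers),
cancer-specific (E-P in both cancers, absent from normal), common (E-P in
all three). Differential E-P loop tests build, per cancer line, the 2×2
table of the loop's raw count versus the line's total in-range
intra-chromosomal contacts, Fisher-exact two-sided with BH across loops;
a loop is differential when both cancer-vs-normal comparisons pass.
The anchor-shuffle null places the same number of non-overlapping
artificial 10 kb anchors uniformly on the chromosome-1 grid, 100 times,
seeded, and reports add-one empirical p per element type.

## Expression

RPKM is counts/(length/1e3)/(total/1e6). Expressed: mean log2(RPKM+1)
over replicates strictly greater than 1.5. Fold change is
`(mean RPKM_cancer + 1)/(mean RPKM_normal + 1)` — the pseudocount keeps
genes silent in normal finite. Differential expression is a Welch t test
on log2(RPKM+1) with BH adjustment (a deliberately simple, documented
test; up-regulated means fold change strictly > 2 and adjusted p < 0.05).
Gene-set comparisons are two-sided rank-sum tests on log2 fold changes
with BH across the comparisons of a report; group sizes summing to ≤ 16
use exact enumeration over all assignments with midranks.

## Exact small-sample statistics

Fisher exact p is the sum of hypergeometric point probabilities not
exceeding the observed one (relative tolerance 1+1e-7), computed
vectorized over tables; it agrees with full enumeration on every 2×2
table with N ≤ 50 and with `scipy.stats.fisher_exact` on random tables.
Benjamini–Hochberg is the step-up formula, with an optional family size
larger than the p-vector for families containing implicit p = 1 members.

## The synthetic generator

The generator defines the study conditions; all downstream checks read
its serialized ground truth rather than re-deriving it.

* **Contacts.** Expected count for a pair at bin distance *d*:
  `C·(d+1)^(−α) × tad_boost^[same planted TAD] × loop_boost^[planted
  anchor pair] × b_i·b_j`, Poisson-sampled; `C` is set so each
  chromosome's total matches the configured depth. Defaults: 2
  chromosomes × 20 Mb, 10 kb fine / 40 kb coarse bins, α = 1.0,
  tad_boost 2.0 (a typical within-TAD contact enrichment), loop_boost
  5.0 applied at exactly the anchor pair (making recovery unambiguous),
  depth 2×10⁶ contacts per chromosome (a deep in situ Hi-C study scaled
  to 20 Mb), log-normal bias sd 0.3 shared across conditions. These
  defaults come from a power analysis of the planted model: with a
  single global decay null, a much deeper matrix or a sharper uniform
  TAD block makes ordinary within-TAD pairs exceed the BH threshold,
  which no single-pass distance-decay caller can avoid; at these
  settings planted loops are recovered at ~94% with ~7% empirical FDR.
  `depth_for_diagonal_mean` converts a target 40 kb diagonal mean (e.g.
  ~100 for the TAD recovery experiments, where tad_boost 3 is used) into
  a depth.
* **TADs and states.** 25 TADs per chromosome (minimum 200 kb, mean
  800 kb); the 5 largest are split at their coarse midpoint into two
  cancer TADs shared by both cancer lines (no cancer–cancer boundary
  jitter — a simplification). States are drawn per TAD (18% H3K36me3,
  18% H3K27me3, 14% H3K9me3, 50% other — fractions kept under the 25%
  signal-quantile cap so planted states are recoverable); 25% of
  non-split H3K27me3 TADs flip to H3K36me3 in cancer.
* **Loops.** Anchor pairs 50–300 kb apart inside single TADs, in three
  classes (common / normal-specific / cancer-specific; 6/5/8 per
  chromosome). Each loop designates a promoter anchor (hosting an
  expressed gene's TSS at the bin center) and an enhancer anchor (kept
  clear of any TSS so the sequential scheme labels it E, with a
  condition-specific high-score H3K27ac peak).
* **Annotations.** Mark peaks concentrate in their state's TADs with
  top scores; low-score background peaks avoid anchor bins. CTCF peaks
  sit at TAD boundaries and loop anchors plus background; NDRs nest
  inside every planted H3K27ac peak; TF peaks bind a fixed 35% of
  cancer-specific looped enhancers (cancer conditions only). Signal
  tracks are 10 kb-binned noise floors elevated inside enriched TADs.
* **Expression.** Three replicates per condition, log-normal noise
  sd 0.25 (log2 scale); expressed baselines uniform in log2(RPKM+1) ∈
  (2.2, 5.0), silent ones in (0, 0.8) — the gap at the 1.5 threshold
  avoids classification flakiness; genes at cancer-specific loop
  promoter anchors get a 4× RPKM effect in both cancer conditions.

What the generator does *not* emulate: read-level noise, A/B
compartments, nested/hierarchical TADs, inter-chromosomal contacts,
copy-number structure, distance-dependent bias, replicate Hi-C
libraries, or realistic peak-shape/width distributions. Passing tests
therefore demonstrate correctness of the algorithms under the planted
generative model, not performance on real tissue data — in particular
real loop calling inherits the well-known sensitivity of decay-null
methods to domain structure discussed above.

## Determinism and reproducibility

All randomness flows from one root seed through named substreams
(`SeedSequence([seed, stage, condition])`), so matrices, annotations,
expression, shuffle nulls and random-TAD sets are reproducible
independently of execution order. Pipeline outputs are written with
fixed float formatting; an identical config + seed reproduces every
tabular output byte for byte. The run manifest records parameters,
per-stage counts, wall times and output checksums.

## Problem sizes

The shipped experiments use 2 chromosomes × 20 Mb (4,000 fine bins,
~1.4–2.9 million tested pairs per run), 20-seed replications for the
loop calibration claims, and a deep single-chromosome matrix for the
continuous-regime calibration check; the full synthetic study (three
conditions end to end) runs in well under a minute on one CPU.

## Known limitations

* The loop caller is single-pass: the decay null is estimated once from
  the full matrix, so within-domain enrichment mildly inflates the null
  and residual false calls concentrate inside TADs (~7% empirical FDR at
  the default conditions).
* `classify_ep_loops` requires exact anchor-bin equality across lines;
  loops shifted by one bin between lines are treated as different.
* The expression test is a two-group Welch t test; it does not model
  library-specific dispersion.
* Random-TAD and shuffle nulls tile/place intervals uniformly; they do
  not preserve chromatin-state composition of the real sets.
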