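# Methods

This note records the models, estimators, parameter choices and known
limitations behind `methylreg`, in the order the pipeline applies them.

## Data model and input handling

A methylome is a per-cell-line set of CpG sites, each the C of a CG
dinucleotide on the forward strand, with a methylated-read count and a total
count; the methylation level is their ratio. Sites covered by fewer than
`min_coverage` reads (default 5, i.e. more than 4 reads required) are dropped
at read time — array-derived tables converted to the count dialect pass
through the same filter only when counts are present. CpG methylation is
strand-symmetric, so an optional merge mode sums counts reported separately
at the C and G positions onto the C. All coordinates are 0-based half-open;
the position column of methylation tables can be declared 0- or 1-based.
Overlapping input regions are kept as-is: no merge rule is imposed.

## Matched background sampling

Each positive region is reduced to a relative coordinate: the context of its
midpoint (upstream window / exon / intron of its target gene) and the
distance to the context anchor normalised by the context length — (transcript
span + 10 kb) for the upstream context, element length with distance to the
*nearest* boundary for exons and introns. The target gene is the gene whose
body contains the midpoint, else the nearest gene downstream within 10 kb.
Backgrounds of identical length are placed at the same relative coordinate in
a uniformly drawn host gene, rejection-sampled (max 50 attempts per
replicate) against (a) overlap with any positive, (b) context change, and
(c) |Δ rel_dist| > 0.01 after integer rounding. Sampling across host genes
rather than within the source gene avoids exhausting placements; backgrounds
may overlap each other, which is harmless for frequency estimation and
deliberate — forbidding it would bias the pool toward sparse genes. A
positive whose relative distance cannot be realised in most hosts (its
distance exceeds the upstream window under a larger normalising length) can
lose replicates; this is logged, and the classifier's 1:1 negative set takes
one background per positive from whatever pool exists.

## Features

1. **Mean methylation** — unweighted mean level of the region's mCpGs in the
   reference (first) methylome. Regions with no covered mCpG are dropped.
2. **Methylation variance** — per site, the population variance (divisor n)
   of its level across the cell lines where it passes coverage; sites seen in
   fewer than two cell lines are excluded rather than zero-filled; the region
   value is the mean over remaining sites, imputed to 0 with a flag when no
   site qualifies.
3. **Autocorrelation (per region)** — the mean over within-region mCpG pairs
   (distance ≤ 2000 bp) of (x_i − x̄)(x_j − x̄)/s², with x̄ and s² pooled over
   the *entire* region set being featurised, never per label stratum (pooling
   per stratum would leak the labels into the feature). A consequence worth
   knowing: when positives carry many more mCpGs than backgrounds, the
   site-weighted pooled mean sits near the positive level, so background
   regions acquire large positive deviation products and the feature's class
   separation can point either way. It remains strongly discriminative (the
   SVM is indifferent to sign), but its direction is a property of the data
   composition, not of the biology. Regions with fewer than two in-range
   sites are imputed to 0 with a flag.
4. **CpG density** — CG dinucleotide count divided by region length ("CG"
   cannot overlap itself); CG content (fraction of C+G bases) is computed by
   the same machinery for composition reports.
5. **Motif score** — mean over the region's mCpG-anchored 8-bp windows of
   −log10 of the window motif's raw over-representation p-value, floored at
   1e-300. Windows may extend past the region boundary (motifs *surround*
   mCpGs) but not past the chromosome; windows with non-ACGT bases are
   skipped; windows are anchored on covered mCpGs, not on all genomic CpGs.

### Pooled autocorrelation profile

The profile r(k) over a region set divides the summed deviation products of
within-region pairs in each distance bin by the summed squared deviations of
all sites, deviations taken around the grand mean over all supplied regions.
Distances are binned: self-pairs form the lag-0 bin (so r(0) = 1 exactly —
the denominator is accumulated from the identical per-region partial sums),
and distance d ≥ 1 falls in the bin labelled by its right edge,
(k−1)·w < d ≤ k·w, default w = 10 bp. Bins with fewer than 30 pairs are
suppressed. The extent of autocorrelation is the smallest positive reported
lag with r ≤ 0.05; when r never reaches the threshold the profiled maximum
lag (default 2000 bp) is returned with a censored flag. Note the estimator is
pair-density dependent: for a dense, regularly spaced series it estimates the
lag-k correlation, but when a bin holds far fewer pairs than there are sites
its r is shrunk toward zero accordingly.

## Motif enrichment

The motif universe is the 2080 canonical centered-CpG 8-mers ((4⁶ + 4³)/2
after collapsing reverse complements; the canonical form is the
lexicographic minimum). Every covered mCpG contributes one window placing the
CG at offsets 3–4. The over-representation p-value is the strict upper tail
P(X > k) of Binomial(n_fg, p_bg); under-representation uses the mirrored
strict lower tail P(X < k). p_bg is the motif's frequency in the full
background pool (all replicates, not the 1:1 subsample), computed per region
class. Two numerical guards: a zero foreground count is never called
over-represented, and a motif absent from the finite pool is tested against
the smallest nonzero estimate 1/bg_total — at p_bg = 0 the printed formula
declares any single occurrence infinitely significant, which is a sampling
artefact, not evidence. Both tails are Bonferroni-corrected with n_tests =
2080 (the enumerated universe, not the observed motifs), and the significance
threshold (default 1e-5) applies to the corrected p-value, with a flag to
apply it to the raw p-value instead. The strict inequality (P(X > k), not
P(X ≥ k)) follows the enrichment formula as printed; for the counts at which
calls are made the difference is far below the threshold.

To keep cross-validation honest, the motif table entering the motif-score
feature is rebuilt inside every training fold from that fold's positive
regions (per-region window k-mers are precomputed once, so a rebuild is an
aggregation). The genome-wide exploratory table written to `motif_table.tsv`
is built once on all data and is not used for classification. At desk scale
the full-data score also carries a *self-enrichment* bias — a region's own
windows inflate the counts it is scored against — which the per-fold rebuild
removes; analyses outside CV that need unbiased scores should cross-fit, as
the feature-ranking tests do.

## Classification and feature ranking

The classifier is an SVM with an inhomogeneous polynomial kernel
(γ·x·y + 1)², misclassification cost C = 10, on features standardised to zero
mean and unit variance with training-fold statistics only. The kernel
constant matters: with zero-centred features the homogeneous degree-2 kernel
(coef0 = 0) is an even function, blind to the sign of every feature, and a
single-feature model collapses to chance — the constant term restores the
linear directions and is exposed as a parameter. Folds are stratified (both
classes in every fold), deterministic given the seed; the headline AUC is
computed on the decision scores pooled across held-out folds and equals the
Mann-Whitney probability that a random positive outscores a random
background (ties half); per-fold AUCs are reported alongside. Feature
importance is the information gain of the labels given the feature after
equal-frequency discretisation into 10 bins (quantile cut-points, ties to the
lower bin, constant features collapse to one bin and zero gain).
`RegulatoryRegionModel.fit()` returns a results object carrying the pooled
and per-fold AUCs, the ROC points, the IG ranking and a `summary()` table.

## Synthetic data generator

The generator emulates the statistical structure of regulatory methylomes;
it makes no attempt at realistic human sequence composition, annotated CpG
islands, or histone tracks, so passing tests demonstrate estimator
correctness and pipeline power under the modelled signal, not performance on
real genomes (real data add alignment artefacts, coverage inhomogeneity,
sub-CpG-island structure and correlated cell-line ancestry that the model
omits).

Layout: genes tiled on 4 chromosomes, each 4 exons of 1 kb with introns
uniform on 2–6 kb, a 10 kb upstream window and 4 kb intergenic gaps; strands
random. Regulatory regions (uniform length 400–800 bp) sit in distinct host
genes: promoter-class in upstream windows, enhancer-class inside introns.

Sequence: i.i.d. bases with every natural CG erased (C,G→C,T), then CG
dinucleotides planted at the configured densities — 0.05 inside regulatory
regions vs 0.01 outside for the promoter scenario (a CpG-island-like
contrast), 0.02 vs 0.01 for enhancers — so density is controlled exactly.
Around a fraction of regulatory CpGs (default 0.25, drawn per CpG so small
rates are honoured) an 8-bp GC-box-like motif (GGGCGGGG or the palindrome
TTGCGCAA, random orientation) overwrites the window; only CpGs isolated by
more than 7 bp are eligible and junctions are repaired, so planting neither
creates stray CpGs nor bleeds into neighbouring windows.

Methylation: latent level = background mean − dip + switching term +
spatially correlated noise, clipped to [0,1]. The dip is Gaussian-shaped
around the region centre with half-width 750 bp, so hypomethylation relaxes
to the background plateau ≈1.5 kb out; its depth targets a regulatory mean
of 0.34 against background 0.72 (promoter scenario) or 0.69 against 0.84
(enhancer), jittered per region by ±10% (promoter) or ±80% (enhancer) to
model heterogeneous element strength — the wide enhancer jitter is what
keeps mean methylation alone a weak enhancer predictor, as observed in real
data. Noise is a distance-decaying AR(1) field (exponential kernel, sd 0.12)
with correlation length 120 bp inside promoter-scenario regions (80 bp for
enhancers) and 15 bp elsewhere, chosen from the closed-form extent
L·ln(r₀/0.05) to put regulatory extents in the hundreds of bp and background
extents near 40 bp. Each region is active in the reference cell line and
switches off in any other with probability 0.4; inactive regions gain +0.08
(hypermethylated *above* background, not merely relaxed). Observed counts
are Binomial(depth, latent) at depth 5 + Poisson(25), so the coverage filter
is exercised without losing sites. Expression is RPKM =
max(0, 20 − 15·(regional mean methylation) + N(0,2)) for genes targeted by a
regulatory region and background noise otherwise, giving the strong negative
methylation–expression coupling expected of functional regulatory calls.

All parameters live in a frozen `GeneratorConfig`; the seed fully determines
every output file.

## Problem sizes

Tests and the acceptance suite run everything at desk scale, chosen as the
smallest sizes at which the contrasts are comfortably resolved: scenario
classification uses 500 positives + 500 matched backgrounds over 5 cell
lines with a 20× background pool; parameter recovery uses 250 regions over
the full 15 cell lines; planted-motif recovery uses 600 regions with a 50×
pool, equal foreground/background CpG density (so the planted motif is the
only compositional difference — with a density contrast, CG-rich flank
motifs are *genuinely* enriched, exactly as real promoters enrich GC-rich
words), and a planting rate of 10/2080 ≈ 0.5% (ten times the uniform
background rate). Background pools of at least ~20 replicates per region
matter for the motif test: the 2080-motif universe needs enough background
windows that per-motif frequencies are estimable.

## Known limitations

* The per-region autocorrelation feature conflates mean offset with local
  correlation under site-count imbalance (see Features above).
* The binned profile's r depends on pair abundance relative to the site
  count; extents from sparse region sets are resolution-limited by the bin
  width and the min-pairs filter.
* Background sampling can under-fill the pool for positives at extreme
  relative distances; counts are logged and the manifest records them.
* The generator's activity states are independent across cell lines and
  regions; real cell lines share lineage, which would correlate switching.
* No position-weight-matrix matching of enriched motifs to transcription
  factor consensus sequences; motifs are reported as raw 8-mers.
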