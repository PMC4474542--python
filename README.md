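# methylreg

Predicting promoters and enhancers from DNA-methylation-derived features.

Regulatory regions leave a characteristic footprint in whole-genome bisulfite
data even before any histone mark is measured: their mCpGs are deeply
**hypomethylated**, the hypomethylation **extends over > 1 kb**, neighbouring
mCpG levels are **correlated over hundreds of bp** (tens of bp elsewhere),
**CpG density** is elevated, methylation **varies strongly across cell lines**
(regions inactive in one cell line are *hyper*methylated relative to
background), and GC-rich **centered-CpG 8-mers** are enriched around the
mCpGs. `methylreg` turns these observations into a classifier: five per-region
features computed against relative-position-matched random backgrounds, a
polynomial-kernel SVM under stratified 10-fold cross-validation, and an
information-gain ranking of the features. It is aimed at computational
epigenomicists who have per-CpG methylation tables (bisulfite or array-derived)
for one or more cell lines and candidate regions to classify.

## The model

For a region set R with mCpG levels x_i and grand mean x̄, the methylation
autocorrelation at genomic distance k is

    r_k = Σ_{pairs at distance k} (x_i − x̄)(x_j − x̄) / Σ_{all sites} (x_i − x̄)²

binned at 10 bp; its *extent* is the first lag where r ≤ 0.05. Each region is
summarised by the feature vector

    ( mean methylation,
      mean across-cell-line variance (population convention),
      mean standardised pair product (x_i − x̄)(x_j − x̄)/s² within the region,
      CpG density = #CG / length,
      mean −log10 p of the centered-CpG 8-mers around its mCpGs )

Motif enrichment is a strict upper-tail binomial test, p-value =
1 − Σ_{i≤k} C(n,i) pⁱ(1−p)^{n−i} with p estimated from the background pool,
Bonferroni-corrected over the 2080 canonical centered-CpG 8-mers (a word and
its reverse complement count as one motif). Backgrounds are sampled at the
same *relative* genomic position as each positive — same distance to the TSS
normalised by (transcript span + 10 kb), or to the nearest exon/intron
boundary normalised by the element length — so location effects cancel.
Feature importance is the information gain IG(S,F) = H(S) − Σ_v |S_v|/|S| H(S_v)
after equal-frequency discretisation.

A first-class synthetic-data generator (`methylreg.simulate`) emits genomes,
annotations, multi-cell-line methylomes and expression tables with exactly
these statistical signatures, so the whole pipeline runs and is tested with
no downloads.

## Worked example

```sh
methylreg run-all --preset enhancer --seed 7 --out results/enhancer_demo
```

simulates an enhancer-like dataset (100 regions, 15 cell lines), samples 20
position-matched backgrounds per region, extracts features, rebuilds the
motif table inside every training fold, and prints:

```
AUC 0.993; manifest at results/enhancer_demo/manifest.json
```

with `summary.txt` containing:

```
Regulatory region classification (SVM, polynomial kernel)
==========================================================
regions: 200  (positives 100, backgrounds 100)
kernel degree: 2   C: 10.0   folds: 10   seed: 7
features: mean_meth, meth_variance, autocorr, cpg_density, motif_score
----------------------------------------------------------
AUC (pooled held-out scores): 0.993
AUC per fold: mean 0.991 (min 0.910, max 1.000)
----------------------------------------------------------
information gain (bits):
  motif_score     0.943
  meth_variance   0.512
  cpg_density     0.455
  mean_meth       0.327
  autocorr        0.056
```

The AUC of 0.993 says a random enhancer outscores a random matched background
99.3% of the time; the information gains say the motif enrichment and the
across-cell-line variance carry most of the signal in this scenario, while
mean methylation alone is a weak predictor — the reason the extra features
exist. The run also writes `roc.tsv`, `feature_table.tsv`, `motif_table.tsv`,
`feature_ig.tsv` and a `manifest.json` whose per-stage record counts must
reconcile. `methylreg predict` runs the same analysis from your own BED +
methylation TSV + FASTA + annotation files; `methylreg simulate` writes a
synthetic dataset to disk; `methylreg motifs` and `methylreg sample-background`
expose the individual stages.

As a library:

```python
from methylreg import RegulatoryRegionModel
model = RegulatoryRegionModel.from_feature_table(feature_frame)  # from io.feature_frame
results = model.fit(folds=10, seed=7)
print(results.summary())
```

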