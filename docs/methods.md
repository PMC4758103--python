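# Methods

This note documents the models and procedures implemented in `cellqc`,
the assumptions behind them, the parameters that matter, and the
numerical choices made where the design was genuinely open.

## Normalization

Each cell is normalized independently by dividing its gene values by the
cell's total over non-ERCC genes, so non-ERCC proportions sum to 1 per
cell. Reference-based size factors (DESeq-style) are deliberately
avoided: they couple a cell's normalization to the rest of the dataset,
which would make a classifier's output depend on which other cells
happen to be present at prediction time. ERCC rows are carried through,
divided by the same denominator, so spike-in fractions remain
interpretable. TPM input goes through the same division (on a complete
TPM matrix this equals TPM/1e6). Cells with a zero endogenous total are
zeroed and flagged rather than dropped, so downstream feature extraction
never sees missing values.

## Features

**Biological.** One feature per gene set: the summed normalized
expression of member genes — the fraction of the cell's library in that
functional category. Sets are scored independently; overlaps are
allowed. Membership is exact string matching of gene IDs; callers must
supply gene sets in the same namespace as the matrix. A set with no gene
in the matrix scores 0 with a warning rather than failing, so a
template GMT can be applied across annotations.

**Technical.** Ratios are conditioned on the relevant universe: mapped,
multimapped and unmapped rates use total reads as denominator;
non-exonic and duplicated rates use mapped reads; the spike-in ratio is
ERCC reads over exonic reads. Zero denominators impute 0 and flag the
cell. Expression-shape features:

* `n_detected_genes` — non-ERCC genes with count > 0;
* `n_genes_bin1..5` — detected genes whose per-cell CPM falls in
  (0,1], (1,10], (10,100], (100,1000], >1000. Fixed decade boundaries
  are used (rather than dataset quantiles) so the feature transfers
  between datasets and is deterministic;
* `transcriptome_variance` — variance across non-ERCC genes of
  log10(normalized + 1e-6); the log stabilizes the otherwise
  mean-dominated scale, and 1e-6 sits well below any plausible
  normalized expression value of interest;
* `cell_to_mean_correlation` — Spearman correlation between the cell's
  normalized vector and the across-cell mean profile, over genes
  detected in at least one cell. Rank correlation is used because
  expression is heavy-tailed; a Pearson version would be driven by a
  handful of top genes;
* `n_high_var_high_expr` — detected members of the dataset-level set of
  genes with mean above the across-gene median **and** positive
  distance-to-median (DM, below). The thresholds (median, DM > 0) are
  parameter-free; absolute cutoffs would not transfer across depths.

`total_reads` is extracted but excluded from the default common set, as
are detected-gene counts — both depend on the experimental setting.

## Distance-to-median (DM)

For genes with positive mean over the chosen cells, CV² = s²/m² (sample
variance, ddof 1). Genes are ordered by log10(mean) and DM is
log10(CV²) minus a centered rolling median of log10(CV²) (window 50
genes by default, shrinking at the edges). The rolling median removes
the mean–variance trend, making DM a mean-independent noise measure;
its median is ~0 by construction. Genes with zero mean or zero CV² are
excluded and reported. The window is the only tunable; 50 genes is wide
enough to be stable and narrow enough to track the trend on a few
thousand expressed genes.

## Gene-set statistics

For each gene set, LOW and HIGH cells are compared with a two-sided
*paired* t-test, pairing by gene: once on per-gene mean normalized
expression, once on per-gene DM computed within each class separately
(genes with undefined DM in either class are excluded). P-values are
adjusted across sets (Benjamini–Hochberg by default; Bonferroni
selectable). Signed −log10 p values (sign of t; positive = higher in
LOW cells) are reported for plotting. Degenerate cases: all-zero paired
differences give t = 0, p = 1 (identical classes carry no signal);
zero-variance but nonzero differences are reported as undefined with a
warning rather than as an infinitely significant result.

Fisher's exact test (hypergeometric, default one-sided "greater") tests
whether annotated cells are enriched among outlier-flagged cells.
Degenerate 2×2 tables (an empty margin) return p = 1 with a warning.

## Accuracy metrics

LOW is the positive class. Sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP), accuracy = (TP+TN)/N,
F_β = (1+β²)TP / ((1+β²)TP + β²FN + FP), and MCC with the convention
that a zero marginal gives 0. β defaults to 2: in QC, a missed broken
cell (false negative) contaminates downstream analysis, while a
discarded good cell merely costs data, so recall of LOW cells is
weighted up. Degenerate denominators (no positives in truth or
prediction) return 0 rather than NaN so metric grids are total.

## Common-feature selection

Features are standardized (mean 0, variance 1, ddof 1; constant
features flagged and left at 0) and decomposed by full-SVD PCA.
Component signs are fixed (largest-|loading| entry positive) so results
are bit-reproducible. On a multi-cell-type table the first two
components encode cell-type identity; features driving them are
removed.

The removal rule: pool the PC1 and PC2 loading values, take the pooled
range, and remove any feature whose PC1 or PC2 loading lies strictly
below min + q·range or strictly above max − q·range (q = 0.25 by
default). Cutoffs as a fraction of the loading *range* — rather than
empirical quantiles of the loading values — are essential: empirical
quantiles remove a fixed ~2q fraction of features per component no
matter how the loadings are distributed, so they would discard
type-independent features whose loadings are near zero. Range-based
cutoffs remove only features that actually stretch toward the extremes.
Pooling PC1 and PC2 before computing the range keeps a
noise-dominated second component from ejecting mid-range features.
Boundary values exactly at a cutoff survive. Finally, an exclude list
(default: `total_reads`, `n_detected_genes`) drops features tied to the
experimental setting. Removing every feature is an error that suggests
a smaller q.

## Outlier detection

Cells are scaled, projected onto the top `n_components` principal
components (default 2), and scored by squared robust Mahalanobis
distance under a minimum-covariance-determinant location/scatter
estimate (seeded, so reports are reproducible). Cells beyond the χ²
quantile at the configured level (default 0.975, df = components) are
flagged. If the robust scatter is singular the detector falls back to a
median/MAD diagonal scatter with a warning. This is the unsupervised
complement to the classifier: it needs no labels, flags "deceptive"
cells that visual annotation calls intact, but cannot cope with
datasets where low-quality cells form their own dense cluster — which
is what motivates the supervised model.

## SVM ensemble

A radial-kernel SVM with per-class weights (LOW weight from the grid,
HIGH fixed at 1) is tuned by mean F_β over stratified k-fold CV on a
grid of gamma × cost × LOW-class weight (defaults: gamma 2⁻¹⁰…2² and
cost 2⁻⁴…2¹² in powers of four, weights {1, 2, 4, 8}). Scaling is fit
on each training fold only. Ties in the grid score break toward smaller
cost, then smaller gamma, then smaller weight — the smoothest model
that achieves the best score. Class weights exist because the training
mix is imbalanced (≈80/20): unweighted selection on imbalanced,
overlapping data collapses to the all-HIGH predictor.

Nested CV (default 10 outer × 10 inner folds) runs the full tuning
inside each outer training portion and evaluates on the held-out fold,
giving an accuracy estimate free of selection optimism. The ensemble is
built by repeating the tuning run (default 50 times) with reshuffled CV
splits; each run's selected grid point yields one SVM fitted on the
full training set. Repeated reshuffled stratified CV is used as the
resampling mechanism throughout (no bootstrap resampling). Prediction
is by majority vote with the exact tie resolved to LOW — quality
control should err toward discarding a questionable cell — and the
LOW-vote fraction is reported per cell as a confidence score.

Models serialize to a single versioned pickle archive (scaler
parameters, feature list, members, metadata including the master seed).
The same data and seed produce a byte-identical archive; loading checks
the schema version and raises a clear error on truncated files.

## UMI count transform

UMI protocols count molecules; the features and any read-count-trained
model expect read-scale values. Per-gene mean transcripts x and mean
reads y (from a paired dataset) are related by a cubic on the log
scale, log10(y+0.1) = a₀+a₁t+a₂t²+a₃t³ with t = log10(x+0.1). The
pseudo count 0.1 keeps zeros finite. The model is linear in its
coefficients, so ordinary least squares on the polynomial basis is the
exact solution (an iterative nonlinear fitter would converge to the
same coefficients). The fitted gene-level curve is applied entry-wise
to the transcript matrix — the simplest consistent reading — and
back-transformed values are clipped at 0.

## Synthetic data

The generator encodes the mechanism the method exploits. A log-normal
gene program (per-cell log-normal jitter, σ = 0.25) is sampled with
Gamma-Poisson counting noise (dispersion 0.2) at a log-normal library
size (mean 50,000 reads, σ = 0.25). ERCC spike-ins are added at a fixed
absolute amount per well (mean 2,500 reads) — the anchor that makes
spike-in fractions informative. Designated gene sets mirror a real
annotation: 37 mtDNA-encoded genes (with an 8× expression boost, as in
real cells), ~7.5% mitochondrially localized, ~half of the remainder
cytoplasmic, plus overlapping GO-role and housekeeping sets.

Cell classes (defaults 160 HIGH / 24 broken / 8 empty / 8 multiple —
the ≈80/20 imbalance of an annotated training set; surveys of real
datasets put low-quality fractions between 10% and 40%):

* **broken** — cytoplasmic transcripts retained at fraction 0.2,
  mitochondrially localized at √0.2 (partially protected), mtDNA
  relatively amplified 2×; mapped rate −0.15, non-exonic rate +0.10.
* **empty** — endogenous library at 1% of baseline; constant spike-ins
  then dominate.
* **multiple** — the sum of two independent cell draws at a combined
  1.9× library.
* **deceptive** (optional fraction of the HIGH pool) — broken
  expression profiles, labeled LOW, or HIGH when mislabeling is
  requested, to exercise relabeling workflows.

Alignment statistics are derived from the drawn counts so the read
accounting invariants hold by construction. What the generator does
*not* emulate: batch effects, chemistry-specific artifacts (UMI
collisions, index hopping), doublets of distinct cell types, gene
length/GC bias, and graded damage. Passing tests therefore demonstrate
that the pipeline recovers planted classes whose effect directions
match real damage signatures; they do not certify accuracy on any real
dataset, where class overlap is larger.

A second generator builds multi-cell-type *feature* tables for the
selection rule: independent standard-normal features plus two
type-separating features with opposite-direction between-type shifts
(so they occupy the two extremes of the leading component).

## Problem sizes and determinism

Tests and the acceptance script run on the 200-cell default fixture
with 2,000 genes and a reduced 18-point hyperparameter grid (gamma
{2⁻⁶,2⁻³,1} × cost {0.5,4,32} × weight {1,4}) — sizes at which the
planted structure is already cleanly recoverable and the full nested
10×10 CV completes in seconds. All randomness flows from explicit
seeds (numpy Generators, seeded MCD and CV splitters); identical
seeds give byte-identical outputs, which the test suite asserts
end-to-end through the CLI.

## Known limitations

* The classifier transfers across cell types only on the common feature
  subset, and even then datasets rich in multiples are hard — multiples
  resemble large intact cells in the common features.
* Gene-set membership is exact-ID matching; no ortholog or symbol
  mapping, so cross-species application requires re-deriving sets.
* The outlier detector assumes low-quality cells are a minority; dense
  clouds of damaged cells defeat any unsupervised χ²-cutoff method.
* The UMI transform is applied entry-wise from a gene-mean fit; it
  preserves ordering for monotone fits but is not a per-cell error
  model.
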