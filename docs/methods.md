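# Methods

## The problem

Severely imbalanced case/control transcriptomics cohorts (hundreds of cases,
a few dozen controls, tens of thousands of genes) defeat most off-the-shelf
classifiers: the feature dimension dwarfs the sample count, the minority
class is easy to ignore, and models that do classify well are hard to
interpret at the gene level. `tximage` implements a pipeline that addresses
all three at once:

1. **Gene filtering** — keep autosomal genes (sex chromosomes have
   different ploidy across donors), drop curated multi-haplotype loci where
   quantification is unreliable, and optionally keep only *high-expression*
   genes (value ≥ 10 in ≥ 10 samples) and/or protein-coding genes.
2. **Feature-to-image transform** — embed each gene's cross-sample
   expression profile into the plane with t-SNE (or kernel PCA), so genes
   with similar profiles are neighbours; enclose the cloud in its
   minimum-area rotated rectangle (found via the convex hull), rotate to
   axis-align it, rescale onto a square pixel grid, and rasterize each
   sample by writing its normalized expression values into the fixed gene
   layout. Genes landing in the same pixel are averaged.
3. **CNN classification** — a small convolutional network (two conv blocks
   of depth 32 and 64, each conv→ReLU→2×2 maxpool→dropout; dense 256;
   single sigmoid output) trained with Adam on class-weighted binary cross
   entropy and early stopping. Balanced class weights
   w_c = n/(2 n_c) make the 30 controls matter as much as the 245 cases.
4. **Attribution and backmapping** — additive per-pixel attributions
   against a background sample set, top-k pixel selection per sample,
   inverse mapping of pixels to the genes that formed them, and a
   cross-sample *gene support* count.

## Normalization ("norm-2")

Each gene is transformed by log2(x+1) and then min–max scaled to [0, 1]
using that gene's own (min, max) on the log scale; constant genes map to 0.
The (min, max) parameters are recorded at fit time and reused when
transforming held-out samples, whose values are clipped back into [0, 1] if
they fall outside the training range. The log-then-minmax form is this
package's explicit definition of the normalization; the variant in use is
recorded in the serialized feature map.

## The gene → pixel map

t-SNE runs on the gene-major matrix (genes are the embedded points, samples
the dimensions) with perplexity 30 by default (clamped to (n_genes−1)/3 for
small inputs), PCA initialization, and a caller-supplied seed; the embedding
is deterministic given the seed and library version. Kernel PCA uses a
linear kernel by default, making it exact PCA — useful when a deterministic,
analytically checkable embedding is wanted.

The minimum-area rectangle is computed from the convex hull (a side of the
optimum is always collinear with a hull edge, the rotating-calipers
theorem); the reported rotation angle is canonicalized to [0, π/2) and the
point cloud is rotated by its negative so the rectangle is axis-aligned.
Degenerate clouds (a single point, collinear points) yield a zero-extent
axis, which the rescaling step pads to a single pixel so the affine map
stays well defined.

Pixel discretization is half-open: each axis is affinely rescaled to
[0, grid_size − ε] and floored, so points on the maximum boundary land in
the last pixel. Every gene gets exactly one pixel; the inverse map
(pixel → gene set) is materialized alongside and is exact by construction.
Collisions are resolved at rasterization time by the unweighted arithmetic
mean of the colliding genes' normalized values (a median option exists).

The map may be fitted on training folds only (the default inside
cross-validation, preventing the held-out fold from informing the layout) or
once on all samples ("all" scope). Both modes are exposed because the
fit-once variant is cheaper and matches how such pipelines are often run in
practice; the default is the conservative one.

## Classifier and training

The network is implemented on numpy (see `tximage.nn`): convolution as
k² shifted GEMMs, exact max-pool gradient routing with deterministic
tie-breaks, inverted dropout, and Adam. All randomness (initialization,
shuffling, dropout, validation split) derives from a single config seed, so
training is bit-reproducible within one numpy version. Early stopping
monitors the class-weighted loss on a stratified 10 % validation split with
patience 20 by default and restores the best weights; these two constants
are package choices exposed in `CNNConfig`. If the split would give any
class fewer than 5 validation samples, validation is skipped and the full
epoch budget is trained instead — stopping on the loss of two or three
minority samples restores essentially arbitrary weights, which measurably
destroys held-out performance on small cohorts. The decision rule is
probability > 0.5 ⇒ case; exactly 0.5 is classified as control, since the
rule is defined by strict inequalities only.

Baselines: random forest and SVM with library defaults (resolved
hyperparameters are logged), and a fully connected network
(200–200–10–1, dropout 0.5 after each hidden layer, Adam, batch 32,
lr 0.001, 100 epochs, early stopping) trained on the raw feature vectors.

## Metrics and cross-validation

SEN, SPE, PPV, NPV, ACC, MCC and F1 come straight from the confusion matrix
with case = positive; AUC-ROC is the trapezoidal area under the ROC curve,
identical to Mann–Whitney concordance with ties scored ½. Zero-denominator
ratios are reported as NaN with a warning and excluded from fold averages.
Cross-validation is stratified by default — with ~30 minority samples,
unstratified 12-fold splitting risks minority-free folds and undefined
specificity — and fold assignment is made order-invariant by sorting samples
by id before splitting. Aggregates are mean ± sample standard deviation
(ddof = 1) across folds.

## Attribution

`attribute_pixels` computes expected gradients: integrated gradients from
each background sample to the target (midpoint rule, `n_steps` points),
averaged over the background. This satisfies the additive completeness
property — per sample, the attribution sum equals f(x) − E_background f(b)
up to the quadrature error of the path integral, which the stack records as
a per-sample residual. In practice residuals are ~10⁻³–10⁻⁴ at 16–32 steps,
far inside the 5 % tolerance the tests assert (with an absolute floor of
10⁻³ for samples whose output gap is essentially zero, where a relative
bound is meaningless). The estimator targets the sigmoid output, so positive
attributions push toward the case class.

Top-k selection (k = 10 by default) ranks pixels by signed value — "highest"
attribution read literally; an absolute-value mode exists because magnitude
ranking is also defensible. Ties break by (row, col) ascending for
reproducibility. Gene support counts, per gene, the samples whose top-k
pixels include that gene's pixel; genes sharing a pixel necessarily share
their support and no within-pixel disaggregation is attempted. The default
reporting threshold is support > ⌈0.36 · n⌉, the "more than 200 of 550"
rule carried over as a proportion; an absolute threshold can be passed
instead.

## Synthetic cohorts

`SyntheticSpec` defaults define the study conditions used throughout the
tests: 245 cases vs 30 controls (half-scale of a 490/60 cohort), 1000
genes, 10 signal genes in 2 correlated modules
(within-module correlation 0.8), a log-scale case shift of 1.0 (an e-fold
change, strong but realistic for a planted benchmark), per-gene biological
sd 0.4 on the log scale, negative-binomial counts with dispersion 0.3, and
20 % of genes constructed to fail the ≥10-in-≥10 filter. 10 % of genes are
assigned non-autosomal chromosomes, 15 % non-coding biotypes and 2 % the
curated-exclusion flag, so every filter has work to do; signal genes are
always autosomal, protein-coding and high-expression so the planted truth
survives filtering. Modules matter: correlated signal genes are exactly what
the similarity embedding co-locates into adjacent pixels, which is the
mechanism the image transform exploits.

`expected_separability` gives the analytic AUC of the oracle statistic
(mean log-expression of the signal genes): AUC = Φ(Δ / √(2 σ_s²)) with σ_s²
from the module covariance plus a delta-method term (1/μ + α)/m for the
counting noise. At the defaults it is ≈ 0.988, and it agrees with a
Monte-Carlo oracle classifier within 0.05 in the tests.

What the generator does *not* emulate: tissue and cell-type heterogeneity,
repeated donors across tissues, RNA-quality (RIN) artifacts, and library-size
variation. Passing the recovery tests therefore shows the pipeline can find
co-regulated, consistently shifted modules in overdispersed count data — not
that it is robust to those real-data confounders.

## Problem sizes in the tests

The test and acceptance runs use 50 × 50 images, 2-fold cross-validation
(so every held-out fold keeps 15 minority samples and fold metrics stay
stable), 60 training epochs, a 16-sample background with 4 integration
steps for the recovery experiment, and a 100-sample background with 16
steps for the completeness check. These sizes were chosen as the
smallest at which the phenomena of interest (imbalance handling, module
co-location, attribution completeness) are clearly expressed; the library
defaults (380 grid, 12 folds, 500 epochs, 200 backgrounds, top-10 pixels)
remain the full-scale settings.

## Known limitations

* The CNN is a CPU numpy implementation; it is intended for desk-scale
  grids (≤ ~120 px) and is not a GPU training framework.
* t-SNE layouts differ across library versions; the serialized feature map,
  not the embedding call, is the reproducibility anchor.
* Attribution under heavily correlated pixels splits credit unevenly — a
  planted gene whose module is already "covered" by neighbouring pixels can
  receive low support (observed on some synthetic seeds). This is inherent
  to attribution on correlated features, not an estimator bug.
* With very small gaps f(x) ≈ E f, relative completeness is ill-posed;
  the absolute floor (10⁻³) covers that regime.
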