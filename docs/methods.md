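# Methods

This note documents the models implemented in `gliapipe`, the defaults
and why they were chosen, what the synthetic cohort does and does not
emulate, and the numerical conventions that matter for reproducing
results.

## Study design being modelled

Four mouse genotypes carrying xenografted human microglia (xMG):
wild-type (`hWT`), amyloid-bearing (`h5XFAD`), tau-bearing (`hPS19`),
and combined pathology (`hPS-5X`). Each genotype contributes one or two
pooled scRNA-seq samples; cells are assigned to eight transcriptional
states (Homeostatic, MHCII, IFN, DAM, humanin-like, cytokine/chemokine,
degranulation, macrophage-like). Histology measures per mouse: amyloid
volume by two stains (Amylo-Glo, 82E1), phospho-tau volume (AT8),
neuronal counts (NeuN) and rod-shaped-microglia counts in CA1.

## Synthetic cohort generator

**Composition.** Mouse totals are negative-binomial (mean 5,000 cells,
size 80). Cluster allocation is Dirichlet-multinomial: the genotype's
expected proportions are the baseline proportions times the genotype's
fold-change vector, re-normalized (enriching one state depletes the
rest); the Dirichlet concentration is 200 x those proportions, giving
mouse-to-mouse compositional noise comparable to biological replicates
(proportion variance ≈ 26x multinomial at 5,000 cells). Setting the
concentration to `None` gives pure multinomial sampling — the sampling
model the DPA's bootstrap itself assumes. Default genotype effects
encode the qualitative cohort phenotype: DAM expansion with amyloid,
IFN expansion with tau, and homeostatic loss with joint IFN/DAM/cytokine
expansion under combined pathology.

**Counts.** Per-cell gene counts are negative-binomial (size 2) around
cluster-specific means: markers of the cell's own cluster sit
`marker_fc` (default 4) above background, and genes named with
`RPS*`/`RPL*` and `MT-*` prefixes receive fixed expected count shares
(15% and 5%) so the QC prefix rules work unchanged. Expected library
size is 2,500 UMI.

**Histology.** A Gaussian copula: latent five-variate normals share the
target correlation matrix, then each measure is linearly rescaled to
its genotype's mean and SD, truncated at zero, with counts rounded.
Linear maps preserve Pearson correlations exactly; truncation and
rounding perturb them slightly, hence recovery tolerances of ±0.05.
Default targets encode the reported pathology structure (rod–AT8
+0.85, rod–NeuN −0.88, AT8–NeuN −0.81, plaque stains +0.90 with each
other and near zero with rods). Within-genotype CVs are per measure:
0.25 for stain volumes, 0.08 for NeuN counts (regional neuron counts
are tight across littermates; a 25% CV would both be unrealistic and
wash out the cohort-level rod–NeuN correlation), 0.25 for rods with a
floor of 0.5.

**Shapes.** Rod templates are 60 x 8 x 8 µm boxes, ramified templates
30 x 24 x 20 µm, filled uniformly with the eight corners always
included (so ground-truth box lengths equal the template exactly),
randomly rotated and translated.

**What is not emulated:** ambient RNA, doublets, batch chemistry,
spatial structure, cluster-assignment error, and any coupling between
the count matrix and the histology. Passing tests therefore demonstrate
correctness of the statistics on data satisfying their nominal
generative assumptions (plus controlled violations such as the Dirichlet
overdispersion), not robustness to real-data artefacts.

## QC

Metrics: UMI total, detected genes, ribo/mito count fractions
(fractions of an all-zero cell are defined as 0; such cells fail the
gene floor regardless). Filters, all strict inequalities: ribo < 0.25
(the protocol states a 20–25% range; the permissive end is the default
and the bound is configurable), mito < 0.125, genes and UMI > 500 and
< 2x the median. Medians are computed per sample (each dataset is QC'd
before merging), on cells that already passed the fraction caps; both
choices are config switches because the original ordering is not
recoverable. Cluster-level exclusions (doublet/gene-poor/dividing) are
caller-designated label drops, not re-detection.

## Differential proportion analysis

Per replicate: cells are resampled with replacement within each sample
(equivalently, a multinomial draw on the sample's observed cluster
proportions — cluster identity is a cell's only attribute here, and no
re-clustering is performed); sample totals are then equalized to the
rounded mean total by largest-remainder apportionment, keeping counts
integral for the Poisson likelihood; a Poisson log-linear model
`cellCount ~ cellType * genotype` is fit by IRLS (statsmodels, max 50
iterations, deviance tolerance 1e-8) with treatment coding (reference:
first cluster, first genotype in roster order). Normalization runs per
replicate by default (switchable to once-before-bootstrap); the GLM's
observation unit is the sample row by default (switchable to
genotype-aggregated, which is the saturated design); both choices are
recorded in the run manifest. Non-converged replicates are dropped with
a logged count and the run fails if more than 1% drop.

Pooling follows Rubin's rules over the m replicate fits: q̄ = mean
estimate, W̄ = mean within-replicate variance, B = between-replicate
variance, T = W̄ + (1 + 1/m)B, statistic q̄/√T on a t distribution with
Barnard–Rubin degrees of freedom (complete-data df = GLM residual df;
when that is zero, the large-sample (m−1)/λ² form is used). Pairwise
genotype contrasts within a cluster are linear combinations of the
genotype main effects and interactions; family-wise adjustment uses the
single-step max-|t| method on the contrasts' estimated correlation
(from T assembled as a matrix), evaluating the multivariate-t rectangle
probability by seeded quasi-Monte-Carlo. Because the six pairwise
contrasts of four genotypes have rank 3, the correlation matrix is
singular; its spectrum is floored at 1e-6 of the largest eigenvalue
before integration, and adjusted p is clamped to be ≥ raw p. On
numerical failure the fallback is Bonferroni, with a warning.

**Calibration caveat (important).** This procedure treats bootstrap
replicates as imputations. Both W̄ and B then approximate the same
multinomial sampling variance, so T roughly double-counts it and the
test is conservative (√2-inflated SE) when the data really are
multinomial — measured type-I error ≈ 0.0003–0.006 at nominal 0.05.
Conversely the model contains no mouse-level variance term, so any real
between-mouse compositional variability (the generator's default
Dirichlet noise, or biology) is unaccounted for and the test becomes
strongly anti-conservative — measured type-I error ≈ 0.5 under the
default generator null. `scripts/acceptance.py` reports both rates.
Power for a 3-fold enrichment of a 5% cluster (2 samples/genotype,
5,000 cells) is essentially 1, and the pooled log-ratio estimator is
unbiased for the re-normalized true log fold. Users should read the
DPA's p-values as measures of resampling precision around the observed
cohort, not as tests generalizing over mice; with one or two samples
per genotype no method could do better without external variance
information.

## Differential expression

Log-normalization: x → ln(1 + 10,000·x/library). Fold-change is natural
log with pseudocount 1 applied to the de-logged group means (the v3
convention of the originating single-cell toolkit; log2 variants
exist). Genes enter the test when expressed (count > 0) in ≥ `min_pct`
of cells in *either* group (switchable to *both*; "either" matches the
cited implementation's semantics) and |lnFC| ≥ the cutoff (0.25 for
markers, 0.10 for genotype comparisons). P-values: exact enumeration of
rank-sum assignments when both groups have ≤ 8 cells (ties handled
exactly; scipy's exact method does not correct ties, which is why this
path is in-package), otherwise the normal approximation with tie and
continuity correction (scipy, vectorized across genes). BH adjustment
runs over the tested (pre-filtered) genes, matching the cited
implementation's family. The genotype-level comparison keeps the name
"pseudobulk" from the source protocol although it operates on cells.

## Module scoring

Genes are ranked by mean expression and cut into `n_bins` = 24
equal-size bins; each module gene contributes up to `n_ctrl` = 100
control genes drawn seeded, without replacement, from its bin
(defaults follow the published method this scoring scheme originates
from; both are exposed). Controls exclude module genes unless a module
owns its entire bin. Score = mean module expression − mean control
expression per cell. Under gene exchangeability the expected score is
0; note that a k-gene module retains O(sd/√k) gene-sampling noise in
its cohort-mean score (≈0.006 for 30 genes at these defaults), which is
a property of the estimator, not a bug. Group comparison is one-way
ANOVA with Tukey HSD on per-cell scores (as the source figures imply;
this pseudo-replicates mice — a per-sample-mean mode would be the
conservative alternative). Quartile binning uses stable cell order for
ties and bin sizes differing by at most one.

## Morphometry

`oriented_bbox` default ("hull") searches convex-hull facet normals:
each candidate box aligns one axis with a facet normal and closes with
the rotating-calipers minimum-area rectangle of the projected hull;
the minimum-volume candidate wins. This is deterministic, exact for
point sets containing a box's vertices, and robust where PCA is not:
for an elongated cell with near-square cross-section the covariance
eigenplane is degenerate (in-plane eigenvectors arbitrary, inflating
minor extents by up to √2), and even the leading eigenvector's ~5 mrad
sampling noise at 1,000 points leaks ~0.3–0.5 µm of a 60 µm axis into
the minor extents — outside a 2% tolerance. "pca" (leading eigenvector
+ minor-plane calipers) and "pca_raw" modes are kept for comparison.
Degenerate inputs (< 4 points, rank-deficient covariance) fall back to
PCA, pad missing directions with zero extents, and are flagged.

A cell is a rod when its longest box length strictly exceeds 50 µm (the
longest axis is the proxy for "maximal process length"; the cutoff is
the reported convention and `A = 50.0` exactly is *not* a rod). The
in-vitro elongation ratio A/B is exported without a hard threshold.
Pearson correlations use pairwise-complete rows with p from the t
transform on n−2 df; pairs with < 3 complete rows or zero variance are
reported missing. Group tests: equal-variance unpaired t-test by
default (Welch by flag), one-way ANOVA + Tukey HSD for rod counts.

## Pipeline and reproducibility

One master seed drives every stage; generator substreams are derived
per component, so stages can be regenerated independently. The run
manifest records the config hash, seed, per-stage timings and row
counts, and SHA-256 digests of all outputs; re-running a config with
the same seed reproduces every output byte-identically (tables are
written with a fixed float format). Simulation scale in the shipped
demo configs (small: 2 mice/genotype x ~1,000 cells, 500 genes;
acceptance simulations: 100–200 repeats at B = 200 bootstrap
replicates) was chosen to keep full runs in the minutes range on one
CPU while leaving Monte-Carlo error well inside the stated tolerances;
B is a scale parameter, not a semantic one, and production runs can use
the original 10,000.

## Known limitations

- The DPA calibration caveat above is the main scientific limitation.
- The synthetic cohort's DE structure is marker-based; it does not
  generate graded per-gene genotype effects, so pseudobulk DEG counts
  are not comparable to a real cohort's.
- Module scoring operates on the raw log-normalized matrix; no
  integration/batch correction is applied (cluster labels and any
  embedding are consumed as inputs elsewhere and out of scope here).
- The oriented bounding box is a bounding-box proxy for process length;
  it cannot measure curved process length and is not claimed equivalent
  to segmentation-based measures.
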