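# Methods

This note records the models, algorithms and numerical conventions behind
`crcith`, the design choices made where several defensible options existed,
and what the synthetic cohorts do and do not establish about real data.

## Normalization

TMM factors follow the edgeR dialect exactly (verified against
`calcNormFactors` to machine precision): the reference library is the one
whose upper-quartile CPM is closest to the cohort mean; gene-wise M-values
(log2 CPM ratio to the reference) and A-values (mean log2 abundance) are
computed on genes positive in both libraries; the most extreme 30 % of
M-values and 5 % of A-values are trimmed from each tail by rank; the factor
is `2**f` where `f` is the inverse-variance-weighted mean of the surviving
M-values (delta-method binomial variances). Factors are rescaled to
geometric mean 1. Because the weights depend on absolute library size, the
factors are only *approximately* invariant to rescaling a single library
(observed deviation < 0.01 for a 4-fold rescale); the M/A statistics
themselves are exactly scale-invariant.

log2(CPM) uses a library-size-proportional prior:
`prior_s = prior_count * L_s / mean(L)` (default `prior_count = 2`),
`value = log2((count + prior_s) / (L_s + 2 * prior_s) * 1e6)` with
`L_s` the TMM-effective library size. The expression filter keeps genes
with mean log2(CPM) strictly above 1 across samples (the mean-based
reading of the filter), optionally restricted to coding genes first.

Row z-scores use the n−1 denominator, as does every SD in the package.
Rows constant up to floating-point rounding (SD ≤ 1e-12 relative to the
row mean) map to zeros rather than amplified rounding noise.

## ITH-scores and gene panels

The ITH-score of a gene in a tumor is the SD (ddof = 1) of its log2(CPM)
over that tumor's biopsies; the inter-tumor score pools all biopsies.
"High ITH" means strictly greater than 0.5 — the boundary value itself is
excluded, as are the boundaries of every other quoted threshold in the
package (expression filter > 1, stroma score > 0.5, CNA score > 0.5,
MSI call at > 3 of 5 markers, NPX detection *below* 75 % removed, AU ≥ 95
included).

Quartile bins are computed per column (per tumor, and separately for the
inter-tumor column) from that column's own quantiles (linear
interpolation); scores tied with a boundary go to the lower bin, so a
fully tied column lands in bin 1. Whether the original analysis binned
per tumor or globally is not determinable; per-column matches per-patient
coloring and is the default, the alternative is a one-line change on the
`ITHTable`. Genes missing a stroma-score annotation are treated as
non-stromal (score 0) with a logged count.

## Subtype classifiers

Both families are generic and retrainable; no published gene lists or
frozen centroids are shipped.

**Nearest-centroid SSP.** Training z-scores each gene over the training
samples, selects markers in a class-balanced way (each class contributes
its top `n_markers / n_classes` genes by one-vs-rest standardized mean
separation; default 1000 markers total), and stores per-class centroids
(per-gene means of the z-scored expression). Prediction z-scores the
sample's genes with the *training* means/SDs and computes Pearson
correlation to each centroid; *nearest* mode returns the argmax, while
*predicted* mode returns UNCLASSIFIED when the best correlation falls
below `correlation_threshold` (default 0.15). When the top-two gap is
below `margin_threshold` (default 0.06) the runner-up is reported as a
secondary label. The gating constants are not fixed by any published
definition; the defaults are frozen in the tests and configurable.
Samples must cover ≥ 50 % of the marker genes (missing markers dropped
pairwise).

**kTSP.** Only within-sample ranks enter, so the classifier is invariant
to any within-sample monotone transform. For each unordered class pair the
candidate genes are the 300 whose mean within-sample rank moves the most
between the two classes, restricted to the upper 75 % of genes by mean
expression (low-abundance transcripts have unstable ranks at bulk depth);
the k = 25 gene pairs maximizing
`|P(x_i < x_j | class a) − P(x_i < x_j | class b)|` are chosen greedily
with genes disjoint within the pair list, a rank-gap secondary tie-break,
and each pair oriented so `x_i < x_j` votes for class a. Prediction runs
a round-robin tournament: each class-pair match is won by majority of its
pair votes, the final label is the class with most match wins, and a tied
or sub-threshold tournament margin produces an uncertain dual call rather
than an arbitrary choice. Per-class-pair ANOVA-style or variance-based
global candidate filters were tried and rejected: they admit genes whose
class association is an artifact of tumor-level baseline drift, which
collapses held-out stability.

In the pipeline the centroid family trains on the full coding space while
the kTSP family trains on the cancer-cell-intrinsic subspace (stroma
score ≤ 0.5 and outside the immune program), mirroring how
cancer-cell-intrinsic subtype systems exclude microenvironment transcripts
by construction. This asymmetry is what lets the two families dissect
microenvironment-driven from cancer-cell-driven ITH.

## Concordance

A tumor is discordant for a classifier when its biopsies carry ≥ 2
distinct primary labels; UNCLASSIFIED counts as its own label (an
unclassified biopsy is operationally a different call), and uncertain dual
calls are compared by primary label only, so a dual call whose primary
agrees with the co-biopsies does not create discordance. Discordance
fractions are reported for all tumors and per colorectal side; an empty
stratum is absent from the output, not zero. The intra-tumor correlation
of a biopsy is its mean pairwise Pearson r to co-biopsies on the filtered
expression matrix; concordant (0 discordant classifiers) versus discordant
(≥ 1) biopsies are compared with the two-sided Wilcoxon rank-sum test.

## Clustering and bootstrap support

Samples are clustered on `1 − Pearson r` (computed on row-z-scored
features) with Ward.D2 linkage — the Lance–Williams recurrence on squared
dissimilarities with square-root heights, which is what
`scipy.cluster.hierarchy.linkage(method="ward")` applies to a precomputed
condensed distance matrix (cross-checked against an independent
Lance–Williams implementation). Distances and trees are invariant to
positive per-sample affine transforms.

Clade support follows the multiscale bootstrap: features (genes or
proteins — the resampling unit for sample-clustering support) are resampled
with replacement at scales r ∈ {0.5, …, 1.4} (step 0.1; `ceil(r * n)`
features; default 100 replicates per scale for desk runs, 1000 to match
the original setting), BP_r is the fraction of replicate trees containing
each observed clade, and the two-parameter model
`BP_r = Φ(−(d√r + c/√r))` is fitted by weighted least squares with weights
`nboot · φ(z)² / (Φ(1−Φ))` evaluated at fitted values with one refit.
The approximately unbiased support is `AU = Φ(c − d) × 100`; BP is the
empirical value at r = 1. Nodes whose BP_r are all 0 or all 1 cannot be
fitted; their AU falls back to `100 · BP_1` with a flag. Clades with
AU ≥ 95 are significant (clade p ≤ 0.05). A tumor forms a
"tumor-specific cluster" when some internal node's leaf set equals exactly
its biopsy set. Cutting the tree at k clusters (default 2 for the protein
heatmap's left/right split) assigns each tumor to the cluster holding the
majority of its biopsies; exact ties go to the cluster with the smaller
mean distance to the tumor's biopsies and are logged.

## ssGSEA

Per sample, genes are ordered by decreasing expression (ties broken by
gene id for determinism) and weighted by `rank_from_bottom ** alpha`
(default alpha 0.75; 0.25 and 0 available). A set's score is the sum over
all ranked positions of a running sum that steps up by the normalized
weight at member genes and down by `1/(N − m)` elsewhere. Because weights
use rank positions, scores are invariant to within-sample monotone
transforms for every alpha; at alpha = 0 a set and its complement sum to
zero. No across-sample normalization is applied — comparisons are within
tumors only. Pathway ITH per tumor is the SD of a set's score over the
tumor's biopsies; the top 5000 varying sets (or all, if fewer exist) are
selected per tumor, per-biopsy deltas are median-normalized within tumors,
and set-set similarity edges use the mean of Jaccard and overlap
coefficients with a 0.375 default threshold.

## Protein panels

NPX values are log2-scale relative units. QC drops flagged samples first,
then proteins detected in strictly less than 75 % of the remaining samples
(exactly 75 % is retained); the operation is idempotent. Panel levels are
per-sample arithmetic means over member proteins, with missing members
skipped and logged. The Wilcoxon rank-sum test uses the exact permutation
distribution when the pooled sample is ≤ 50 and untied, otherwise the
normal approximation with tie and continuity corrections
(`scipy.stats.mannwhitneyu` under the hood; dual-checked against full
enumeration in the tests). Fisher's exact test reports the two-sided
p-value summing hypergeometric probabilities not exceeding the observed
table's (1 + 1e−7 relative tolerance) and the sample odds ratio with a
0.5 continuity correction when a cell is zero. Pairwise subtype tests are
reported unadjusted, with star annotations at 0.05 / 0.01 / 0.001 and a
Benjamini–Hochberg column alongside for transparency.

## The synthetic cohort model

Counts for gene g in biopsy b of tumor t are negative binomial with shared
dispersion (default 0.05) around
`exp2( base_g + tumordev_gt + biopsydev_gb + stromal_g·frac_b
+ cna_effect·log2(copies_gb / 2) + immune_effect·level_b·[g immune]
+ subtype shift )`, scaled to a per-biopsy library (~1e6, 10 % lognormal
jitter). Key structure:

* **Universe vs cohort.** Gene baselines, program roles, stroma scores and
  the protein-panel structure form a fixed "universe" drawn from
  `gene_seed`; tumors consume independent substreams
  `[seed, replicate·1e5 + t]`, so adding tumors or drawing a second
  replicate cohort never perturbs existing ones, and cohorts that must be
  comparable (classifier training vs application) share their universe.
* **Programs.** 300 stromal genes (stroma score 0.6–1; expression rises by
  `3 · score` log2 units per unit stromal fraction), 400 housekeeping
  genes (between/within-tumor drift scaled by 0.15), 200 immune genes
  driven by a latent infiltration level (MSI +1, proximal +0.5,
  immune subtype +1.5, within-tumor jitter SD 0.1). Program genes carry
  half the gene-autonomous between-tumor drift of generic genes because
  their variance is program-driven.
* **Subtypes.** Four classes (immune IMM, metabolic MET, chromosomal CIN,
  stromal STR) with 50-gene signatures shifted +2 log2 in labeled
  biopsies. Signature genes get drift multiplier 0.35 — signatures are
  class-driven by definition, and larger autonomous drift makes
  single-sample classification of a 4-class system collapse for *any*
  method. The STR signature is half stromal-program (admixture-sensitive)
  and half intrinsic; the CIN signature sits entirely on the recurrent
  CNA segments; IMM and MET signatures are intrinsic. MSI tumors are
  immune-subtype with probability 0.8, MSS tumors with probability 0.1.
* **Copy number.** Ten 20-gene segments; distal/MSS tumors aberrate all of
  them, near-diploid tumors only the non-signature segments (the leading
  segments are the canonical CIN amplicons). Default copy states are
  arm-level (1, 3, 4) with the physical dosage response
  `log2(copies/2)` (floored at copies 0.25).
* **Stromal admixture.** Per-biopsy Beta fraction (mean 0.3, configurable
  SD, capped at 0.9 — a biopsy always retains tumor content); STR biopsies
  get +0.3.
* **NPX.** 96 proteins: a 12-protein TAM-inflammation and an 8-protein
  cytotoxic-T panel load on the biopsy's immune level (Gaussian noise SD
  0.5); 28 planted low-detection proteins (detection probability 0.4)
  reliably fail the 75 % QC rule, leaving 68 analyzed proteins.

**The location-contrast scenario** (`contrast_scenario_config`) isolates
the two planted ITH mechanisms: proximal tumors receive a large
stromal-admixture spread (SD 0.4 against a 0.05 background), distal MSS
tumors receive fully subclonal focal events (copy states 0/1/4/8, two
guaranteed subclones per tumor), and the immune latent's within-tumor
jitter is off. Under it the centroid family's discordance concentrates
proximally (microenvironment mechanism) and the kTSP family's distally
(cancer-cell mechanism).

## What the simulations do and do not show

Passing tests establish that every operation implements its stated
definition (against independent oracles), that thresholds act exactly as
printed, and that the pipeline recovers planted structure at realistic
effect sizes: tumor-specific clades at between/within SD 2.0/0.3,
≥ 95 % subtype recovery at a 2-log2 class shift with 0.3 noise, the
stromal-vs-housekeeping ITH contrast, the location-dependent discordance
contrast, and MSI enrichment of the immune protein cluster. They do not
establish performance on real cohorts: the generator has independent
genes within programs, no batch or purity-calling error, Gaussian program
latents, and class-balanced training labels — all kinder than reality.
Effect sizes of location on expression are free parameters of the
generator, not estimates from any cohort.

Two deliberate behaviors worth knowing: clade recovery at the default
gene count is insensitive to raising within-tumor SD all the way to the
between-tumor SD (correlation over ~1800 genes averages the noise away;
degradation appears only beyond that range or at much smaller gene
counts), and a correlation-based single-sample classifier will
occasionally meet a tumor whose two best correlations tie within ~1e-3 —
such razor-edge tumors can split calls under arbitrarily small noise,
which is why the uncertain-call mechanism exists.

## Problem sizes

Defaults used throughout the tests and the acceptance script: 2000 genes,
14 tumors × 3 biopsies (42 samples), training cohorts of 100 tumors × 2
biopsies, 100 bootstrap replicates per scale, and 20–100 simulated cohorts
per Monte-Carlo claim. These sizes keep a full run on a laptop core in
minutes while leaving every Monte-Carlo margin comfortably wide.
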