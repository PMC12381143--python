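# Methods

`stratomics` re-implements, as a tested library, the statistical core of a
compartment-resolved multi-omics analysis of laminated brain tissue: paired
RNA-seq and DIA proteomics of hippocampal subregions (CA1, CA2/3, DG) and
CA1 strata (SO, SP, SR, SLM), plus fluorescence-activated synaptosome
sorting (FASS) with a sorted fraction (P3) and a size-gated unsorted control
(P2). This note documents the models, the defaults and the numerical
choices, and what the synthetic-data tests do and do not establish.

## Differential enrichment

**RNA counts.** Counts `K_gj` are modeled as negative binomial with mean
`s_j * q_g * 2^{beta_{g,c(j)}}` and per-gene dispersion `alpha_g`. Size
factors `s_j` are the median-of-ratios estimator (median over genes with
all-positive counts of `K_gj / geomean_g`), fixed to unit geometric mean so
the overall scale is identified. Dispersion estimation is a declared
simplification of the full empirical-Bayes MAP workflow used by count-based
DE tools: (1) gene-wise method-of-moments `alpha_hat = max(pooled (v - mu) /
pooled mu^2, 1e-8)` with within-group moments pooled across compartments;
(2) a robust (Huber-weighted, nonnegative) fit of the trend
`alpha(mu) = a0 + a1/mu` across informative genes; (3) the final dispersion
is the geometric mean of gene-wise and trend values, or the trend alone when
the gene-wise estimate hits the floor. The GLM (log link, offset `log s_j`,
compartment indicator plus replicate blocking factor) is fitted per gene by
IRLS (tol 1e-8, 100 iterations, 1e-10 ridge on the normal equations for
numerical safety); the Wald statistic `beta / SE` is referred to a standard
normal, two-sided. Measured on 7-vs-7 null simulations (2000 genes), the
rejection rate at nominal 0.05 is ~0.06.

Contrast schemes: subregions use all ordered pairwise contrasts with calls
requiring significance in *both* of a compartment's comparisons; strata use
one-vs-rest (each stratum against the pooled remainder). Both are exposed.

**Protein log2 intensities.** DIA protein-group intensities arrive at the
protein level here, so peptide-level DE algorithms are replaced by a
protein-level empirical-Bayes moderated linear model (a documented stand-in,
also listed in every run summary): per protein, OLS on the non-missing
values with compartment and replicate factors; residual variances `s_g^2`
with df `d_g`; a scaled inverse-chi-square prior `(d0, s0^2)` fitted by
matching the first two moments of `log s_g^2` (digamma/trigamma identities,
trigamma inverted by Newton iteration); moderated variance
`(d0 s0^2 + d_g s_g^2)/(d0 + d_g)` and a t reference with `d0 + d_g` df.
When the observed spread of `log s^2` does not exceed what the residual df
alone imply, `d0 = inf` and the test collapses to a z-test with the pooled
variance. Prior recovery on simulated variances (d0=4, s0^2=0.05, 5000
proteins) is within a few percent.

**Valid-value filter.** Before each intensity contrast, features must have
at least `min_quant` (default 1) non-missing values in *each* group of the
contrast (`by_contrast=False` relaxes this to the union).

**Calls and thresholds.** A feature is enriched in a compartment when
`q < alpha` and `log2FC >= 0.1` in all supporting contrasts (depleted with
`log2FC <= -0.1`); alpha defaults to 0.01 for tissue and 0.05 for
synaptosomes. Multiple testing uses Benjamini-Hochberg within contrast. The
fold-change cutoff 0.1 is deliberately permissive — it exists to remove
sign-trivial calls, not to act as an effect-size filter.

## Synaptosome contaminant filtering

For each compartment, the sorted fraction is compared against the unsorted
control (P3 vs P2) with the matching DE model; features significantly
enriched in P2 (`log2FC(P3/P2) <= -0.1`) in any compartment form the
contaminant list (one list per molecule type), which is removed from all
compartments before synaptic comparisons. Because the list is a *union* of
one FDR-controlled screening per compartment, thresholding each screening at
`alpha` would let the false-listing rate of the compiled list grow roughly
linearly with the number of compartments (~`C * alpha / 2` of the list under
realistic contamination rates). The default therefore thresholds each
screening at `alpha / n_compartments`, so `alpha` bounds the error of the
compiled list; `union_adjust=False` restores per-screening control. With the
default synthetic conditions (10% contaminants, +2 log2 shift in P2, n=7)
the list recovers ~100% of planted contaminants with ~2-4% false listings.

## Normalization and iBAQ

rlr normalization fits each sample's log2 intensities against the
per-feature median reference by Huber M-estimation (tuning constant 1.345,
50 IRLS iterations, tol 1e-8) and inverts the affine map
`x' = (x - a_j)/b_j`; a non-positive slope is an error naming the sample.
This inversion is taken as the canonical reading of "robust linear
regression normalization"; it is idempotent once samples agree up to affine
maps. iBAQ divides linear-scale intensity by the count of distinct
theoretical tryptic peptides of length 7-35. The digest follows Trypsin/P
(cleave after every K/R, including before proline) with 0 missed cleavages
by default — the canonical iBAQ convention; missed cleavages for
identification-library purposes are a separate concern and exposed as a
flag.

## Integration

* **Population correlation**: Pearson r between mean log2 normalized counts
  and mean log2 iBAQ over complete gene pairs, per stratum and pooled.
* **Profile correlation classes**: per gene, Pearson r between the
  4-stratum mean mRNA and protein profiles; `positive` at `r >= 0.9`,
  `negative` at `r <= -0.9`. No p-value is attached at 4 profile points.
  Zero-variance profiles are flagged and classed `neither`.
* **Half-life rank test**: classes joined to a protein half-life table by
  gene symbol; tie-corrected Kruskal-Wallis H with chi-square reference and
  Dunn's pairwise z tests, Bonferroni-adjusted. The `all` group contains
  every joined gene and overlaps the class groups (three-box convention);
  the resulting non-independence is intentional and logged. At very small
  group sizes the chi-square reference is known to be anti-conservative
  relative to the exact permutation distribution (differences up to ~0.09
  in the tail for n_i <= 4); the statistic itself is oracle-checked against
  an independent implementation under permutation.
* **Co-enrichment**: cross-tab of enriched-direction calls; genes enriched
  in several compartments contribute to every applicable cell (alluvial
  semantics). Per cell, translatome-label proportions are computed over
  labeled genes and sum to 1; unlabeled genes are counted separately.
* **z-scored fold changes**: row-wise `(x - mean)/sd` (ddof=1) across
  strata; constant rows become zeros and are flagged.

## Overrepresentation analysis

One-sided hypergeometric upper tail against a custom background (all genes
detected in the respective experiment); query and sets are intersected with
the background, sets below 3 background genes skipped, BH across tested
sets, significance at FDR 0.05. Depletion testing and GO-graph redundancy
simplification are out of scope.

## PLS-DA

NIPALS PLS2 on autoscaled predictors (zero-variance columns removed) against
the column-centered one-hot class matrix; per component,
`w = X'u/||X'u||`, `t = Xw`, `q = Y't/t't`, `u = Yq/q'q` iterated to a
relative score change below 1e-12 (5000 iterations cap — the slack matters
when the leading cross-covariance singular values are nearly degenerate, and
makes the first weight vector agree with the cross-covariance SVD direction
to 1e-8). Prediction is the argmax of the fitted class scores. Stratified
k-fold cross-validation (default 3-fold, 15 repeats) refits preprocessing
inside each training fold; the component count is chosen by the
one-standard-error rule, with the SE computed across all fold-by-repeat
accuracies of the best component count. VIP scores use
`VIP_j = sqrt(P * sum_a SSY_a w_aj^2 / sum_a SSY_a)` with
`SSY_a = (t_a.t_a)(q_a.q_a)`; mean squared VIP is 1 by construction, and the
reported 0-100 score is `100 * VIP / max(VIP)` (the raw VIP is always
emitted alongside). Complete cases only: proteins with any missing value
across the classified samples are excluded, and the exclusion count logged.

## Synthetic data and what the tests show

The generator plants every structure the analysis estimates, with defaults
chosen to represent a deep paired tissue design:

| parameter | default | rationale |
|---|---|---|
| compartments, replicates | 4 strata x 7 | paired tissue design at full depth |
| enriched fraction / effect | 10% per compartment, +1.0 log2 | clearly detectable at n=7 without being trivial |
| NB dispersion | lognormal(log 0.02, 0.3) | deep bulk RNA-seq of pooled tissue (alpha 0.01-0.05) |
| size factors | lognormal, sd 0.15, geomean 1 | typical library-size spread |
| protein noise | 0.5 log2 | DIA replicate CV of roughly 35% |
| profile coupling | classes +1/-1/0 at 20/15/65% | realizes strong positive/negative/no coupling |
| coupling amplitude | 1.0 log2 SD | protein spatial profiles comparable to mRNA effects |
| population coupling | r = 0.35 | modest cross-gene mRNA-protein abundance correlation observed in tissue |
| missingness | 5%, doubled in lowest intensity tercile | abundance-linked DIA missingness (MNAR-lite) |
| contaminants | 10% of features, +2.0 log2 in P2 | residual co-sorting material |
| half-lives | 96 h base, slope -0.4 per unit rho, lognormal sd 0.5 | positively coupled genes turn over faster |

Enrichment counts per compartment are planted exactly (a permutation cut
into fixed-size blocks) rather than by iid coin flips, which keeps small
configurations usable; membership remains random. Coupling classes are
planted only among genes with a planted (non-flat) mRNA profile — a flat
profile has no direction for a protein profile to correlate with — so
non-enriched genes stay truly null for enrichment-recovery evaluation. The
protein profile is `amplitude * (rho * standardized(beta) +
sqrt(1-rho^2) * independent standardized profile)`, making the expected
profile correlation equal the planted rho.

What the generator does **not** emulate: peptide-level quantification and
its shared-peptide ambiguity, between-replicate batch structure, count
outliers, library-preparation biases, annotation errors in the gene-symbol
join, or realistic gene-set topology. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated generative
model, not performance on real tissue.

Problem sizes used by the test-suite and the acceptance script — 2000 genes
for calibration and recovery, 250-500 genes for end-to-end checks, 20 seeds
for sign-agreement — were chosen so the full battery runs on a laptop-class
single core in a couple of minutes while keeping binomial noise on the
measured rates well inside the asserted margins.

## Known limitations

* Wald p-values use the normal reference regardless of residual df, like
  the count-DE tools this mirrors; at n=7 per group this is mildly
  anti-conservative (measured type-I ~0.06 at nominal 0.05).
* No effect-size shrinkage: reported log2 fold changes are unshrunk MLEs,
  and significance uses BH q-values rather than sign-error-based s-values.
* The moderated linear model treats protein-group intensities as given;
  peptide-level error structure is not propagated.
* The half-life "all" group overlaps the class groups; its Dunn contrasts
  are descriptive, not independent tests.
* Gene symbols are assumed pre-resolved one-to-one across molecule types.
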