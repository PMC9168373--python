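# Methods

This note documents the statistical machinery in `tmescore`: the model each
stage assumes, the defaults and why they were chosen, what the synthetic
cohorts do and do not emulate, and the numerical conventions.

## Deconvolution (`tmescore.deconvolution`)

A bulk profile *y* over the signature genes is modeled as a nonnegative
mixture of cell-type reference profiles (columns of the signature matrix
*S*). We fit linear ν-SVR of *y* on *S* for ν ∈ {0.25, 0.5, 0.75} and keep
the fit with the lowest reconstruction RMSE; negative coefficients are set
to zero and the remainder normalized to sum to one (relative fractions).

Standardization matters: the mixture is z-scored over the shared genes, and
the signature is standardized **globally** (a single mean and standard
deviation for the whole matrix). Per-column z-scoring would rescale each
cell type's coefficient by its column spread and destroy the proportionality
between coefficients and mixing weights; global standardization preserves
it, and noiseless mixtures are recovered to ≈1e-5 absolute error. Fractions
are invariant to positive rescaling of the mixture. The SVR cost parameter
is the library default (C = 1); the permutation p-value of the original
deconvolution tool is not computed because nothing downstream uses it — the
per-sample RMSE and Pearson r of the reconstruction are kept as diagnostics.

The bundled 22-type signature is a deterministic block design (20 marker
genes per cell type, markers ≈32-fold above background on the log2 scale
with 0.5 log2 within-block spread). It is generated from a fixed seed and is
a synthetic stand-in for an LM22-style reference; any real signature can be
supplied as a genes × cell-types TSV.

## Preprocessing (`tmescore.preprocess`)

* **FPKM → TPM**: column normalization to 10⁶; idempotent up to scale.
* **Gene filter**: a gene is dropped when *more than* 70% of its entries are
  missing or exactly zero (strict inequality at the boundary); zeros and
  missing values are pooled into a single bad-entry count.
* **KNN imputation**: a missing entry is the mean over the k = 10 nearest
  genes (rows) by Euclidean distance on shared observed samples. Row-space
  neighbors suit expression data, where co-regulated genes are better
  predictors than other samples. k is configurable.
* **log2 transform**: log2(TPM + 1); the pseudocount of 1 is the common
  convention and is configurable.
* **ComBat batch correction**: parametric empirical-Bayes location/scale
  adjustment — per-gene standardization under a design of batch indicators
  plus optional covariates, normal/inverse-gamma priors across genes,
  iterative posterior estimates, then removal. The implementation agrees
  with `sva::ComBat` to ~2e-6 on shared fixtures (frozen as a test). Note
  that empirical-Bayes shrinkage deliberately retains the gene-specific
  *sampling-noise* component of batch differences; only when standardized
  batch effects are homogeneous across genes is removal exact.
* **Moderated t**: two-group differential expression with empirical-Bayes
  variance shrinkage. The prior degrees of freedom and scale are estimated
  by digamma/trigamma moment matching on log residual variances, the
  moderated t uses the shrunken variance with augmented degrees of freedom,
  and BH adjustment controls FDR. Agrees with `limma::eBayes` to ~1e-13 on
  shared fixtures (frozen as a test). DEG flag: FDR < 0.05 **and**
  |log2FC| > 1.

## Consensus clustering (`tmescore.consensus`)

For each candidate k, 100 iterations subsample 80% of the items without
replacement, hierarchically cluster them, and cut the tree at k; the
consensus of a pair is its co-clustering rate among co-sampled iterations.
Pairs never co-sampled (vanishingly rare at these settings) get consensus 0
with a warning. Distances: Euclidean for samples on cell fractions,
1 − Pearson for genes on z-scored expression; average linkage for both —
standard choices where only "hierarchical clustering" is dictated.

Model selection uses the consensus-CDF area: A(k) is the trapezoid area
under the empirical CDF of the upper-triangle consensus values on a
101-point grid; Δ(k) = (A(k) − A(k−1))/A(k−1) with Δ(k_min) = A(k_min), and
the chosen k is the **largest k with Δ(k) ≥ 0.1**. On planted-partition data
the rule recovers the true k (4-block designs: 10/10 seeds in our tests). A
`force_k` override exists for manual inspection. Final labels come from
average-linkage clustering of 1 − consensus, renumbered by decreasing
cluster size so that naming (S1…S4, G1/G2) is reproducible.

## Stability selection and TMEscore (`tmescore.signature`)

**Random-forest stability selection.** A forest classifying subtype from
expression is fit 100 times with different seeds; each run records the
`per_run_top` genes by impurity importance, and a gene is selected when it
recurs in ≥80% of runs (boundary inclusive). Two caveats discovered during
validation and documented here deliberately:

* `per_run_top` must comfortably exceed the number of genuinely
  discriminating genes. With the bundled signature, several hundred genes
  carry real subtype signal; a cut of 100 turns the 80% threshold into a
  lottery among equally informative genes and keeps an unstable sliver. The
  pipeline default is therefore 300; for sparse planted designs (tens of
  informative genes) a cut near 100 behaves well.
* Repeating the forest with different seeds on a *fixed* cohort cannot wash
  out in-sample chance associations: with small samples the luckiest null
  genes are stably top-ranked. Expect a few false positives (we measure ≤2
  at n = 200 with 500 genes), not zero; true data-splitting stability
  selection would be needed to remove them and is out of scope.

**Prognostic screen.** Univariate Cox per selected gene (z-scored), kept at
p < 0.05 (configurable); constant or non-convergent genes are dropped with
warnings.

**Gene clusters and metagenes.** Prognostic genes are consensus-clustered
(1 − Pearson, k by the CDF rule over 2..5). Each cluster's per-sample score
is the projection onto the first principal component of its z-scored
submatrix; the PC sign is fixed so the score correlates nonnegatively with
the cluster's mean profile (PCA alone leaves the sign arbitrary). A
single-gene cluster reduces to that gene's z-score.

**TMEscore.** Each cluster's Cox sign comes from a univariate Cox fit of its
PC1 score (not a vote of member genes); the TMEscore is the signed sum
Σ₊PC1 − Σ₋PC1. It is invariant to cluster relabeling, and flipping the
simulated survival effect flips the affected cluster's sign and
contribution. Dichotomization uses the maximally selected rank statistic:
candidate cutoffs are midpoints between adjacent distinct scores leaving at
least 10% of samples on each side (`minprop = 0.1`, the cited tool's
default); the cutoff maximizing the standardized two-group log-rank
statistic wins, ties broken toward the median.

## Survival statistics (`tmescore.survstats`)

Kaplan–Meier estimation and Cox models are delegated to `lifelines`; the
median survival convention is the smallest time with S(t) ≤ 0.5. Cox fits
use Efron tie handling (the modern default; day-resolution data tie often).
Monotone likelihood (perfect separation) is reported as `converged=False`
rather than raised. A dedicated score test of the partial likelihood at
β = 0 (Efron convention) is provided; for a binary covariate with untied
event times it equals the two-group log-rank chi-square exactly, which is
frozen as an oracle test at 1e-6. Wilcoxon rank-sum uses the exact null for
the smaller sample ≤ 8 without ties, otherwise the normal approximation with
tie correction (no continuity correction, so exchangeable samples give
p = 1). Spearman correlation is Pearson on midranks with the
t-approximation.

## Enrichment and genomics (`tmescore.enrichment`)

**GSEA.** Genes are ranked by signal-to-noise between the two phenotype
classes (standard deviations floored at 20% of the class mean); the running
sum increments by |metric|^weight (weight 1 by default; weight 0 reduces to
the classical KS statistic, verified against direct computation) at member
genes and decrements by 1/(N − N_hit) otherwise; ES is the maximum
deviation. Significance uses phenotype permutation (default 1000): NES
divides ES by the mean same-sign permutation ES, the nominal p is the
same-sign permutation tail with an add-one correction (so p ≥ 1/(n_perm+1)),
and FDR q follows the permutation NES-ratio procedure. Set sizes outside
[15, 500] after intersection are skipped with a warning.

**ORA** is the upper-tail hypergeometric with BH adjustment; significance at
adjusted p < 0.2 by default (a deliberately permissive screen for small gene
lists). **Fisher's exact test** returns the sample odds ratio ad/bc (0/∞ for
zero cells) and a two-sided p by the minimum-likelihood rule; it matches a
full enumeration oracle on every table with margins ≤ 15. **Differential
mutation** builds a per-gene 2×2 of mutation × group and flags p < 0.01.
**TMB** is the raw count of non-silent variants (missense, nonsense,
nonstop, frameshift and in-frame indels, splice site, translation start
site) per sample — no per-megabase normalization, since a simulated exome
has no defined capture size; samples absent from the MAF count 0. The
biomarker-combination stratifier splits a second marker at the cohort median
and tests the four TMEscore × marker strata with an overall log-rank
(df = strata − 1), plus an optional responder cross-tabulation.

## Synthetic cohorts (`tmescore.synthetic`)

The generator emulates the data structure the pipeline assumes, with every
latent quantity exposed as ground truth:

* **Subtypes and fractions.** Each sample gets one of four infiltration
  subtypes; its 22 cell-type fractions are Dirichlet draws around the
  subtype's mean profile with common concentration 50, giving realistic
  within-subtype variability. The default profiles boost four cell types per
  subtype (mast/dendritic/Treg; B/plasma/activated CD4; M0/M2/resting CD4;
  CD8/NK/Tfh/M1), echoing the canonical immune-excluded, humoral,
  macrophage-suppressed and immune-active patterns.
* **Latent prognostic score.** Subtype means are evenly spaced on [−1, 1]
  with within-subtype frailty sd 0.3, so the infiltration subtype is the
  dominant but not sole determinant of prognosis — a cohort where the
  discrete subtypes separate survival, while a continuous expression-based
  score is more prognostic still. Survival is exponential with hazard
  baseline·exp(log HR × score) (default log HR = 1, baseline 1/1000 per
  day); censoring is an independent exponential clock whose rate is solved
  by bisection to hit the requested censored fraction (default 30%).
* **Expression.** Marker genes are the signature-weighted mixture on the
  linear TPM scale; planted prognostic modules (default: 30 risk genes with
  slope +1 log2 per score unit, 20 protective with −1) and filler genes are
  added on the log2 scale; multiplicative log-normal noise (log2 sd 0.25),
  optional per-gene batch shifts, library-size scaling to one million, and
  an optional uniform missingness mask complete the matrix. At zero noise
  with no modules the matrix is exactly the scaled mixture.
* **Mutations.** Per-gene Bernoulli mutation calls at rates that differ
  between the high- and low-score halves (default: 6 differential genes at
  45% vs 15%, 19 background genes at 20%), written as minimal MAF rows with
  a realistic mix of variant classes.

What the generator does **not** emulate: tumor-cell content (fractions span
immune types only), read-level noise or library-size artifacts, gene–gene
correlation beyond the planted modules and shared fractions, microarray
probe effects, copy number, and informative censoring. Passing recovery
tests therefore demonstrate internal consistency of the pipeline under its
own assumptions, not performance on real cohorts.

## Problem sizes and numerical conventions

Recovery and calibration checks run at the cohort sizes the method is meant
for while staying desk-scale: n = 200 samples (n = 500 for the
cutpoint/KM check), 1000 genes, 50 deconvolution mixtures, 100 forest runs,
2000-gene null panels, 200–1000 permutations for GSEA, and 10 seeds for the
model-selection sweep (run on the true fractions; deconvolved fractions
recover truth to MAE < 0.01, and the full deconvolution → clustering path is
checked separately on one cohort). Determinism is enforced by deriving every
stage seed from one global seed via SHA-256 of the stage name, so any stage
can be rerun in isolation; identical configs give byte-identical outputs.
Degenerate inputs fail loudly: all-zero samples, constant genes/scores,
confounded batch designs, zero-variance clusters and sub-minimum gene sets
raise or warn as documented in the API.

## Known limitations

* Relative fractions only: no absolute-abundance mode, and no construction
  of new signature matrices.
* The stability-selection false-positive floor described above.
* Non-parametric ComBat, time-varying covariates, competing risks and
  proportional-hazards diagnostics are out of scope.
* TIDE/IPS-style immunotherapy predictors are accepted as precomputed
  per-sample columns and only compared across score groups, never computed.
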