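# tmescore

Tumor-microenvironment (TME) classification and prognostic scoring from bulk
transcriptomes.

Bulk tumor RNA profiles mix malignant cells with infiltrating immune and
stromal cells, and the composition of that infiltrate carries prognostic and
immunotherapy-response information. `tmescore` implements, as a reusable and
tested Python pipeline, the transcriptome-based workflow that turns a bulk
expression matrix into (1) an immune-infiltration subtype per patient and
(2) a continuous per-patient risk score, the **TMEscore**:

1. **Deconvolution.** Immune-cell fractions for 22 leukocyte phenotypes are
   estimated per sample by linear ν-support-vector regression of the
   (standardized) bulk profile on a reference signature matrix (LM22-like),
   with negative coefficients clipped and the rest normalized to
   proportions.
2. **Subtype discovery.** Samples are grouped on their cell-fraction
   profiles by resampling-based consensus clustering (100 iterations, 80%
   resample rate, hierarchical clustering), with the number of clusters *k*
   chosen from the relative gain in area under the consensus-CDF curve.
3. **Signature genes.** Genes separating the subtypes are stability-selected
   by repeated random-forest classification (100 forests with different
   seeds; a gene is kept if it recurs among the top importance ranks in at
   least 80% of runs), then screened for prognosis with univariate Cox
   models.
4. **TMEscore.** The prognostic genes are consensus-clustered into gene
   clusters; each cluster is summarized by its first principal component
   (PC1 metagene), signed by the cluster's Cox coefficient:

   `TMEscore = Σᵢ PC1ᵢ − Σⱼ PC1ⱼ`

   where *i* runs over clusters with hazard-increasing (positive Cox
   coefficient) metagenes and *j* over hazard-decreasing ones. The score is
   dichotomized at the maximally selected log-rank cutpoint.

Downstream modules cover Kaplan–Meier/log-rank/Cox survival analysis,
phenotype-permutation GSEA with FDR by the permutation NES procedure,
hypergeometric over-representation, MAF-based differential-mutation and
tumor-mutational-burden comparison, and survival stratification by
TMEscore × a second biomarker (e.g. checkpoint-gene expression or TMB).

A first-class synthetic-cohort generator (`tmescore.synthetic`) produces
expression/clinical/mutation data with full ground truth — planted
infiltration subtypes, known cell fractions, a latent prognostic score, and
hazard-linked gene modules — so every stage of the pipeline is testable
against the truth that generated its input.

## Worked example

```python
import pandas as pd
from tmescore import preprocess, signature, survstats, synthetic
from tmescore.consensus import consensus_cluster
from tmescore.deconvolution import deconvolve_matrix

sig = synthetic.bundled_signature()                    # 440 genes x 22 cell types
cfg = synthetic.SimConfig(n_samples=200, seed=7)
expr, clinical, maf, truth = synthetic.simulate_cohort(cfg, sig)

fractions = deconvolve_matrix(expr, sig).fractions     # nu-SVR deconvolution
subtypes = consensus_cluster(fractions, k_range=range(2, 8), seed=1)
print(f"chosen k = {subtypes.chosen_k}")

log_expr = preprocess.log2_transform(expr)
records = pd.DataFrame({"time": clinical["os_days"], "event": clinical["os_event"]})
stable = signature.rf_stability_select(log_expr, subtypes.labels, seed=2)
genes = list(stable.index[stable["selected"]])
screen = signature.screen_prognostic(log_expr, records, genes)
members = signature.cluster_genes(log_expr, list(screen.index[screen["keep"]]), seed=3)
clusters = signature.build_cluster_set(log_expr, members, records)
score = signature.compute_tmescore(clusters)

cutoff, _ = survstats.optimal_cutpoint(score.scores, records)
score = signature.dichotomize(score, cutoff)
chi2, df, p = survstats.logrank_test(score.groups, records)
print(f"cutoff = {cutoff:.3f}; log-rank chi2 = {chi2:.1f} (p = {p:.2e})")
print(f"corr(TMEscore, true latent risk) = "
      f"{score.scores.corr(truth.true_latent_score):.3f}")
```

Output:

```
chosen k = 4
cutoff = 0.402; log-rank chi2 = 45.3 (p = 1.67e-11)
corr(TMEscore, true latent risk) = 0.837
```

The consensus-CDF rule recovers the four planted infiltration subtypes; the
TMEscore built from the stability-selected subtype genes tracks the latent
risk score that actually generated the survival times (correlation 0.84
here), and splitting patients at the learned cutpoint separates overall
survival decisively (log-rank p ≈ 2 × 10⁻¹¹).

## Command line

The same stages are exposed as subcommands of a single entry point:

```bash
tmescore simulate --config sim.yaml --out cohort/
tmescore deconvolve --expr cohort/expression.tsv --signature cohort/signature.tsv --out fractions.tsv
tmescore cluster --input fractions.tsv --mode samples --kmax 7 --out clusters/
tmescore score --expr cohort/expression.tsv --subtypes clusters/labels.tsv --clinical cohort/clinical.tsv --out score/
tmescore run-all --config run.yaml      # full pipeline with a YAML config
```

All inputs and outputs are plain TSV (expression: genes × samples; clinical:
`sample, os_days, os_event, ...`), MAF and GMT.

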