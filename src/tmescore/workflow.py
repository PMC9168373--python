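"""End-to-end pipeline: preprocess -> deconvolve -> subtype clustering ->
stability selection -> gene clustering -> TMEscore -> cutpoint -> survival ->
enrichment and mutation comparison.

Every intermediate is persisted as TSV with a JSON sidecar of parameters, and
the run report records per-stage item counts so cross-stage consistency can
be asserted. One global seed expands deterministically into per-stage seeds
by hashing the stage name, so any stage can be rerun in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import io as tio
from . import preprocess, signature, survstats
from .consensus import consensus_cluster
from .containers import ExpressionMatrix, Unit
from .deconvolution import deconvolve_matrix
from .enrichment import gsea, mutation_compare, tmb_from_maf

log = logging.getLogger("tmescore")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the global seed and stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    """Paths, stage toggles and parameters for a full pipeline run."""

    expression: str
    clinical: str
    signature: str
    maf: str | None = None
    gmt: str | None = None
    normal_expression: str | None = None
    outdir: str = "tmescore_run"
    unit: str = "TPM"

    run_deconvolution: bool = True
    run_subtype_clustering: bool = True
    run_scoring: bool = True
    run_gsea: bool = True
    run_mutations: bool = True

    max_bad_frac: float = 0.7
    knn_k: int = 10
    combat_batch_column: str | None = None
    sample_k_range: tuple[int, int] = (2, 7)
    gene_k_range: tuple[int, int] = (2, 5)
    consensus_iterations: int = 100
    resample_frac: float = 0.8
    rf_runs: int = 100
    rf_repeat_frac: float = 0.8
    rf_per_run_top: int = 300
    rf_trees: int = 100
    prognostic_alpha: float = 0.05
    cutpoint_minprop: float = 0.1
    gsea_permutations: int = 1000
    mutation_p_cut: float = 0.01
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "sample_k_range" in raw:
            raw["sample_k_range"] = tuple(raw["sample_k_range"])
        if "gene_k_range" in raw:
            raw["gene_k_range"] = tuple(raw["gene_k_range"])
        return cls(**raw)

    def validate(self) -> None:
        for name in ("expression", "clinical", "signature"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")
        for name in ("maf", "gmt", "normal_expression"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")
        if self.run_subtype_clustering and not self.run_deconvolution:
            raise ValueError("subtype clustering requires deconvolution")
        if self.run_scoring and not self.run_subtype_clustering:
            raise ValueError("scoring requires subtype clustering")


def validate_inputs(expr: ExpressionMatrix, clinical: pd.DataFrame,
                    maf: pd.DataFrame | None = None,
                    ) -> tuple[ExpressionMatrix, pd.DataFrame, list[str]]:
    """Reconcile sample ids across inputs; returns aligned data + warnings.

    Duplicated clinical samples keep the first occurrence; samples without
    both expression and clinical data are dropped; fewer than 3 overlapping
    samples is fatal. Survival times must be positive.
    """
    warns: list[str] = []
    if clinical.index.has_duplicates:
        n_dup = int(clinical.index.duplicated().sum())
        warns.append(f"{n_dup} duplicated clinical sample ids; keeping first")
        clinical = clinical[~clinical.index.duplicated(keep="first")]
    shared = expr.sample_ids.intersection(clinical.index)
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} samples shared between expression and "
            "clinical tables; need at least 3")
    dropped = len(clinical) - len(shared)
    if dropped:
        warns.append(f"{dropped} clinical samples absent from expression; excluded")
    dropped_expr = expr.shape[1] - len(shared)
    if dropped_expr:
        warns.append(f"{dropped_expr} expression samples without clinical data; excluded")
    mask = expr.mask.loc[:, shared] if expr.mask is not None else None
    expr = ExpressionMatrix(expr.values.loc[:, shared], expr.unit, mask)
    clinical = clinical.loc[shared]
    if (clinical["os_days"] <= 0).any():
        raise ValueError("nonpositive survival times in clinical table")
    if maf is not None:
        unknown = ~maf["Tumor_Sample_Barcode"].isin(shared)
        if unknown.any():
            warns.append(f"{int(unknown.sum())} MAF rows with samples outside "
                         "the cohort")
    for w in warns:
        log.warning(w)
    return expr, clinical, warns


def _save_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=str) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run report (also saved as
    ``report.json`` in the output directory)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "warnings": [], "seed": config.seed}

    def record(stage: str, **info) -> None:
        report["stages"][stage] = info
        log.info("stage %s: %s", stage, info)

    # ---- load & validate ---------------------------------------------------
    expr = tio.read_expression(config.expression, Unit(config.unit))
    clinical = tio.read_clinical(config.clinical)
    sig = tio.read_signature(config.signature)
    maf = tio.read_maf(config.maf) if config.maf else None
    expr, clinical, warns = validate_inputs(expr, clinical, maf)
    report["warnings"].extend(warns)
    records = pd.DataFrame({"time": clinical["os_days"].astype(float),
                            "event": clinical["os_event"].astype(int)},
                           index=clinical.index)
    record("load", n_genes=expr.shape[0], n_samples=expr.shape[1])

    # ---- preprocess --------------------------------------------------------
    if expr.unit is Unit.FPKM:
        expr = preprocess.fpkm_to_tpm(expr)
    n_before = expr.shape[0]
    expr = preprocess.filter_genes(expr, config.max_bad_frac)
    expr = preprocess.knn_impute(expr, config.knn_k)
    log_expr = preprocess.log2_transform(expr)
    if config.combat_batch_column:
        batch = clinical[config.combat_batch_column]
        if batch.nunique() > 1:
            log_expr = preprocess.combat_correct(log_expr, batch)
    tio.write_expression(expr, outdir / "expression_tpm.tsv")
    record("preprocess", genes_in=n_before, genes_out=expr.shape[0],
           genes_filtered=n_before - expr.shape[0])

    # ---- deconvolution -----------------------------------------------------
    fractions = None
    if config.run_deconvolution:
        table = deconvolve_matrix(expr, sig)
        fractions = table.fractions
        out = fractions.copy()
        out["rmse"] = table.rmse
        out["pearson_r"] = table.pearson_r
        out.to_csv(outdir / "cell_fractions.tsv", sep="\t",
                   index_label="sample")
        record("deconvolution", n_cell_types=fractions.shape[1],
               mean_r=float(table.pearson_r.mean()))

    # ---- subtype clustering ------------------------------------------------
    subtypes = None
    if config.run_subtype_clustering:
        lo, hi = config.sample_k_range
        res = consensus_cluster(
            fractions, k_range=range(lo, hi + 1),
            iterations=config.consensus_iterations,
            resample_frac=config.resample_frac, distance="euclidean",
            seed=stage_seed(config.seed, "subtype_clustering"))
        subtypes = res.labels.rename("subtype")
        subtypes.to_csv(outdir / "subtypes.tsv", sep="\t",
                        index_label="sample")
        pd.Series(res.cdf_areas).rename("cdf_area").to_csv(
            outdir / "cdf_areas.tsv", sep="\t", index_label="k")
        record("subtype_clustering", chosen_k=res.chosen_k,
               cdf_areas=res.cdf_areas,
               cluster_sizes=subtypes.value_counts().to_dict())

    # ---- signature & scoring ----------------------------------------------
    score_table = None
    if config.run_scoring:
        sel = signature.rf_stability_select(
            log_expr, subtypes, n_runs=config.rf_runs,
            repeat_frac=config.rf_repeat_frac,
            per_run_top=config.rf_per_run_top,
            seed=stage_seed(config.seed, "stability_selection"),
            n_estimators=config.rf_trees)
        sel.to_csv(outdir / "stability_selection.tsv", sep="\t",
                   index_label="gene")
        selected = list(sel.index[sel["selected"]])
        record("stability_selection", genes_selected=len(selected))
        if len(selected) < 2:
            raise RuntimeError("stage stability_selection: fewer than 2 "
                               "stable genes; cannot build the score")

        screen = signature.screen_prognostic(
            log_expr, records, selected, alpha=config.prognostic_alpha)
        screen.to_csv(outdir / "prognostic_screen.tsv", sep="\t",
                      index_label="gene")
        prognostic = list(screen.index[screen["keep"]])
        record("prognostic_screen", genes_in=len(selected),
               genes_kept=len(prognostic))
        if len(prognostic) < 2:
            raise RuntimeError("stage prognostic_screen: fewer than 2 "
                               "prognostic genes")

        lo, hi = config.gene_k_range
        members = signature.cluster_genes(
            log_expr, prognostic, k_range=range(lo, hi + 1),
            iterations=config.consensus_iterations,
            seed=stage_seed(config.seed, "gene_clustering"))
        pd.Series({g: cid for cid, genes in members.items() for g in genes},
                  name="cluster").to_csv(outdir / "gene_clusters.tsv",
                                         sep="\t", index_label="gene")
        cluster_set = signature.build_cluster_set(log_expr, members, records)
        score_table = signature.compute_tmescore(cluster_set)
        cutoff, maxstat = survstats.optimal_cutpoint(
            score_table.scores, records, minprop=config.cutpoint_minprop)
        score_table = signature.dichotomize(score_table, cutoff)
        pd.DataFrame({"score": score_table.scores,
                      "group": score_table.groups}).to_csv(
            outdir / "tmescore.tsv", sep="\t", index_label="sample")
        record("scoring", n_gene_clusters=len(members),
               cox_signs=cluster_set.cox_signs, cutoff=cutoff,
               cutpoint_statistic=maxstat,
               n_high=int((score_table.groups == "high").sum()),
               n_low=int((score_table.groups == "low").sum()))

        # ---- survival ------------------------------------------------------
        chi2, df, p = survstats.logrank_test(score_table.groups, records)
        km_high = survstats.km_estimate(
            records[score_table.groups == "high"])
        km_low = survstats.km_estimate(records[score_table.groups == "low"])
        rec = records.copy()
        rec["score"] = score_table.scores
        cox = survstats.cox_fit(rec, ["score"])
        surv_summary = {
            "logrank_chi2": chi2, "logrank_df": df, "logrank_p": p,
            "median_os_high": km_high.median, "median_os_low": km_low.median,
            "cox_coef": float(cox.coef.iloc[0]),
            "cox_hr": float(cox.hr.iloc[0]),
            "cox_p": float(cox.p.iloc[0]),
        }
        _save_json(surv_summary, outdir / "survival_summary.json")
        record("survival", **surv_summary)

    # ---- enrichment --------------------------------------------------------
    if config.run_gsea and config.gmt and score_table is not None:
        sets = tio.read_gmt(config.gmt)
        res = gsea(log_expr, (score_table.groups == "high").astype(int),
                   sets, n_perm=config.gsea_permutations,
                   seed=stage_seed(config.seed, "gsea"))
        res.to_csv(outdir / "gsea.tsv", sep="\t")
        record("gsea", n_sets=len(res),
               n_fdr25=int((res["fdr_q"] < 0.25).sum()))

    # ---- mutations ---------------------------------------------------------
    if config.run_mutations and maf is not None and score_table is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comp = mutation_compare(maf, score_table.groups,
                                    p_cut=config.mutation_p_cut)
            tmb = tmb_from_maf(maf, samples=clinical.index)
        comp.to_csv(outdir / "mutation_comparison.tsv", sep="\t")
        tmb.to_csv(outdir / "tmb.tsv", sep="\t", index_label="sample")
        record("mutations", n_genes=len(comp),
               n_differential=int(comp["differential"].sum()),
               median_tmb=float(tmb.median()))

    _save_json(report, outdir / "report.json")
    return report
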