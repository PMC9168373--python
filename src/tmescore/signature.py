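"""TMEscore construction.

The prognostic score is built in four steps: (1) stability selection of
subtype-discriminating genes by repeated random forests; (2) univariate Cox
screening of the selected genes; (3) consensus clustering of the surviving
genes into clusters and extraction of each cluster's first principal
component as a per-sample metagene score; (4) the TMEscore of a sample is
the sum of metagene scores of hazard-increasing clusters minus the sum over
hazard-decreasing clusters:

    TMEscore = sum_i PC1_i - sum_j PC1_j,

where i runs over clusters whose Cox coefficient is positive and j over
clusters whose Cox coefficient is negative.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import survstats
from .consensus import consensus_cluster
from .containers import ExpressionMatrix, GeneClusterSet, TMEscoreTable


def rf_stability_select(expr: ExpressionMatrix, subtype_labels: pd.Series,
                        n_runs: int = 100, repeat_frac: float = 0.8,
                        per_run_top: int = 300, seed: int = 0,
                        n_estimators: int = 100) -> pd.DataFrame:
    """Stability selection of subtype-discriminating genes by repeated RF.

    Each run fits a random-forest classifier of subtype from expression with
    a run-specific seed and records the ``per_run_top`` genes by impurity
    importance. A gene is selected iff it appears in at least
    ``repeat_frac * n_runs`` runs (boundary inclusive).

    ``per_run_top`` should comfortably exceed the number of genuinely
    subtype-discriminating genes: a cut below that count turns the stability
    threshold into a lottery among equally informative genes and keeps only
    an unstable sliver of them.

    Returns a gene-indexed DataFrame with ``selection_count`` and ``selected``.
    """
    labels = subtype_labels.reindex(expr.sample_ids)
    counts = labels.value_counts()
    if len(counts) < 2 or (counts < 5).any():
        raise ValueError("need >= 2 subtypes with >= 5 samples each")
    X = expr.values.to_numpy(dtype=float).T  # samples x genes
    gene_ids = expr.gene_ids
    constant = X.std(axis=0) == 0
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} constant genes "
                      "before random-forest fitting")
        X = X[:, ~constant]
        gene_ids = gene_ids[~constant]
    y = labels.to_numpy()
    per_run_top = min(per_run_top, X.shape[1])
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    sel_count = np.zeros(X.shape[1], dtype=int)
    for rs in run_seeds:
        forest = RandomForestClassifier(n_estimators=n_estimators,
                                        random_state=int(rs), n_jobs=1)
        forest.fit(X, y)
        top = np.argsort(forest.feature_importances_)[::-1][:per_run_top]
        sel_count[top] += 1
    threshold = repeat_frac * n_runs
    out = pd.DataFrame({
        "selection_count": sel_count,
        "selected": sel_count >= threshold,
    }, index=gene_ids)
    return out.sort_values("selection_count", ascending=False)


def screen_prognostic(expr: ExpressionMatrix, survival: pd.DataFrame,
                      genes, alpha: float = 0.05) -> pd.DataFrame:
    """Univariate Cox screen of candidate genes.

    Returns a gene-indexed DataFrame with ``coef``, ``p`` and ``keep``
    (p < alpha). Constant or non-convergent genes are dropped with a warning.
    """
    samples = expr.sample_ids.intersection(survival.index)
    surv = survival.loc[samples, ["time", "event"]]
    rows = {}
    for gene in genes:
        x = expr.values.loc[gene, samples].astype(float)
        if x.std() == 0:
            warnings.warn(f"gene {gene} is constant; dropped from screen")
            continue
        rec = surv.copy()
        rec["expr"] = ((x - x.mean()) / x.std()).to_numpy()
        fit = survstats.cox_fit(rec, ["expr"])
        if not fit.converged:
            warnings.warn(f"Cox fit for gene {gene} did not converge; dropped")
            continue
        rows[gene] = (float(fit.coef.iloc[0]), float(fit.p.iloc[0]))
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["coef", "p"])
    out["keep"] = out["p"] < alpha
    return out


def pc1_score(expr: ExpressionMatrix, genes=None) -> pd.Series:
    """Per-sample projection onto PC1 of a gene cluster.

    Genes are z-scored across samples first. The component orientation is
    fixed so the score correlates nonnegatively with the per-sample mean of
    the cluster genes. A single-gene cluster reduces to that gene's z-score.
    """
    values = expr.values if genes is None else expr.values.loc[list(genes)]
    X = values.to_numpy(dtype=float)  # genes x samples
    sd = X.std(axis=1, keepdims=True)
    if (sd == 0).all():
        raise ValueError("zero-variance gene cluster has no principal component")
    Z = (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    # PC1 via SVD of the centered (z-scored) matrix: samples projected on the
    # leading right singular vector.
    _, svals, vt = np.linalg.svd(Z, full_matrices=False)
    score = svals[0] * vt[0]
    mean_profile = Z.mean(axis=0)
    if np.corrcoef(score, mean_profile)[0, 1] < 0:
        score = -score
    return pd.Series(score, index=expr.sample_ids, name="pc1")


def cluster_genes(expr: ExpressionMatrix, genes, k_range=range(2, 6),
                  iterations: int = 100, seed: int = 0,
                  force_k: int | None = None) -> dict[str, list[str]]:
    """Consensus-cluster genes (1 - Pearson distance on z-scored rows) into
    clusters named G1, G2, ... by decreasing size."""
    genes = list(genes)
    if len(genes) < 3:
        return {"G1": genes}
    k_range = range(min(k_range), min(max(k_range), len(genes) - 1) + 1)
    sub = expr.values.loc[genes]
    result = consensus_cluster(sub, k_range=k_range, iterations=iterations,
                               distance="pearson", seed=seed, force_k=force_k)
    members: dict[str, list[str]] = {}
    for cid in sorted(result.labels.unique()):
        members[f"G{cid}"] = list(result.labels.index[result.labels == cid])
    return members


def build_cluster_set(expr: ExpressionMatrix, members: dict[str, list[str]],
                      survival: pd.DataFrame) -> GeneClusterSet:
    """Metagene scores and Cox signs for each gene cluster.

    The sign comes from a univariate Cox fit of the cluster's PC1 score, not
    from a vote of member genes.
    """
    samples = expr.sample_ids.intersection(survival.index)
    scores = {}
    signs = {}
    for cid, genes in members.items():
        s = pc1_score(expr, genes)
        scores[cid] = s
        rec = survival.loc[samples, ["time", "event"]].copy()
        rec["pc1"] = s.reindex(samples).to_numpy()
        fit = survstats.cox_fit(rec, ["pc1"])
        signs[cid] = +1 if float(fit.coef.iloc[0]) >= 0 else -1
    return GeneClusterSet(members=members,
                          pc1_scores=pd.DataFrame(scores),
                          cox_signs=signs)


def compute_tmescore(cluster_set: GeneClusterSet) -> TMEscoreTable:
    """TMEscore = sum of PC1 over hazard-positive clusters minus the sum over
    hazard-negative clusters."""
    missing = [c for c in cluster_set.pc1_scores.columns
               if c not in cluster_set.cox_signs]
    if missing:
        raise ValueError(f"clusters without a Cox sign: {missing}")
    score = pd.Series(0.0, index=cluster_set.pc1_scores.index)
    for cid in cluster_set.pc1_scores.columns:
        score = score + cluster_set.cox_signs[cid] * cluster_set.pc1_scores[cid]
    return TMEscoreTable(scores=score.rename("tmescore"))


def dichotomize(table: TMEscoreTable, cutoff: float) -> TMEscoreTable:
    """Split samples into high (score > cutoff) and low groups."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    scores = table.scores
    if cutoff >= scores.max() or cutoff < scores.min():
        warnings.warn("cutoff outside the score range leaves one group empty")
    groups = pd.Series(np.where(scores > cutoff, "high", "low"),
                       index=scores.index, name="group")
    return TMEscoreTable(scores=scores, cutoff=float(cutoff), groups=groups)
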