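"""Expression preprocessing: unit conversion, gene filtering, imputation,
batch correction, and moderated-t differential expression.

The differential-expression front end uses an empirical-Bayes moderated
t-statistic: per-gene variances are shrunk toward a pooled prior whose scale
and degrees of freedom are estimated by moment matching on the distribution
of log residual variances, then two-group t-tests use the shrunken variance
with augmented degrees of freedom.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.impute import KNNImputer
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, Unit


def fpkm_to_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale FPKM columns so each sample sums to one million (TPM).

    tpm_ij = fpkm_ij / sum_i fpkm_ij * 1e6.
    """
    if matrix.unit is not Unit.FPKM:
        raise ValueError(f"expected FPKM input, got {matrix.unit.value}")
    values = matrix.values
    if (values.to_numpy() < 0).any():
        raise ValueError("FPKM values must be nonnegative")
    colsum = values.sum(axis=0)
    zero = colsum[colsum == 0]
    if len(zero) > 0:
        raise ValueError(f"all-zero expression for sample(s): {list(zero.index)}")
    return matrix.with_values(values / colsum * 1e6, Unit.TPM, matrix.mask)


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(TPM + pseudocount); the scale expected by ComBat and limma-style DE."""
    if matrix.unit is not Unit.TPM:
        raise ValueError(f"expected TPM input, got {matrix.unit.value}")
    return matrix.with_values(np.log2(matrix.values + pseudocount),
                              Unit.LOG2TPM, matrix.mask)


def filter_genes(matrix: ExpressionMatrix, max_bad_frac: float = 0.7) -> ExpressionMatrix:
    """Drop genes whose fraction of missing-or-zero entries exceeds the cap.

    A gene is retained iff its bad fraction is <= ``max_bad_frac`` (strictly
    greater removed); zeros and masked entries are pooled into one count.
    """
    values = matrix.values
    bad = values.to_numpy() == 0
    if matrix.mask is not None:
        bad = bad | matrix.mask.to_numpy()
    bad_frac = bad.mean(axis=1)
    keep = bad_frac <= max_bad_frac
    if not keep.any():
        raise ValueError(
            "no genes survive the missing/zero filter; review max_bad_frac")
    mask = matrix.mask.loc[keep] if matrix.mask is not None else None
    return matrix.with_values(values.loc[keep], matrix.unit, mask)


def knn_impute(matrix: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Fill missing entries from the k nearest genes (rows) by Euclidean
    distance over shared observed samples; mean aggregation; mask cleared."""
    if matrix.mask is None or not matrix.mask.to_numpy().any():
        return matrix.with_values(matrix.values.copy(), matrix.unit, None)
    values = matrix.values.to_numpy(dtype=float).copy()
    mask = matrix.mask.to_numpy()
    all_missing = mask.all(axis=1)
    if all_missing.any():
        genes = list(matrix.gene_ids[all_missing])
        raise ValueError(f"cannot impute genes with no observed entries: {genes}")
    values[mask] = np.nan
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    imputed = imputer.fit_transform(values)
    out = pd.DataFrame(imputed, index=matrix.gene_ids, columns=matrix.sample_ids)
    return matrix.with_values(out, matrix.unit, None)


# ---------------------------------------------------------------------------
# ComBat empirical-Bayes batch correction (parametric, location + scale)
# ---------------------------------------------------------------------------

def combat_correct(matrix: ExpressionMatrix,
                   batch: pd.Series,
                   covariates: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Parametric empirical-Bayes batch correction on log2 expression.

    Per gene the data are standardized under a design containing batch
    indicators plus optional covariates; batch location and scale effects are
    then shrunk toward normal / inverse-gamma priors estimated across genes
    and removed. Covariate-associated signal survives because covariates sit
    in the standardization design.
    """
    if matrix.unit is not Unit.LOG2TPM:
        raise ValueError("ComBat expects log2-scale expression")
    batch = batch.reindex(matrix.sample_ids)
    if batch.isna().any():
        raise ValueError("batch labels missing for some samples")
    levels = pd.unique(batch)
    if len(levels) < 2:
        return matrix.with_values(matrix.values.copy(), matrix.unit, matrix.mask)
    counts = batch.value_counts()
    if (counts < 3).any():
        small = list(counts[counts < 3].index)
        raise ValueError(f"batches with fewer than 3 samples: {small}")

    X = matrix.values.to_numpy(dtype=float)  # genes x samples
    G, n = X.shape
    batch_design = pd.get_dummies(batch).astype(float)  # n x B, all levels
    batch_design = batch_design[list(levels)]
    B = batch_design.shape[1]
    design = batch_design.to_numpy()
    if covariates is not None:
        cov = covariates.reindex(matrix.sample_ids)
        cov_num = pd.get_dummies(cov, drop_first=True).astype(float).to_numpy()
        design = np.hstack([design, cov_num])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("design is collinear: a covariate is confounded "
                         "with batch")

    # gene-wise OLS of expression on [batch indicators | covariates]
    beta, *_ = np.linalg.lstsq(design, X.T, rcond=None)  # params x genes
    n_batch_arr = batch_design.sum(axis=0).to_numpy()
    grand_mean = (n_batch_arr / n) @ beta[:B]            # genes
    stand_mean = np.tile(grand_mean[:, None], (1, n))
    if design.shape[1] > B:
        stand_mean = stand_mean + (design[:, B:] @ beta[B:]).T
    resid = X - (design @ beta).T
    var_pooled = (resid ** 2).sum(axis=1) / n
    var_pooled = np.maximum(var_pooled, 1e-12)
    sd = np.sqrt(var_pooled)[:, None]
    Z = (X - stand_mean) / sd

    member = batch_design.to_numpy().astype(bool)  # n x B
    gamma_hat = np.empty((G, B))
    delta_hat = np.empty((G, B))
    for b in range(B):
        Zb = Z[:, member[:, b]]
        gamma_hat[:, b] = Zb.mean(axis=1)
        delta_hat[:, b] = Zb.var(axis=1, ddof=1)
    delta_hat = np.maximum(delta_hat, 1e-12)

    # parametric priors across genes (per batch)
    gamma_bar = gamma_hat.mean(axis=0)
    tau2 = gamma_hat.var(axis=0, ddof=1)
    d_mean = delta_hat.mean(axis=0)
    d_var = delta_hat.var(axis=0, ddof=1)
    lam = (2 * d_var + d_mean ** 2) / np.maximum(d_var, 1e-12)  # IG shape
    theta = (d_mean * d_var + d_mean ** 3) / np.maximum(d_var, 1e-12)  # IG scale

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for b in range(B):
        nb = int(n_batch_arr[b])
        g_old = gamma_hat[:, b].copy()
        d_old = delta_hat[:, b].copy()
        Zb = Z[:, member[:, b]]
        sse_base = ((Zb - gamma_hat[:, b][:, None]) ** 2)
        for _ in range(100):
            g_new = ((nb * tau2[b] * gamma_hat[:, b] + d_old * gamma_bar[b])
                     / (nb * tau2[b] + d_old))
            sse = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (theta[b] + 0.5 * sse) / (nb / 2 + lam[b] - 1)
            if (np.max(np.abs(g_new - g_old)) < 1e-8
                    and np.max(np.abs(d_new - d_old)) < 1e-8):
                g_old, d_old = g_new, d_new
                break
            g_old, d_old = g_new, d_new
        del sse_base
        gamma_star[:, b] = g_old
        delta_star[:, b] = np.maximum(d_old, 1e-12)

    corrected = Z.copy()
    for b in range(B):
        idx = member[:, b]
        corrected[:, idx] = ((Z[:, idx] - gamma_star[:, b][:, None])
                             / np.sqrt(delta_star[:, b])[:, None])
    corrected = corrected * sd + stand_mean
    out = pd.DataFrame(corrected, index=matrix.gene_ids,
                       columns=matrix.sample_ids)
    return matrix.with_values(out, matrix.unit, matrix.mask)


# ---------------------------------------------------------------------------
# Moderated-t differential expression
# ---------------------------------------------------------------------------

def _fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match an scaled inverse-chi-square prior to gene variances.

    Works on z = log(s2): E[z] and Var[z] involve digamma/trigamma of df/2;
    solving the trigamma equation for the prior df follows the classic
    empirical-Bayes recipe for variance shrinkage.
    """
    z = np.log(np.maximum(s2, 1e-300))
    e_z = z.mean()
    var_z = z.var(ddof=1)
    target = var_z - special.polygamma(1, df / 2.0)
    if target <= 1e-8:
        return np.inf, float(np.exp(e_z - special.digamma(df / 2.0)
                                    + np.log(df / 2.0)))
    # invert trigamma(x) = target by Newton on 1/trigamma (monotone, stable)
    x = 0.5 + 1.0 / target
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / target) / special.polygamma(2, x)
        x = x + step
        if abs(step) < 1e-8 * x:
            break
    d0 = 2.0 * max(x, 1e-3)
    s0_log = (e_z + special.digamma(d0 / 2.0) - special.digamma(df / 2.0)
              - np.log(d0 / 2.0) + np.log(df / 2.0))
    return float(d0), float(np.exp(s0_log))


def moderated_t_deg(tumor: ExpressionMatrix, normal: ExpressionMatrix,
                    fdr_cut: float = 0.05, lfc_cut: float = 1.0) -> pd.DataFrame:
    """Two-group moderated-t differential expression on log2 data.

    Returns a gene-indexed DataFrame with log2fc (tumor - normal), the
    moderated t, raw p, BH fdr, direction, and an ``is_deg`` flag set iff
    fdr < fdr_cut and |log2fc| > lfc_cut.
    """
    if tumor.unit is not Unit.LOG2TPM or normal.unit is not Unit.LOG2TPM:
        raise ValueError("moderated t expects log2-scale inputs")
    shared = tumor.gene_ids.intersection(normal.gene_ids)
    xt = tumor.values.loc[shared].to_numpy(dtype=float)
    xn = normal.values.loc[shared].to_numpy(dtype=float)
    n1, n2 = xt.shape[1], xn.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")
    df = n1 + n2 - 2
    if df <= 0:
        raise ValueError("zero residual degrees of freedom")
    m1, m2 = xt.mean(axis=1), xn.mean(axis=1)
    lfc = m1 - m2
    s2 = ((xt.var(axis=1, ddof=1) * (n1 - 1) + xn.var(axis=1, ddof=1) * (n2 - 1))
          / df)
    d0, s0_2 = _fit_variance_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_post = np.inf
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_post = d0 + df
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    tstat = lfc / np.maximum(se, 1e-300)
    if np.isinf(df_post):
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df_post)
    fdr = bh_adjust(p)
    out = pd.DataFrame({
        "log2fc": lfc,
        "moderated_t": tstat,
        "p": p,
        "fdr": fdr,
        "direction": np.where(lfc >= 0, "up", "down"),
    }, index=shared)
    out["is_deg"] = (out["fdr"] < fdr_cut) & (out["log2fc"].abs() > lfc_cut)
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-values cannot be adjusted")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def subtype_marker_degs(expr: ExpressionMatrix, labels: pd.Series,
                        fdr_cut: float = 0.05, lfc_cut: float = 1.0,
                        ) -> pd.DataFrame:
    """One-vs-rest moderated-t DE across subtypes; union over subtypes.

    Returns the per-gene best (smallest-fdr) contrast with its subtype.
    """
    labels = labels.reindex(expr.sample_ids)
    tables = []
    for subtype in pd.unique(labels):
        in_group = labels == subtype
        if in_group.sum() < 2 or (~in_group).sum() < 2:
            warnings.warn(f"subtype {subtype} too small for DE; skipped")
            continue
        t = ExpressionMatrix(expr.values.loc[:, in_group.to_numpy()], expr.unit)
        r = ExpressionMatrix(expr.values.loc[:, (~in_group).to_numpy()], expr.unit)
        tab = moderated_t_deg(t, r, fdr_cut, lfc_cut)
        tab["subtype"] = subtype
        tables.append(tab)
    merged = pd.concat(tables)
    merged = merged.sort_values("fdr").groupby(level=0).first()
    return merged
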