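"""Gene-set enrichment, over-representation, and MAF-based mutation analysis.

GSEA follows the weighted Kolmogorov-Smirnov running-sum formulation with
phenotype permutation: genes are ranked by signal-to-noise between the two
phenotype classes, the enrichment score (ES) of a set is the maximum
deviation of the running sum, the normalized score (NES) divides the ES by
the mean of same-sign permutation ESs, and nominal p / FDR q come from the
permutation null.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .io import read_gmt, write_gmt  # noqa: F401  (GMT IO re-exported here)
from .survstats import logrank_test

#: Non-silent variant classifications counted toward mutation burden.
NONSILENT_CLASSES = frozenset({
    "Missense_Mutation", "Nonsense_Mutation", "Nonstop_Mutation",
    "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins",
    "Splice_Site", "Translation_Start_Site",
})

KNOWN_CLASSES = NONSILENT_CLASSES | {
    "Silent", "Intron", "3'UTR", "5'UTR", "3'Flank", "5'Flank", "IGR", "RNA",
}


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------

def signal_to_noise(expr: np.ndarray, is_class1: np.ndarray) -> np.ndarray:
    """Per-gene signal-to-noise ratio (class1 minus class0).

    Standard deviations are floored at 20% of the absolute class mean (0.2
    when the mean is zero), the usual stabilization for small classes.
    """
    x1 = expr[:, is_class1]
    x0 = expr[:, ~is_class1]
    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    s1, s0 = x1.std(axis=1, ddof=1), x0.std(axis=1, ddof=1)

    def _fix(s, m):
        floor = np.where(m != 0, 0.2 * np.abs(m), 0.2)
        return np.maximum(s, floor)

    return (m1 - m0) / (_fix(s1, m1) + _fix(s0, m0))


def _es_from_positions(sorted_metric: np.ndarray, q: np.ndarray, n: int,
                       weight: float) -> float:
    """ES given sorted hit positions ``q`` in a descending ranking.

    Only the running-sum values at and just before each hit are needed: the
    sum decreases linearly between hits, so extrema occur at hit boundaries.
    """
    nh = q.size
    if weight == 0:
        w = np.ones(nh)
    else:
        w = np.abs(sorted_metric[q]) ** weight
    total = w.sum()
    if total == 0:
        w = np.ones(nh)
        total = float(nh)
    miss = 1.0 / (n - nh)
    cum_hit = np.cumsum(w) / total
    k = np.arange(1, nh + 1)
    at_hit = cum_hit - (q + 1 - k) * miss            # value right after hit k
    before_hit = np.concatenate([[0.0], cum_hit[:-1]]) - (q - (k - 1)) * miss
    es_pos = float(at_hit.max())
    es_neg = float(before_hit.min())
    return es_pos if es_pos >= -es_neg else es_neg


def _enrichment_score(metric: np.ndarray, hit_idx: np.ndarray,
                      weight: float) -> float:
    """ES of one gene set against one ranking."""
    return _es_all_sets(metric, [hit_idx], weight)[0]


def _es_all_sets(metric: np.ndarray, sets_idx: list[np.ndarray],
                 weight: float) -> np.ndarray:
    n = metric.size
    order = np.argsort(-metric, kind="mergesort")
    pos = np.empty(n, dtype=int)
    pos[order] = np.arange(n)
    sorted_metric = metric[order]
    return np.array([
        _es_from_positions(sorted_metric, np.sort(pos[idx]), n, weight)
        for idx in sets_idx
    ])


def gsea(expr: ExpressionMatrix, phenotype: pd.Series,
         sets: dict[str, list[str]], n_perm: int = 1000, weight: float = 1.0,
         seed: int = 0, min_size: int = 15, max_size: int = 500,
         ) -> pd.DataFrame:
    """Phenotype-permutation GSEA.

    ``phenotype`` is a binary per-sample series (the positive class is the
    larger label after sorting, e.g. "high" vs "low" sorts to high = class1
    when labels are {"high","low"}: lexicographically "low" > "high", so pass
    booleans or 0/1 for full control; the positive class is ``max(labels)``).

    Returns a set-indexed DataFrame with es, nes, nominal_p, fdr_q and
    direction ("high-enriched" for positive NES on the positive class).
    """
    phenotype = phenotype.reindex(expr.sample_ids)
    labels = sorted(pd.unique(phenotype.dropna()))
    if len(labels) != 2:
        raise ValueError("phenotype must be binary")
    is_pos = (phenotype == labels[-1]).to_numpy()
    if is_pos.sum() < 3 or (~is_pos).sum() < 3:
        raise ValueError("each phenotype class needs >= 3 samples")

    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    sets_idx, names = [], []
    for name, genes in sets.items():
        idx = np.array([gene_index[g] for g in genes if g in gene_index],
                       dtype=int)
        if not min_size <= idx.size <= max_size:
            warnings.warn(f"gene set {name!r} has {idx.size} usable genes; "
                          "skipped")
            continue
        sets_idx.append(idx)
        names.append(name)
    if not names:
        raise ValueError("no gene set within the size bounds")

    X = expr.values.to_numpy(dtype=float)
    metric = signal_to_noise(X, is_pos)
    es_obs = _es_all_sets(metric, sets_idx, weight)

    rng = np.random.default_rng(seed)
    es_perm = np.empty((n_perm, len(names)))
    perm_labels = is_pos.copy()
    for p in range(n_perm):
        rng.shuffle(perm_labels)
        es_perm[p] = _es_all_sets(signal_to_noise(X, perm_labels),
                                  sets_idx, weight)

    nes = np.empty(len(names))
    nominal_p = np.empty(len(names))
    nes_perm_all: list[np.ndarray] = []
    for j, es in enumerate(es_obs):
        perm = es_perm[:, j]
        same = perm[np.sign(perm) == np.sign(es)] if es != 0 else perm
        mean_abs = np.abs(same).mean() if same.size else np.abs(perm).mean()
        if mean_abs == 0:
            mean_abs = 1.0
        nes[j] = es / mean_abs
        nominal_p[j] = ((1 + np.sum(np.abs(same) >= abs(es)))
                        / (1 + same.size))
        # permutation NES for the FDR procedure, normalized per set and sign
        pos_mean = np.abs(perm[perm > 0]).mean() if (perm > 0).any() else 1.0
        neg_mean = np.abs(perm[perm < 0]).mean() if (perm < 0).any() else 1.0
        nes_perm_all.append(np.where(perm >= 0, perm / pos_mean,
                                     perm / neg_mean))
    nes_perm = np.concatenate(nes_perm_all)

    fdr_q = np.empty(len(names))
    for j, v in enumerate(nes):
        if v >= 0:
            num_pool = nes_perm[nes_perm >= 0]
            obs_pool = nes[nes >= 0]
            num = np.mean(num_pool >= v) if num_pool.size else 0.0
            den = np.mean(obs_pool >= v)
        else:
            num_pool = nes_perm[nes_perm < 0]
            obs_pool = nes[nes < 0]
            num = np.mean(num_pool <= v) if num_pool.size else 0.0
            den = np.mean(obs_pool <= v)
        fdr_q[j] = min(1.0, num / den) if den > 0 else 1.0

    return pd.DataFrame({
        "es": es_obs,
        "nes": nes,
        "nominal_p": nominal_p,
        "fdr_q": fdr_q,
        "direction": np.where(es_obs >= 0, "high-enriched", "low-enriched"),
    }, index=pd.Index(names, name="set"))


# ---------------------------------------------------------------------------
# Over-representation and Fisher tests
# ---------------------------------------------------------------------------

def ora_hypergeom(hit_genes, universe, sets: dict[str, list[str]],
                  adj_p_cut: float = 0.2) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation with BH adjustment."""
    hits = set(hit_genes)
    uni = set(universe)
    if not hits:
        raise ValueError("empty hit list")
    if not hits <= uni:
        raise ValueError("hit genes must be contained in the universe")
    rows = []
    for name, genes in sets.items():
        members = set(genes) & uni
        overlap = len(members & hits)
        # P(X >= overlap) for X ~ Hypergeom(N=|uni|, K=|members|, n=|hits|)
        p = float(stats.hypergeom.sf(overlap - 1, len(uni), len(members),
                                     len(hits)))
        rows.append((name, overlap, len(members), p))
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p"]
                       ).set_index("set")
    from .preprocess import bh_adjust
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["adj_p"] < adj_p_cut
    return out


def fisher_2x2(table) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table.

    Two-sided p sums the probabilities of all tables with the same margins
    whose probability does not exceed the observed one (minimum-likelihood
    rule); the odds ratio is ad/bc with 0/inf/nan conventions for zero cells.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("need a 2x2 table of nonnegative integers")
    a, b, c, d = t.ravel()
    _, p = stats.fisher_exact(t, alternative="two-sided")
    if b * c > 0:
        odds = (a * d) / (b * c)   # 0 when ad == 0
    elif a * d > 0:
        odds = np.inf
    else:
        odds = np.nan              # both products zero: OR undefined
    return float(odds), float(p)


# ---------------------------------------------------------------------------
# MAF utilities
# ---------------------------------------------------------------------------

def mutation_compare(maf: pd.DataFrame, groups: pd.Series,
                     p_cut: float = 0.01) -> pd.DataFrame:
    """Per-gene Fisher comparison of mutation frequency between two groups.

    ``groups`` maps sample barcode to "high"/"low". MAF barcodes without a
    group are dropped with a warning; genes mutated in zero mapped samples
    are excluded. Returns per-gene mutated counts, frequencies per group,
    odds ratio, p, and a flag at ``p < p_cut``.
    """
    levels = sorted(pd.unique(groups.dropna()))
    if len(levels) != 2:
        raise ValueError("groups must have exactly two levels")
    mapped = maf["Tumor_Sample_Barcode"].isin(groups.index)
    if (~mapped).any():
        warnings.warn(f"{int((~mapped).sum())} MAF rows with unmapped "
                      "barcodes dropped")
        maf = maf[mapped]
    n_by_group = groups.value_counts()
    n_hi = int(n_by_group.get("high", n_by_group.get(levels[-1], 0)))
    n_lo = int(n_by_group.get("low", n_by_group.get(levels[0], 0)))
    hi_label = "high" if "high" in levels else levels[-1]
    rows = []
    for gene, sub in maf.groupby("Hugo_Symbol"):
        barcodes = sub["Tumor_Sample_Barcode"].unique()
        g = groups.reindex(barcodes)
        mut_hi = int((g == hi_label).sum())
        mut_lo = len(barcodes) - mut_hi
        if mut_hi + mut_lo == 0:
            continue
        odds, p = fisher_2x2([[mut_hi, n_hi - mut_hi],
                              [mut_lo, n_lo - mut_lo]])
        rows.append((gene, mut_hi, mut_lo, mut_hi / max(n_hi, 1),
                     mut_lo / max(n_lo, 1), odds, p))
    out = pd.DataFrame(rows, columns=[
        "gene", "mutated_high", "mutated_low", "freq_high", "freq_low",
        "odds_ratio", "p"]).set_index("gene")
    out["differential"] = out["p"] < p_cut
    return out.sort_values("p")


def tmb_from_maf(maf: pd.DataFrame, samples=None) -> pd.Series:
    """Tumor mutational burden: non-silent variant count per sample.

    Samples listed in ``samples`` but absent from the MAF get 0. Unknown
    variant classifications are excluded with a warning.
    """
    vc = maf["Variant_Classification"]
    unknown = set(vc.unique()) - KNOWN_CLASSES
    if unknown:
        warnings.warn(f"unknown variant classifications excluded: {sorted(unknown)}")
    counted = maf[vc.isin(NONSILENT_CLASSES)]
    tmb = counted.groupby("Tumor_Sample_Barcode").size()
    if samples is not None:
        tmb = tmb.reindex(samples, fill_value=0)
    return tmb.rename("tmb").astype(int)


def stratify_combination(score_groups: pd.Series, marker: pd.Series,
                         records: pd.DataFrame,
                         marker_rule: str = "median",
                         response: pd.Series | None = None) -> dict:
    """Survival stratification by TMEscore group x a second biomarker.

    The marker is dichotomized at the cohort median by default; the combined
    labels feed an overall log-rank test (df = strata - 1). If a categorical
    therapy outcome is supplied (CR/PR/SD/PD), the responder proportion
    (CR/PR) per stratum is reported with a chi-square test.
    """
    marker = marker.reindex(score_groups.index)
    if marker.isna().any():
        raise ValueError("marker must be defined for all samples")
    if marker_rule == "median":
        cut = marker.median()
        marker_group = pd.Series(
            np.where(marker > cut, "marker-high", "marker-low"),
            index=marker.index)
    else:
        raise ValueError(f"unknown marker rule: {marker_rule}")
    combined = score_groups.astype(str) + "/" + marker_group
    strata = pd.unique(combined)
    if len(strata) < 4:
        warnings.warn("fewer than 4 nonempty strata; testing the remainder")
    recs = records.loc[combined.index]
    chi2, df, p = logrank_test(combined, recs)
    out = {
        "labels": combined.rename("stratum"),
        "logrank_chi2": chi2,
        "logrank_df": df,
        "logrank_p": p,
    }
    if response is not None:
        resp = response.reindex(combined.index)
        responder = resp.isin(["CR", "PR"])
        tab = pd.crosstab(combined, responder)
        out["response_table"] = tab
        out["response_rate"] = responder.groupby(combined).mean()
        if tab.shape == (len(strata), 2):
            _, p_resp, _, _ = stats.chi2_contingency(tab)
            out["response_p"] = float(p_resp)
    return out
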