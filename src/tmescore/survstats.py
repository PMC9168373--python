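"""Survival and association statistics: Kaplan-Meier, log-rank, Cox
proportional hazards, maximally selected rank cutpoints, Wilcoxon, Spearman.

Survival data is a DataFrame with positive ``time`` (days), binary ``event``
(1 = death) and optional covariate columns. Cox models are fit by partial
likelihood with Efron tie handling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    if len(records) == 0:
        raise ValueError("no survival records")
    if (records["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not records["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return records


@dataclass
class KMEstimate:
    """Product-limit estimate: step function plus median survival."""

    times: np.ndarray
    survival: np.ndarray
    median: float | None

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(records: pd.DataFrame) -> KMEstimate:
    """Kaplan-Meier estimator; median is the smallest t with S(t) <= 0.5,
    None if never reached."""
    _check_records(records)
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], records["event"])
    sf = kmf.survival_function_["KM_estimate"]
    times = sf.index.to_numpy(dtype=float)
    surv = sf.to_numpy(dtype=float)
    below = surv <= 0.5
    median = float(times[below][0]) if below.any() else None
    return KMEstimate(times, surv, median)


def logrank_test(groups: pd.Series | np.ndarray,
                 records: pd.DataFrame) -> tuple[float, int, float]:
    """Multi-group log-rank test. Returns (chi2, df, p)."""
    _check_records(records)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    df = len(labels) - 1
    if records["event"].sum() == 0:
        return 0.0, df, 1.0
    res = multivariate_logrank_test(records["time"], g, records["event"])
    chi2 = float(res.test_statistic)
    if not np.isfinite(chi2):
        return 0.0, df, 1.0
    return chi2, df, float(stats.chi2.sf(chi2, df))


def _logrank_uv(time: np.ndarray, event: np.ndarray,
                in_group1: np.ndarray) -> tuple[float, float]:
    """Observed-minus-expected and hypergeometric variance for two groups."""
    order = np.argsort(time, kind="mergesort")
    t, e, g = time[order], event[order], in_group1[order].astype(float)
    n_total = len(t)
    event_times = np.unique(t[e == 1])
    # counts at risk and deaths at each event time
    left = np.searchsorted(t, event_times, side="left")
    right = np.searchsorted(t, event_times, side="right")
    n_at_risk = n_total - left
    cum_g = np.concatenate([[0.0], np.cumsum(g)])
    n1_at_risk = cum_g[-1] - cum_g[left]
    ev = np.where(e == 1, 1.0, 0.0)
    cum_d = np.concatenate([[0.0], np.cumsum(ev)])
    cum_d1 = np.concatenate([[0.0], np.cumsum(ev * g)])
    d = cum_d[right] - cum_d[left]
    d1 = cum_d1[right] - cum_d1[left]
    frac = n1_at_risk / n_at_risk
    u = float(np.sum(d1 - d * frac))
    with np.errstate(invalid="ignore", divide="ignore"):
        v_terms = d * frac * (1 - frac) * (n_at_risk - d) / (n_at_risk - 1)
    v = float(np.nansum(v_terms))
    return u, v


@dataclass
class CoxFit:
    terms: list[str]
    coef: pd.Series
    hr: pd.Series
    ci95: pd.DataFrame  # columns lo, hi
    p: pd.Series
    converged: bool


def cox_fit(records: pd.DataFrame, terms: list[str]) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties) with Wald CIs and p-values.

    Categorical covariates are expanded to treatment-coded dummies. A
    monotone likelihood (perfect separation) is reported via
    ``converged=False`` rather than raising.
    """
    _check_records(records)
    if records["event"].sum() == 0:
        raise ValueError("need at least one event")
    df = records[["time", "event", *terms]].copy()
    df = pd.get_dummies(df, columns=[t for t in terms
                                     if df[t].dtype == object
                                     or isinstance(df[t].dtype, pd.CategoricalDtype)],
                        drop_first=True)
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fitter.fit(df, duration_col="time", event_col="event")
        converged = not any("failed to converge" in str(w.message)
                            for w in caught)
    except ConvergenceError:
        # refit with a ridge whisper purely to report direction diagnostics
        fitter = CoxPHFitter(penalizer=1e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="time", event_col="event")
        converged = False
    summary = fitter.summary
    coef = summary["coef"]
    if not converged or coef.abs().max() > 20:
        converged = False
    return CoxFit(
        terms=list(summary.index),
        coef=coef,
        hr=summary["exp(coef)"],
        ci95=pd.DataFrame({"lo": summary["exp(coef) lower 95%"],
                           "hi": summary["exp(coef) upper 95%"]}),
        p=summary["p"],
        converged=converged,
    )


def cox_score_test(records: pd.DataFrame, term: str) -> tuple[float, float]:
    """Partial-likelihood score test of a single covariate at beta = 0.

    Uses the Efron tie convention; with untied event times this equals the
    two-group log-rank chi-square for a binary covariate. Returns (chi2, p).
    """
    _check_records(records)
    x = records[term].to_numpy(dtype=float)
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    order = np.argsort(time, kind="mergesort")
    t, e, xv = time[order], event[order], x[order]
    n = len(t)
    u = 0.0
    info = 0.0
    event_times = np.unique(t[e == 1])
    for et in event_times:
        at_risk = t >= et
        dead = (t == et) & (e == 1)
        d = int(dead.sum())
        s_r, q_r, n_r = xv[at_risk].sum(), (xv[at_risk] ** 2).sum(), at_risk.sum()
        s_d, q_d = xv[dead].sum(), (xv[dead] ** 2).sum()
        u += s_d
        for ell in range(d):
            f = ell / d
            denom = n_r - ell
            mean_l = (s_r - f * s_d) / denom
            u -= mean_l
            info += (q_r - f * q_d) / denom - mean_l ** 2
    if info <= 0:
        return 0.0, 1.0
    chi2 = u * u / info
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def optimal_cutpoint(score: pd.Series, records: pd.DataFrame,
                     minprop: float = 0.1) -> tuple[float, float]:
    """Maximally selected rank statistic cutpoint for a continuous score.

    Candidate cutoffs are midpoints between adjacent distinct score values
    that leave at least ``minprop`` of the samples on each side; the returned
    cutoff maximizes the standardized two-group log-rank statistic, ties
    broken toward the median score.
    """
    _check_records(records)
    score = score.reindex(records.index)
    s = score.to_numpy(dtype=float)
    if np.ptp(s) == 0:
        raise ValueError("all scores equal; no cutpoint exists")
    if records["event"].sum() < 1:
        raise ValueError("no events; cutpoint undefined")
    n = len(s)
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    lower = np.quantile(s, minprop)
    upper = np.quantile(s, 1.0 - minprop)
    cands = mids[(mids >= lower) & (mids <= upper)]
    if cands.size == 0:
        raise ValueError("no candidate cutoffs satisfy minprop")
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    med = np.median(s)
    best_cut, best_stat = None, -np.inf
    for c in cands:
        high = s > c
        if min(high.sum(), n - high.sum()) < max(1, int(minprop * n)):
            continue
        u, v = _logrank_uv(time, event, high)
        z = abs(u) / np.sqrt(v) if v > 0 else 0.0
        if (z > best_stat + 1e-12
                or (abs(z - best_stat) <= 1e-12 and best_cut is not None
                    and abs(c - med) < abs(best_cut - med))):
            best_cut, best_stat = float(c), float(z)
    return best_cut, best_stat


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when the smaller sample has <= 8 observations and
    there are no ties; normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no rank correlation")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
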