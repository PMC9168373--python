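"""Resampling-based consensus clustering with CDF-area model selection.

For each candidate k, items are repeatedly subsampled (default 100 iterations
at an 80% resample rate), hierarchically clustered, and the fraction of
co-sampled iterations in which two items land in the same cluster forms the
consensus matrix. The cluster number is chosen from the relative gain in
area under the empirical CDF of consensus values.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .containers import ConsensusResult


def _distance(data: np.ndarray, metric: str) -> np.ndarray:
    """Condensed pairwise distances; 'pearson' means 1 - Pearson correlation."""
    if metric == "pearson":
        z = data - data.mean(axis=1, keepdims=True)
        sd = z.std(axis=1, keepdims=True)
        z = z / np.where(sd > 0, sd, 1.0)
        corr = np.clip((z @ z.T) / z.shape[1], -1.0, 1.0)
        return squareform(1.0 - corr, checks=False)
    return pdist(data, metric=metric)


def consensus_matrix(data: np.ndarray, k: int, iterations: int = 100,
                     resample_frac: float = 0.8, distance: str = "euclidean",
                     linkage_method: str = "average",
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Co-clustering frequency matrix over resampled hierarchical clusterings.

    consensus(i, j) = (# iterations i and j co-clustered) / (# co-sampled);
    never co-sampled pairs are set to 0 with a warning; diagonal forced to 1.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"need 2 <= k < n_items, got k={k}, n={n}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    m = int(np.ceil(resample_frac * n))
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    for _ in range(iterations):
        idx = rng.choice(n, size=m, replace=False)
        sub = data[idx]
        labels = fcluster(linkage(_distance(sub, distance),
                                  method=linkage_method),
                          t=k, criterion="maxclust")
        co = (labels[:, None] == labels[None, :]).astype(float)
        together[np.ix_(idx, idx)] += co
        sampled[np.ix_(idx, idx)] += 1.0
    never = sampled == 0
    np.fill_diagonal(never, False)
    if never.any():
        warnings.warn(f"{int(never.sum() // 2)} item pairs never co-sampled; "
                      "their consensus is set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        cm = np.where(sampled > 0, together / np.maximum(sampled, 1), 0.0)
    cm = (cm + cm.T) / 2.0
    np.fill_diagonal(cm, 1.0)
    return cm


def cdf_area(cm: np.ndarray, grid_points: int = 101) -> tuple[np.ndarray, float]:
    """Empirical CDF of upper-triangle consensus values and its trapezoid area."""
    cm = np.asarray(cm, dtype=float)
    vals = cm[np.triu_indices_from(cm, k=1)]
    grid = np.linspace(0.0, 1.0, grid_points)
    cdf = np.searchsorted(np.sort(vals), grid, side="right") / vals.size
    area = float(np.trapezoid(cdf, grid))
    return cdf, area


def select_k(areas: dict[int, float], delta_threshold: float = 0.1) -> int:
    """Choose k by the relative CDF-area gain rule.

    Delta(k) = (A(k) - A(k-1)) / A(k-1) for k > k_min, Delta(k_min) = A(k_min);
    chosen k is the largest with Delta(k) >= threshold. Pathological
    (non-monotone) area sequences fall back to the argmax of Delta with a
    warning.
    """
    ks = sorted(areas)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("areas must cover consecutive k values")
    deltas: dict[int, float] = {ks[0]: areas[ks[0]]}
    for k_prev, k in zip(ks, ks[1:]):
        prev = areas[k_prev]
        deltas[k] = (areas[k] - prev) / prev if prev > 0 else np.inf
    passing = [k for k in ks if deltas[k] >= delta_threshold]
    if passing:
        return max(passing)
    warnings.warn("no k reaches the delta-area threshold; "
                  "falling back to the largest relative gain")
    return max(deltas, key=lambda k: deltas[k])


def assign_clusters(cm: np.ndarray, k: int,
                    item_ids=None) -> pd.Series:
    """Final partition: average-linkage clustering of 1 - consensus, cut at k,
    cluster ids renumbered 1..k by decreasing size."""
    cm = np.asarray(cm, dtype=float)
    n = cm.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of items")
    dist = squareform(1.0 - cm, checks=False)
    raw = fcluster(linkage(dist, method="average"), t=k, criterion="maxclust")
    if len(np.unique(raw)) < k:
        raise ValueError(f"consensus matrix supports fewer than {k} clusters")
    order = pd.Series(raw).value_counts().index  # largest first
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([remap[r] for r in raw])
    index = item_ids if item_ids is not None else pd.RangeIndex(n)
    return pd.Series(labels, index=index, name="cluster")


def consensus_cluster(data, k_range=range(2, 8), iterations: int = 100,
                      resample_frac: float = 0.8, distance: str = "euclidean",
                      linkage_method: str = "average", seed: int = 0,
                      delta_threshold: float = 0.1,
                      force_k: int | None = None) -> ConsensusResult:
    """Run the full consensus-clustering sweep and pick k.

    ``data`` may be a DataFrame (rows are items) or ndarray; ``force_k``
    overrides the CDF-area rule (manual inspection override).
    """
    if isinstance(data, pd.DataFrame):
        item_ids = data.index
        arr = data.to_numpy(dtype=float)
    else:
        arr = np.asarray(data, dtype=float)
        item_ids = pd.RangeIndex(arr.shape[0])
    rng = np.random.default_rng(seed)
    matrices: dict[int, np.ndarray] = {}
    areas: dict[int, float] = {}
    for k in k_range:
        cm = consensus_matrix(arr, k, iterations, resample_frac, distance,
                              linkage_method, rng)
        matrices[k] = cm
        areas[k] = cdf_area(cm)[1]
    chosen = force_k if force_k is not None else select_k(areas, delta_threshold)
    labels = assign_clusters(matrices[chosen], chosen, item_ids)
    return ConsensusResult(list(k_range), matrices, areas, chosen, labels)
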