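"""Two-tier grouping of co-behaving signals within each temporal class.

Tier 1 clusters the autocorrelation vectors (agglomerative, complete
linkage, Euclidean) and captures the dominant temporal pattern; tier 2
re-clusters the unit-norm value series Q inside each tier-1 group and
separates variations the autocorrelations cannot see — in particular sign
flips, since ρ is invariant to negating the series.  Cluster counts are
chosen by mean-silhouette maximization over k = 2..min(10, n−1), ties
broken toward the smaller k; sets of fewer than three members form a
single group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score
from sklearn.metrics.pairwise import nan_euclidean_distances


@dataclass
class Grouping:
    class_label: str
    members: list[str]
    group: dict[str, int]
    subgroup: dict[str, tuple[int, int]]   # (group, subgroup within group)
    k_tier1: int
    k_tier2: dict[int, int]
    silhouette_tier1: dict[int, float] = field(default_factory=dict)


def _complete_linkage(dist: np.ndarray, k: int) -> np.ndarray:
    model = AgglomerativeClustering(n_clusters=k, metric="precomputed",
                                    linkage="complete")
    return model.fit_predict(dist)


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by order of first appearance (input-order stable)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def silhouette_select_k(distance_matrix: np.ndarray,
                        k_min: int = 2,
                        k_max: int | None = None
                        ) -> tuple[int, dict[int, float]]:
    """Mean-silhouette argmax over candidate k for complete-linkage cuts.

    Returns (k, {k: score}); n < 3 yields k = 1 with no scores.  Exact ties
    (including all-equidistant inputs) resolve to the smallest k.
    """
    n = distance_matrix.shape[0]
    if n < 3:
        return 1, {}
    if k_max is None:
        k_max = min(10, n - 1)
    k_max = max(k_min, min(k_max, n - 1))
    scores: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        labels = _complete_linkage(distance_matrix, k)
        if len(np.unique(labels)) < 2:
            continue
        scores[k] = float(silhouette_score(distance_matrix, labels,
                                           metric="precomputed"))
    if not scores:
        return 1, scores
    best = max(scores, key=lambda k: (scores[k], -k))
    return best, scores


def two_tier_cluster(members: list[str],
                     autocorrs: np.ndarray,
                     unit_series: np.ndarray,
                     class_label: str = "") -> Grouping:
    """Group one temporal class by autocorrelation shape, then subgroup by
    signal values.

    ``autocorrs`` is (n, lags) without NaN; ``unit_series`` is (n, N) on the
    subject grid and may hold NaN at missing visits (distances are then
    NaN-aware Euclidean over co-observed stamps).
    """
    n = len(members)
    if n == 0:
        raise ValueError("empty class")
    if autocorrs.shape[0] != n or unit_series.shape[0] != n:
        raise ValueError("member/matrix size mismatch")
    if n == 1:
        return Grouping(class_label, list(members), {members[0]: 0},
                        {members[0]: (0, 0)}, 1, {0: 1})

    d1 = squareform(pdist(autocorrs, metric="euclidean"))
    k1, sil1 = silhouette_select_k(d1)
    groups = (_canonical(_complete_linkage(d1, k1)) if k1 > 1
              else np.zeros(n, dtype=int))

    group_map = {m: int(g) for m, g in zip(members, groups)}
    sub_map: dict[str, tuple[int, int]] = {}
    k2: dict[int, int] = {}
    for g in range(groups.max() + 1):
        idx = np.flatnonzero(groups == g)
        if len(idx) == 1:
            sub_map[members[idx[0]]] = (g, 0)
            k2[g] = 1
            continue
        d2 = nan_euclidean_distances(unit_series[idx])
        np.fill_diagonal(d2, 0.0)
        kg, _ = silhouette_select_k(d2)
        subs = (_canonical(_complete_linkage(d2, kg)) if kg > 1
                else np.zeros(len(idx), dtype=int))
        k2[g] = int(subs.max()) + 1
        for local, i in enumerate(idx):
            sub_map[members[i]] = (g, int(subs[local]))

    return Grouping(class_label, list(members), group_map, sub_map,
                    int(groups.max()) + 1, k2, sil1)


def subgroup_mean_series(member_values: np.ndarray,
                         times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-timepoint mean over members, skipping missing values.

    Returns (times, mean); a stamp missing in every member yields NaN.
    """
    vals = np.atleast_2d(np.asarray(member_values, float))
    if vals.shape[1] != len(times):
        raise ValueError("values/times length mismatch")
    observed = ~np.isnan(vals)
    counts = observed.sum(axis=0)
    sums = np.where(observed, vals, 0.0).sum(axis=0)
    mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return np.asarray(times, float), mean
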