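"""Cross-subject similarity network from periodogram correlations.

For every omic i shared by a pair of subjects (p, q), the Spearman
correlation of their periodograms (evaluated on the cohort-wide common time
frame, so the frequency grids coincide) enters the matrix S_i.  A bootstrap
null of value-resampled series fixes a significance cutoff s_c at the 0.99
quantile of null pair correlations; the indicator matrices

    [R_i]_pq = 1  if [S_i]_pq > s_c  else 0

sum to the weighted adjacency A = Σ_i R_i: subjects are connected when at
least one omic behaves similarly, with edge weight the number of such omics.

Communities are detected by a one-dimensional spectral embedding of A (the
leading non-trivial singular direction of the degree-normalized adjacency)
followed by k-means on the coordinates; the number of communities is chosen
by silhouette maximization, with the k-means inertia curve reported as an
elbow diagnostic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .core_model import MultiOmicsDataset
from .preprocess import CommonTimeFrame
from .spectral_classify import (MIN_OBSERVED, _lombscargle_batch,
                                _normalize_rows, frame_frequencies)

logger = logging.getLogger(__name__)


@dataclass
class SimilarityNetwork:
    subjects: list[str]
    adjacency: np.ndarray                 # integer, symmetric, zero diagonal
    s_c: float
    indicator_matrices: dict[str, np.ndarray] = field(default_factory=dict)

    def edge_list(self) -> list[tuple[str, str, int]]:
        edges = []
        n = len(self.subjects)
        for p in range(n):
            for q in range(p + 1, n):
                w = int(self.adjacency[p, q])
                if w > 0:
                    edges.append((self.subjects[p], self.subjects[q], w))
        return edges

    def to_networkx(self):
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(self.subjects)
        g.add_weighted_edges_from(self.edge_list())
        return g


@dataclass
class CommunityAssignment:
    communities: dict[str, int]
    k: int
    silhouettes: dict[int, float]
    inertias: dict[int, float]            # elbow diagnostic
    embedding: np.ndarray


# ---------------------------------------------------------------------------
# Periodograms on the common frame
# ---------------------------------------------------------------------------

def periodogram_matrix(ds: MultiOmicsDataset, frame: CommonTimeFrame
                       ) -> dict[tuple[str, str], np.ndarray]:
    """Periodogram power vector for every eligible (subject, omic) series,
    evaluated on the common frame's frequency grid (equal length for all).

    Constant or too-short series are skipped with a log entry.
    """
    freqs, _ = frame_frequencies(frame)
    out: dict[tuple[str, str], np.ndarray] = {}
    groups: dict[tuple, list[tuple[str, str]]] = {}
    for key, ts in ds.signals.items():
        if ts.n_observed < MIN_OBSERVED or np.ptp(ts.observed_values) == 0:
            logger.debug("skipping %s: constant or < %d observed",
                         key, MIN_OBSERVED)
            continue
        groups.setdefault(tuple(ts.observed_times.tolist()), []).append(key)
    for t_key, keys in groups.items():
        t_obs = np.array(t_key)
        raw = np.stack([ds.signals[k].observed_values for k in keys])
        _, q, ok = _normalize_rows(raw)
        powers = _lombscargle_batch(t_obs, q, freqs)
        for r, key in enumerate(keys):
            if ok[r]:
                out[key] = powers[r]
    return out


# ---------------------------------------------------------------------------
# Null cutoff for Spearman similarity
# ---------------------------------------------------------------------------

def spearman_cutoff(ds: MultiOmicsDataset, frame: CommonTimeFrame,
                    B: int = 50_000, q: float = 0.99,
                    seed: int | None = None) -> float:
    """s_c: the q-quantile of Spearman correlations between periodograms of
    independently value-resampled null series (paired without replacement
    within each draw); deterministic given the seed."""
    pool = [ts for ts in ds.signals.values()
            if ts.n_observed >= MIN_OBSERVED and np.ptp(ts.observed_values) > 0]
    if len(pool) < 2:
        raise ValueError("pool too small to form null pairs")
    freqs, _ = frame_frequencies(frame)
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(pool), size=B)

    null_p = np.empty((B, len(freqs)))
    for i, ts in enumerate(pool):
        rows = np.flatnonzero(draws == i)
        if rows.size == 0:
            continue
        vals, t_obs = ts.observed_values, ts.observed_times
        raw = rng.choice(vals, size=(rows.size, len(vals)), replace=True)
        _, qn, ok = _normalize_rows(raw)
        while not ok.all():
            bad = np.flatnonzero(~ok)
            raw[bad] = rng.choice(vals, size=(bad.size, len(vals)), replace=True)
            _, qn, ok = _normalize_rows(raw)
        null_p[rows] = _lombscargle_batch(t_obs, qn, freqs)

    ranks = rankdata(null_p, axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    ranks /= np.linalg.norm(ranks, axis=1, keepdims=True)
    half = B // 2
    corr = (ranks[:half] * ranks[half:2 * half]).sum(axis=1)
    return float(np.quantile(corr, q))


# ---------------------------------------------------------------------------
# Network construction (A = Σ_i R_i)
# ---------------------------------------------------------------------------

def build_network(periodograms: dict[tuple[str, str], np.ndarray],
                  s_c: float,
                  retain_indicators: bool = True) -> SimilarityNetwork:
    """Sum per-omic indicator matrices R_i = [S_i > s_c] into the weighted
    adjacency.  Only omics observed in both subjects of a pair contribute;
    the comparison is strictly greater-than."""
    subjects = sorted({s for (s, _) in periodograms})
    index = {s: i for i, s in enumerate(subjects)}
    n = len(subjects)
    if n < 2:
        raise ValueError("need ≥ 2 subjects with periodograms")

    by_omic: dict[str, list[tuple[int, np.ndarray]]] = {}
    for (s, omic), p in periodograms.items():
        by_omic.setdefault(omic, []).append((index[s], p))

    adjacency = np.zeros((n, n), dtype=int)
    indicators: dict[str, np.ndarray] = {}
    for omic, entries in by_omic.items():
        if len(entries) < 2:
            continue
        idx = np.array([e[0] for e in entries])
        mat = np.stack([e[1] for e in entries])
        ranks = rankdata(mat, axis=1)
        ranks -= ranks.mean(axis=1, keepdims=True)
        ranks /= np.linalg.norm(ranks, axis=1, keepdims=True)
        s_mat = ranks @ ranks.T
        r_local = s_mat > s_c
        np.fill_diagonal(r_local, False)
        r_full = np.zeros((n, n), dtype=bool)
        r_full[np.ix_(idx, idx)] = r_local
        adjacency += r_full
        if retain_indicators and r_full.any():
            indicators[omic] = r_full
    return SimilarityNetwork(subjects=subjects, adjacency=adjacency, s_c=s_c,
                             indicator_matrices=indicators)


# ---------------------------------------------------------------------------
# Community detection
# ---------------------------------------------------------------------------

def _spectral_embedding_1d(a: np.ndarray) -> np.ndarray:
    """One-dimensional spectral embedding of a weighted adjacency matrix.

    Coordinates are the leading non-trivial eigenvector of the
    degree-normalized adjacency D^{-1/2} A D^{-1/2} (a rank-one truncated
    SVD after removing the Perron direction, which is determined by node
    degrees alone and carries no partition information).
    """
    d = a.sum(axis=1).astype(float)
    d[d == 0] = 1.0
    dn = 1.0 / np.sqrt(d)
    m = dn[:, None] * a * dn[None, :]
    vals, vecs = np.linalg.eigh(m)
    if a.shape[0] > 1 and vals[-2] <= 1e-10:
        # no assortative direction beyond the trivial one (e.g. all
        # subjects equivalent): flat embedding -> single community
        return np.zeros(a.shape[0])
    v = vecs[:, -2] if a.shape[0] > 1 else vecs[:, -1]
    if v[np.argmax(np.abs(v))] < 0:  # deterministic sign convention
        v = -v
    return v


def detect_communities(net: SimilarityNetwork, k: int | None = None,
                       k_max: int = 8, seed: int = 0,
                       n_restarts: int = 10) -> CommunityAssignment:
    """One-dimensional spectral embedding of A followed by k-means.

    If k is not given it is chosen by silhouette argmax over
    2..min(k_max, n−1) (ties toward smaller k); the inertia curve is kept as
    the elbow diagnostic.  A zero network puts every node in its own
    community; an embedding with no spread collapses to one community.
    """
    a = net.adjacency
    n = a.shape[0]
    if n < 2:
        raise ValueError("need ≥ 2 nodes")
    if not a.any():
        warnings.warn("all-zero network: every node its own community",
                      stacklevel=2)
        return CommunityAssignment(
            {s: i for i, s in enumerate(net.subjects)}, n, {}, {},
            np.zeros(n))

    lead = _spectral_embedding_1d(a.astype(float))
    emb = lead.reshape(-1, 1)

    if np.ptp(lead) < 1e-10:     # all subjects equivalent
        return CommunityAssignment({s: 0 for s in net.subjects}, 1, {}, {},
                                   lead)

    def fit(kk: int):
        km = KMeans(n_clusters=kk, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(emb)
        return labels, float(km.inertia_)

    silhouettes: dict[int, float] = {}
    inertias: dict[int, float] = {}
    if k is None:
        candidates = range(2, max(3, min(k_max, n - 1) + 1))
        fits = {}
        for kk in candidates:
            labels, inertia = fit(kk)
            if len(np.unique(labels)) < 2:
                continue
            fits[kk] = labels
            inertias[kk] = inertia
            silhouettes[kk] = float(silhouette_score(emb, labels))
        k = max(silhouettes, key=lambda kk: (silhouettes[kk], -kk))
        labels = fits[k]
    else:
        labels, inertia = fit(k)
        inertias[k] = inertia

    # canonical labels: by order of first appearance along the subject list
    mapping: dict[int, int] = {}
    comm: dict[str, int] = {}
    for s, lab in zip(net.subjects, labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        comm[s] = mapping[lab]
    return CommunityAssignment(comm, int(k), silhouettes, inertias, lead)
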