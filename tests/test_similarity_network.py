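"""Subject-similarity network: periodograms on the common frame, the
Spearman null cutoff, Eq.-style adjacency and community detection."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from chronomics import (MultiOmicsDataset, SimilarityNetwork, SyntheticConfig,
                        build_network, common_timeframe, detect_communities,
                        generate_cohort, periodogram_matrix, spearman_cutoff)
from conftest import make_series


@pytest.fixture(scope="module")
def community_cohort():
    cfg = SyntheticConfig(n_subjects=12,
                          n_omics_per_modality={"transcript": 60},
                          visits_per_subject=(10, 18),
                          frac_lag_responders={}, frac_spike_max=0.0,
                          frac_spike_min=0.0, n_communities=2,
                          n_shared_omics=25, missing_fraction=0.0, seed=17)
    return generate_cohort(cfg)


class TestPeriodogramMatrix:
    def test_identical_series_identical_periodograms(self):
        ds = MultiOmicsDataset()
        times = (0.0, 28.0, 56.0, 84.0, 112.0, 140.0)
        values = (0.5, 1.8, -0.3, 0.9, 2.2, -1.0)
        ds.add(make_series(subject="a", times=times, values=values))
        ds.add(make_series(subject="b", times=times, values=values))
        pg = periodogram_matrix(ds, common_timeframe(ds))
        np.testing.assert_array_equal(pg[("a", "g1")], pg[("b", "g1")])

    def test_defined_despite_missing_stamps(self):
        ds = MultiOmicsDataset()
        ds.add(make_series(subject="a",
                           times=(0.0, 28.0, 56.0, 84.0, 112.0, 140.0),
                           values=(0.5, 1.8, -0.3, 0.9, 2.2, -1.0)))
        ds.add(make_series(subject="b", times=(0.0, 28.0, 84.0, 140.0),
                           values=(1.0, -0.5, 0.7, 0.2)))
        frame = common_timeframe(ds)
        pg = periodogram_matrix(ds, frame)
        assert len(pg[("a", "g1")]) == len(pg[("b", "g1")])

    def test_constant_series_skipped(self):
        ds = MultiOmicsDataset()
        ds.add(make_series(subject="a",
                           times=(0.0, 28.0, 56.0, 84.0, 112.0),
                           values=(1.0, 2.0, 0.5, 1.5, 0.8)))
        ds.add(make_series(subject="b", omic="flat",
                           times=(0.0, 28.0, 56.0, 84.0, 112.0),
                           values=(2.0, 2.0, 2.0, 2.0, 2.0)))
        pg = periodogram_matrix(ds, common_timeframe(ds))
        assert ("b", "flat") not in pg
        assert ("a", "g1") in pg

    def test_shared_template_high_spearman(self, community_cohort):
        ds, _, truth = community_cohort
        frame = common_timeframe(ds)
        pg = periodogram_matrix(ds, frame)
        omic = truth.template_omics[0][0]
        members = [s for s, c in truth.communities.items() if c == 0][:4]
        corrs = [spearmanr(pg[(a, omic)], pg[(b, omic)]).statistic
                 for i, a in enumerate(members) for b in members[i + 1:]]
        others = [s for s, c in truth.communities.items() if c == 1][:4]
        cross = [spearmanr(pg[(a, omic)], pg[(b, omic)]).statistic
                 for a in members[:2] for b in others]
        assert np.mean(corrs) > np.mean(cross)
        assert np.mean(corrs) > 0.4


class TestSpearmanCutoff:
    def test_deterministic_and_in_range(self, community_cohort):
        ds, _, _ = community_cohort
        frame = common_timeframe(ds)
        s1 = spearman_cutoff(ds, frame, B=2000, seed=9)
        s2 = spearman_cutoff(ds, frame, B=2000, seed=9)
        assert s1 == s2
        assert -1.0 <= s1 <= 1.0

    def test_matches_permutation_null_quantile(self):
        """Under the null the two periodogram rank vectors are independent,
        so the Spearman null is the exact permutation distribution."""
        ds = MultiOmicsDataset()
        rng = np.random.default_rng(11)
        times = np.arange(21.0) * 28  # frame of 21 stamps -> m = 10 bins
        for j in range(30):
            ds.add(make_series(omic=f"g{j}", times=tuple(times),
                               values=tuple(rng.normal(size=21))))
        frame = common_timeframe(ds)
        s_c = spearman_cutoff(ds, frame, B=20_000, q=0.99, seed=3)

        m = 10
        base = np.arange(m, dtype=float)
        sims = np.empty(20_000)
        for i in range(len(sims)):
            sims[i] = spearmanr(base, rng.permutation(m)).statistic
        assert abs(s_c - np.quantile(sims, 0.99)) < 0.06

    def test_pool_too_small_errors(self):
        ds = MultiOmicsDataset()
        ds.add(make_series(values=(1.0, 2.0, 0.5, 1.5)))
        with pytest.raises(ValueError, match="pool"):
            spearman_cutoff(ds, common_timeframe(ds), B=1000, seed=0)


def _pg_from_vectors(vectors):
    """Map (subject, omic) -> fixed vectors for adjacency tests."""
    return {key: np.asarray(v, float) for key, v in vectors.items()}


class TestBuildNetwork:
    def test_strict_threshold_zero_network(self):
        rng = np.random.default_rng(1)
        pg = _pg_from_vectors({(s, f"g{j}"): rng.normal(size=12)
                               for s in ("a", "b") for j in range(3)})
        net = build_network(pg, s_c=1.0)  # Spearman can never exceed 1
        assert not net.adjacency.any()

    def test_edge_weight_counts_omics_above_cutoff(self):
        base = np.arange(12.0)
        rng = np.random.default_rng(2)
        pg = _pg_from_vectors({
            ("a", "g1"): base, ("b", "g1"): base,                  # rho = 1
            ("a", "g2"): base, ("b", "g2"): base[::-1],            # rho = -1
            ("a", "g3"): base, ("b", "g3"): base + rng.normal(0, 0.01, 12),
        })
        net = build_network(pg, s_c=0.9)
        assert net.adjacency[0, 1] == 2

    def test_adjacency_matches_bruteforce_recount(self):
        rng = np.random.default_rng(3)
        subjects = [f"s{i}" for i in range(5)]
        pg = {}
        for s in subjects:
            for j in range(20):
                if rng.random() < 0.1:
                    continue  # omic absent for this subject
                pg[(s, f"g{j}")] = rng.normal(size=10)
        s_c = 0.3
        net = build_network(pg, s_c)

        brute = np.zeros((5, 5), dtype=int)
        for j in range(20):
            for p in range(5):
                for q in range(p + 1, 5):
                    kp, kq = (subjects[p], f"g{j}"), (subjects[q], f"g{j}")
                    if kp in pg and kq in pg:
                        rho = spearmanr(pg[kp], pg[kq]).statistic
                        if rho > s_c:
                            brute[p, q] += 1
                            brute[q, p] += 1
        np.testing.assert_array_equal(net.adjacency, brute)

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(4)
        pg = _pg_from_vectors({(f"s{i}", f"g{j}"): rng.normal(size=10)
                               for i in range(4) for j in range(15)})
        low = build_network(pg, s_c=0.2).adjacency
        high = build_network(pg, s_c=0.6).adjacency
        assert np.all(high <= low)

    def test_invariants(self, community_cohort):
        ds, _, _ = community_cohort
        frame = common_timeframe(ds)
        pg = periodogram_matrix(ds, frame)
        net = build_network(pg, s_c=0.5)
        a = net.adjacency
        np.testing.assert_array_equal(a, a.T)
        assert np.all(np.diag(a) == 0)
        assert a.max() <= 60


class TestDetectCommunities:
    @staticmethod
    def _net_from_blocks(within, between, sizes=(12, 12), seed=0):
        rng = np.random.default_rng(seed)
        n = sum(sizes)
        labels = np.repeat(np.arange(len(sizes)), sizes)
        a = np.where(labels[:, None] == labels[None, :], within, between)
        a = a + rng.integers(0, 2, size=(n, n))
        a = np.triu(a, 1)
        a = a + a.T
        subjects = [f"s{i:02d}" for i in range(n)]
        return SimilarityNetwork(subjects, a.astype(int), 0.5), labels

    def test_two_block_recovery(self):
        net, labels = self._net_from_blocks(10, 0)
        comm = detect_communities(net, seed=0)
        assert comm.k == 2
        from sklearn.metrics import adjusted_rand_score
        found = [comm.communities[s] for s in net.subjects]
        assert adjusted_rand_score(labels, found) == 1.0

    def test_identical_rows_single_community(self):
        subjects = ["a", "b", "c", "d"]
        a = np.ones((4, 4), dtype=int) - np.eye(4, dtype=int)
        net = SimilarityNetwork(subjects, a, 0.5)
        comm = detect_communities(net, seed=0)
        assert comm.k == 1
        assert set(comm.communities.values()) == {0}

    def test_zero_network_every_node_alone(self):
        net = SimilarityNetwork(["a", "b", "c"], np.zeros((3, 3), int), 0.5)
        with pytest.warns(UserWarning, match="all-zero"):
            comm = detect_communities(net)
        assert comm.k == 3
        assert len(set(comm.communities.values())) == 3

    def test_deterministic(self):
        net, _ = self._net_from_blocks(8, 1, seed=5)
        c1 = detect_communities(net, seed=3)
        c2 = detect_communities(net, seed=3)
        assert c1.communities == c2.communities and c1.k == c2.k

    def test_fixed_k_respected(self):
        net, _ = self._net_from_blocks(8, 1, sizes=(8, 8, 8), seed=6)
        comm = detect_communities(net, k=3, seed=0)
        assert comm.k == 3
        assert set(comm.communities.values()) == {0, 1, 2}
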