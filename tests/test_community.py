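"""Community detection: modularity, Louvain, consensus clustering."""

import numpy as np
import pytest

from memnet.community import (
    agreement_matrix,
    consensus_partition,
    louvain,
    modularity,
    restrict_and_cluster,
)
from memnet.connectivity import compute_fc
from memnet.parcellation import make_parcellation
from memnet.prep import PhaseBold
from memnet.synthetic import build_block_covariance


def two_cliques():
    w = np.zeros((6, 6))
    for block in (range(3), range(3, 6)):
        for i in block:
            for j in block:
                if i != j:
                    w[i, j] = 1.0
    return w


def set_partitions(n):
    """All set partitions of range(n) as restricted-growth label strings."""
    def rec(prefix, mx):
        if len(prefix) == n:
            yield np.array(prefix)
            return
        for v in range(mx + 2):
            yield from rec(prefix + [v], max(mx, v))
    yield from rec([0], 0)


def random_weighted_graph(rng, n):
    w = rng.random((n, n))
    w = (w + w.T) / 2
    mask = rng.random((n, n)) < 0.5
    mask |= mask.T
    w *= mask
    np.fill_diagonal(w, 0.0)
    if w.sum() == 0:
        w[0, 1] = w[1, 0] = 1.0
    return w


class TestModularity:
    def test_two_cliques_hand_value(self):
        assert modularity(two_cliques(), [1, 1, 1, 2, 2, 2]) == pytest.approx(0.5, abs=1e-12)

    def test_single_community_is_zero(self, rng):
        w = random_weighted_graph(rng, 7)
        assert modularity(w, np.zeros(7)) == pytest.approx(0.0, abs=1e-12)

    def test_relabeling_invariance(self, rng):
        w = random_weighted_graph(rng, 8)
        labels = rng.integers(0, 3, 8)
        relabeled = np.array([{0: 7, 1: 2, 2: 5}[v] for v in labels])
        assert modularity(w, labels) == pytest.approx(modularity(w, relabeled), abs=1e-14)

    def test_matches_networkx_on_all_partitions(self, rng):
        # independent oracle: networkx's modularity over all 203 partitions
        import networkx as nx

        w = random_weighted_graph(rng, 6)
        g = nx.from_numpy_array(w)
        for labels in set_partitions(6):
            comms = [set(np.flatnonzero(labels == c)) for c in np.unique(labels)]
            expected = nx.community.modularity(g, comms, weight="weight")
            assert modularity(w, labels) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            modularity(np.zeros((4, 4)), [0, 0, 1, 1])


class TestLouvain:
    def test_two_cliques_exact(self):
        part = louvain(two_cliques(), seed=0)
        assert part.modularity_q == pytest.approx(0.5, abs=1e-12)
        labels = part.labels()
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_complete_graph_single_community(self):
        w = np.ones((6, 6)) - np.eye(6)
        assert louvain(w, seed=1).n_communities == 1

    def test_deterministic_given_seed(self, rng):
        w = random_weighted_graph(rng, 30)
        a = louvain(w, seed=42)
        b = louvain(w, seed=42)
        assert a.assignment == b.assignment and a.modularity_q == b.modularity_q

    def test_beats_trivial_partitions(self, rng):
        w = random_weighted_graph(rng, 12)
        part = louvain(w, seed=3)
        q_single = modularity(w, np.zeros(12))
        q_singletons = modularity(w, np.arange(12))
        assert part.modularity_q >= max(q_single, q_singletons) - 1e-12

    def test_near_optimal_on_small_graphs(self, rng):
        hits = 0
        for trial in range(10):
            n = int(rng.integers(4, 9))
            w = random_weighted_graph(rng, n)
            best = max(modularity(w, lab) for lab in set_partitions(n))
            part = louvain(w, seed=trial)
            hits += abs(part.modularity_q - best) < 1e-9
        assert hits >= 9

    def test_isolated_node_becomes_singleton(self):
        w = two_cliques()
        w2 = np.zeros((7, 7))
        w2[:6, :6] = w
        part = louvain(w2, seed=0)
        labels = part.labels()
        assert (labels == labels[6]).sum() == 1


class TestConsensus:
    def test_stable_instance_converges_immediately(self):
        part = consensus_partition(two_cliques(), n_runs=10, seed=0)
        assert part.modularity_q == pytest.approx(0.5, abs=1e-12)
        assert part.n_communities == 2

    def test_agreement_of_identical_partitions_is_binary(self):
        runs = [np.array([0, 0, 1, 1, 2])] * 5
        agree = agreement_matrix(runs)
        assert set(np.unique(agree)) <= {0.0, 1.0}
        assert np.array_equal(agree, agree.T)
        assert np.array_equal(np.diag(agree), np.ones(5))

    def test_planted_blocks_recovered_and_reproducible(self, rng):
        labels = np.repeat([1, 2, 3], [8, 7, 5])
        cov = build_block_covariance(labels, within_r=0.45, between_r=0.05)
        draws = rng.multivariate_normal(np.zeros(20), cov, size=200, method="cholesky")
        w = np.maximum(np.corrcoef(draws.T), 0)
        np.fill_diagonal(w, 0.0)
        a = consensus_partition(w, n_runs=30, seed=11)
        b = consensus_partition(w, n_runs=30, seed=11)
        assert a.assignment == b.assignment
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels, a.labels()) == 1.0

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            consensus_partition(two_cliques(), n_runs=1)
        with pytest.raises(ValueError):
            consensus_partition(two_cliques(), tau=1.5)


class TestRestrictAndCluster:
    @staticmethod
    def _control_fc(subjects):
        return [
            compute_fc(
                PhaseBold(
                    node_ids=s.node_ids,
                    data=s.phases["maintenance"],
                    phase="maintenance",
                    tr_seconds=3.0,
                )
            )
            for s in subjects
            if s.group == "CN"
        ]

    def test_planted_communities_recovered(self, small_cohort, small_parcellation):
        subjects, truth = small_cohort
        part = restrict_and_cluster(
            self._control_fc(subjects), small_parcellation, n_runs=30, seed=2
        )
        restricted = small_parcellation.restricted_node_ids
        planted = [truth.planted_partition[n] for n in restricted]
        from sklearn.metrics import adjusted_rand_score

        assert part.n_communities == 3
        assert adjusted_rand_score(planted, part.labels()) == 1.0
        # labels ordered by size: Network 1 is the largest
        sizes = part.sizes()
        assert list(sizes) == sorted(sizes)
        assert sizes[1] == max(sizes.values())

    def test_single_planted_community(self, small_parcellation):
        from memnet.synthetic import CohortConfig, generate_cohort

        partition = {
            n: (1 if r else 2)
            for n, r in zip(
                small_parcellation.node_ids,
                small_parcellation.table["in_restricted_set"],
            )
        }
        cfg = CohortConfig(
            n_per_group=6,
            n_nodes=30,
            phase_lengths={"encoding": 20, "maintenance": 80, "retrieval": 20},
            planted_partition=partition,
            deficit_community=1,
            n_entropy_nodes=0,
            seed=9,
        )
        subjects, _ = generate_cohort(cfg, small_parcellation)
        part = restrict_and_cluster(
            self._control_fc(subjects), small_parcellation, n_runs=20, seed=3
        )
        assert part.n_communities == 1

    def test_empty_control_group_rejected(self, small_parcellation):
        with pytest.raises(ValueError, match="empty"):
            restrict_and_cluster([], small_parcellation)
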