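"""Clique and k-partite detection against hand arithmetic and brute force."""

import numpy as np
import pytest

import latentconn as lc
from latentconn.detect import (
    DetectedNetwork,
    between_block_edges,
    clique_edges,
    resolve_lambda,
)
from latentconn.exceptions import ValidationError

from conftest import (
    brute_force_best_clique,
    brute_force_best_kpartite,
    random_weight_matrix,
)


def _matrix(n, entries, default=0.0):
    W = np.full((n, n), default)
    np.fill_diagonal(W, 0.0)
    for (i, j), w in entries.items():
        W[i, j] = W[j, i] = w
    return W


def _clique_network(nodes, score=0.0):
    return DetectedNetwork(
        nodes=tuple(nodes), topology="clique", score=score, scoring_edges=clique_edges(tuple(nodes))
    )


class TestScore:
    def test_constant_matrix_scores_zero_at_its_own_level(self):
        W = _matrix(5, {}, default=2.0)
        net = _clique_network((0, 1, 2))
        assert lc.score_subgraph(W, net, 2.0) == 0.0

    def test_hand_arithmetic_on_four_node_graph(self):
        # clique {0,1,2} has W = 5 on its 3 edges, W = 1 on the other 3; mean = 3
        W = _matrix(4, {(0, 1): 5, (0, 2): 5, (1, 2): 5}, default=1.0)
        net = _clique_network((0, 1, 2))
        assert lc.score_subgraph(W, net, 3.0) == pytest.approx(6.0)

    def test_adding_below_lambda_node_strictly_decreases_score(self):
        W = _matrix(4, {(0, 1): 5, (0, 2): 5, (1, 2): 5}, default=1.0)
        small = lc.score_subgraph(W, _clique_network((0, 1, 2)), 3.0)
        bigger = lc.score_subgraph(W, _clique_network((0, 1, 2, 3)), 3.0)
        assert bigger < small

    def test_empty_scoring_edges_rejected(self):
        W = _matrix(4, {})
        net = DetectedNetwork(nodes=(0,), topology="clique", score=0.0, scoring_edges=())
        with pytest.raises(ValidationError):
            lc.score_subgraph(W, net, 1.0)


class TestCliqueDetection:
    def test_zero_matrix_yields_nothing(self):
        nets = lc.detect_clique_networks(np.zeros((8, 8)), lc.DetectionConfig())
        assert nets == []

    def test_planted_heavy_clique_matches_exhaustive_search(self):
        rng = np.random.default_rng(0)
        W = random_weight_matrix(10, rng) * 0.5
        for i in (3, 5, 7, 9):
            for j in (3, 5, 7, 9):
                if i < j:
                    W[i, j] = W[j, i] = 8.0
        config = lc.DetectionConfig(n_restarts=20)
        lam = resolve_lambda(W, config)
        nets = lc.detect_clique_networks(W, config)
        best_score, best_set = brute_force_best_clique(W, lam)
        assert nets
        assert set(nets[0].nodes) == set(best_set) == {3, 5, 7, 9}
        assert nets[0].score == pytest.approx(best_score)

    def test_two_disjoint_planted_cliques_both_recovered_in_score_order(self):
        rng = np.random.default_rng(1)
        W = random_weight_matrix(12, rng)
        for group, w in (((0, 1, 2, 3), 9.0), ((6, 7, 8), 7.0)):
            for i in group:
                for j in group:
                    if i < j:
                        W[i, j] = W[j, i] = w
        config = lc.DetectionConfig(n_restarts=20, lambda_mode="fixed", lambda_value=3.0)
        lam = resolve_lambda(W, config)
        nets = lc.detect_clique_networks(W, config)
        assert len(nets) >= 2
        assert {0, 1, 2, 3} <= set(nets[0].nodes)
        assert set(nets[1].nodes) == {6, 7, 8}
        assert nets[0].score > nets[1].score
        assert not (set(nets[0].nodes) & set(nets[1].nodes))
        # first extraction equals the global exhaustive optimum
        assert nets[0].score == pytest.approx(brute_force_best_clique(W, lam)[0])

    def test_networks_are_node_disjoint_and_positive(self):
        rng = np.random.default_rng(2)
        W = random_weight_matrix(15, rng)
        nets = lc.detect_clique_networks(W, lc.DetectionConfig())
        seen = set()
        for net in nets:
            assert net.score > 0
            assert len(net.nodes) >= 3
            assert not (seen & set(net.nodes))
            seen |= set(net.nodes)


class TestKPartite:
    def test_bipartite_four_node_example_matches_enumeration(self):
        W = _matrix(4, {(0, 2): 5, (0, 3): 5, (1, 2): 5, (1, 3): 5}, default=0.1)
        config = lc.DetectionConfig(n_restarts=10, lambda_mode="global_mean")
        lam = resolve_lambda(W, config)
        net = lc.detect_kpartite_network(W, (0, 1, 2, 3), config)
        assert net is not None
        assert net.k == 2
        assert {frozenset(b) for b in net.partition} == {frozenset({0, 1}), frozenset({2, 3})}
        assert net.score == pytest.approx(brute_force_best_kpartite(W, range(4), lam))
        assert set(net.scoring_edges) == {(0, 2), (0, 3), (1, 2), (1, 3)}

    def test_constant_matrix_gives_degenerate_result(self):
        W = _matrix(6, {}, default=2.0)
        config = lc.DetectionConfig(lambda_mode="fixed", lambda_value=2.0)
        assert lc.detect_kpartite_network(W, range(6), config) is None

    def test_planted_three_partite_recovers_k_equal_three(self):
        blocks = [(0, 1, 2), (3, 4, 5), (6, 7, 8)]
        entries = {}
        for a, ba in enumerate(blocks):
            for bb in blocks[a + 1 :]:
                for i in ba:
                    for j in bb:
                        entries[(i, j)] = 6.0
        W = _matrix(9, entries, default=0.2)
        config = lc.DetectionConfig(n_restarts=20, k_max=3, lambda_mode="global_mean")
        lam = resolve_lambda(W, config)
        net = lc.detect_kpartite_network(W, range(9), config)
        assert net.k == 3
        assert {frozenset(b) for b in net.partition} == {frozenset(b) for b in blocks}
        assert net.score == pytest.approx(brute_force_best_kpartite(W, range(9), lam))

    def test_requires_at_least_four_nodes(self):
        W = _matrix(5, {})
        with pytest.raises(ValidationError, match="at least 4"):
            lc.detect_kpartite_network(W, (0, 1, 2), lc.DetectionConfig())

    def test_exact_partition_recovery_on_noise_free_weights(self):
        set1, set2 = (0, 1, 2, 3), (4, 5, 6, 7, 8)
        entries = {(i, j): 10.0 for i in set1 for j in set2}
        W = _matrix(9, entries, default=0.5)
        config = lc.DetectionConfig(n_restarts=10, lambda_mode="global_mean")
        net = lc.detect_kpartite_network(W, range(9), config)
        assert net.k == 2
        assert {frozenset(b) for b in net.partition} == {frozenset(set1), frozenset(set2)}


class TestDetectAll:
    def test_clique_and_bipartite_topologies_assigned(self):
        rng = np.random.default_rng(3)
        W = random_weight_matrix(12, rng)
        for i in (0, 1, 2, 3):
            for j in (0, 1, 2, 3):
                if i < j:
                    W[i, j] = W[j, i] = 8.0
        for i in (6, 7):
            for j in (8, 9):
                W[i, j] = W[j, i] = 8.0
        config = lc.DetectionConfig(n_restarts=20, lambda_mode="fixed", lambda_value=3.0)
        nets = lc.detect_all(W, config)
        by_nodes = {frozenset(net.nodes): net for net in nets}
        assert by_nodes[frozenset({0, 1, 2, 3})].topology == "clique"
        bip = by_nodes[frozenset({6, 7, 8, 9})]
        assert bip.topology == "k_partite"
        assert {frozenset(b) for b in bip.partition} == {frozenset({6, 7}), frozenset({8, 9})}
        assert [n.score for n in nets] == sorted((n.score for n in nets), reverse=True)

    def test_kpartite_reading_kept_only_when_it_beats_clique_score(self):
        # dense clique: every within edge is heavy, so no partition can win
        W = _matrix(6, {(i, j): 5.0 for i in range(4) for j in range(4) if i < j}, default=0.1)
        nets = lc.detect_all(W, lc.DetectionConfig(n_restarts=10))
        assert nets[0].topology == "clique"

    def test_node_relabeling_permutes_detected_sets(self):
        rng = np.random.default_rng(4)
        W = random_weight_matrix(10, rng) * 0.3
        for i in (1, 4, 6, 9):
            for j in (1, 4, 6, 9):
                if i < j:
                    W[i, j] = W[j, i] = 7.0
        perm = rng.permutation(10)
        W2 = W[np.ix_(perm, perm)]  # node v of W2 is node perm[v] of W
        config = lc.DetectionConfig(n_restarts=20)
        nets1 = lc.detect_all(W, config)
        nets2 = lc.detect_all(W2, config)
        mapped = [frozenset(int(perm[v]) for v in net.nodes) for net in nets2]
        assert [frozenset(net.nodes) for net in nets1] == mapped


class TestOracleEquivalence:
    """Local search vs exhaustive enumeration on random small graphs."""

    def test_clique_search_matches_exhaustive_optimum(self):
        rng = np.random.default_rng(2024)
        shortfalls = []
        for trial in range(100):
            n = int(rng.integers(6, 11))
            W = random_weight_matrix(n, rng)
            config = lc.DetectionConfig(n_restarts=20, seed=trial)
            lam = resolve_lambda(W, config)
            best, _ = brute_force_best_clique(W, lam)
            nets = lc.detect_clique_networks(W, config)
            found = nets[0].score if nets else 0.0
            if best > 0 and found < best - 1e-9:
                shortfalls.append((best - found) / best)
        assert len(shortfalls) < 5
        assert all(s < 0.01 for s in shortfalls)

    def test_kpartite_search_matches_exhaustive_optimum(self):
        rng = np.random.default_rng(4048)
        shortfalls = []
        for trial in range(100):
            n = int(rng.integers(5, 9))
            W = random_weight_matrix(n, rng)
            config = lc.DetectionConfig(n_restarts=20, seed=trial)
            lam = resolve_lambda(W, config)
            best = brute_force_best_kpartite(W, range(n), lam)
            net = lc.detect_kpartite_network(W, range(n), config)
            found = net.score if net else 0.0
            if best > 0 and found < best - 1e-9:
                shortfalls.append((best - found) / best)
        assert len(shortfalls) < 5
        assert all(s < 0.01 for s in shortfalls)


def test_monotone_recovery_in_effect_size():
    """Planted-clique Jaccard recovery does not degrade as delta grows."""
    from conftest import planted_clique_config

    planted = {0, 1, 2, 3, 4}
    jaccards = []
    for delta in (0.15, 0.45, 0.9):
        scores = []
        for seed in range(3):
            cfg = planted_clique_config(n_nodes=20, delta=delta, seed=seed)
            sample, _ = lc.generate_sample(cfg)
            W = lc.weight_matrix(lc.edgewise_tests(sample))
            nets = lc.detect_all(W, lc.DetectionConfig(n_restarts=10))
            found = set(nets[0].nodes) if nets else set()
            scores.append(len(found & planted) / len(found | planted) if found else 0.0)
        jaccards.append(np.mean(scores))
    assert jaccards[0] <= jaccards[1] + 1e-9 <= jaccards[2] + 2e-9


def test_between_block_edges_counts():
    part = ((0, 1), (2, 3, 4))
    assert len(between_block_edges(part)) == 6
    part3 = ((0,), (1, 2), (3, 4, 5))
    assert len(between_block_edges(part3)) == 1 * 2 + 1 * 3 + 2 * 3
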