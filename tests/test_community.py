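import numpy as np
import pytest

from netdim import (
    EGASettings,
    RegularizedNetwork,
    WeightedGraph,
    bootstrap_ega,
    build_graph,
    ega,
    modularity,
    scenario_config,
    simulate_dataset,
    two_factor_config,
    walktrap,
)
from netdim.community import _contiguous


def modularity_by_edge_sum(w: np.ndarray, labels: np.ndarray) -> float:
    """Independent re-implementation: Q = (1/2m) sum_ij (w_ij - d_i d_j / 2m)
    over pairs in the same community."""
    d = w.sum(axis=1)
    two_m = w.sum()
    q = 0.0
    n = len(labels)
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += w[i, j] - d[i] * d[j] / two_m
    return q / two_m


def best_partition_by_enumeration(w: np.ndarray, kmax: int, helpers):
    partitions_into_at_most, _ = helpers
    best_q, best = -np.inf, None
    g = WeightedGraph(weights=w)
    for labels in partitions_into_at_most(w.shape[0], kmax):
        q = modularity(g, labels)
        if q > best_q:
            best_q, best = q, labels
    return best_q, best


def two_cliques_graph():
    w = np.zeros((10, 10))
    for block in (range(5), range(5, 10)):
        for i in block:
            for j in block:
                if i < j:
                    w[i, j] = w[j, i] = 1.0
    w[4, 5] = w[5, 4] = 1.0  # bridge
    return w


def two_triangles_graph():
    w = np.zeros((6, 6))
    for block in (range(3), range(3, 6)):
        for i in block:
            for j in block:
                if i < j:
                    w[i, j] = w[j, i] = 1.0
    return w


class TestBuildGraph:
    def _network(self, pcor):
        p = pcor.shape[0]
        return RegularizedNetwork(
            partial_correlations=pcor, precision=np.eye(p), lambda_selected=0.1,
            lambda_path=np.array([0.1]), ebic_path=np.array([0.0]), gamma=0.5,
            n=100, p=p)

    def test_negative_policies(self):
        pcor = np.array([[0.0, -0.3], [-0.3, 0.0]])
        net = self._network(pcor)
        assert build_graph(net, "absolute").weights[0, 1] == pytest.approx(0.3)
        assert build_graph(net, "truncate").weights[0, 1] == 0.0

    def test_empty_network_isolates_everything(self):
        net = self._network(np.zeros((4, 4)))
        g = build_graph(net)
        assert list(g.isolated) == [0, 1, 2, 3]


class TestModularity:
    def test_single_community_is_zero(self):
        g = WeightedGraph(weights=two_cliques_graph())
        assert modularity(g, np.ones(10, dtype=int)) == pytest.approx(0.0)

    def test_disconnected_triangles_split_is_half(self):
        g = WeightedGraph(weights=two_triangles_graph())
        labels = np.array([1, 1, 1, 2, 2, 2])
        assert modularity(g, labels) == pytest.approx(0.5)

    def test_agrees_with_independent_edge_sum(self):
        rng = np.random.default_rng(7)
        w = rng.uniform(0, 1, (8, 8))
        w = np.triu(w, 1)
        w = w + w.T
        labels = rng.integers(1, 4, 8)
        g = WeightedGraph(weights=w)
        assert modularity(g, labels) == pytest.approx(
            modularity_by_edge_sum(w, labels), abs=1e-12)


class TestWalktrap:
    def test_two_joined_cliques_found_and_optimal(self, partition_helpers):
        w = two_cliques_graph()
        part = walktrap(WeightedGraph(weights=w), t=4)
        _, same = partition_helpers
        assert part.n_communities == 2
        assert same(part.membership, [1] * 5 + [2] * 5)
        best_q, best = best_partition_by_enumeration(w, 3, partition_helpers)
        assert part.modularity == pytest.approx(best_q, abs=1e-12)
        assert same(part.membership, best)

    def test_disconnected_triangles_are_components(self, partition_helpers):
        part = walktrap(WeightedGraph(weights=two_triangles_graph()), t=4)
        _, same = partition_helpers
        assert part.n_communities == 2
        assert same(part.membership, [1, 1, 1, 2, 2, 2])
        best_q, _ = best_partition_by_enumeration(two_triangles_graph(), 3,
                                                  partition_helpers)
        assert part.modularity == pytest.approx(best_q, abs=1e-12)

    def test_homogeneous_clique_stays_whole(self, partition_helpers):
        w = 1.0 - np.eye(7)
        part = walktrap(WeightedGraph(weights=w), t=4)
        assert part.n_communities == 1
        # oracle: every split of a homogeneous clique has Q <= 0
        best_q, _ = best_partition_by_enumeration(w, 3, partition_helpers)
        assert best_q == pytest.approx(0.0, abs=1e-12)
        assert part.modularity == pytest.approx(0.0, abs=1e-12)

    def test_reported_q_matches_independent_recomputation(self):
        rng = np.random.default_rng(3)
        w = rng.uniform(0, 1, (9, 9)) * (rng.random((9, 9)) < 0.5)
        w = np.triu(w, 1)
        w = w + w.T
        if (w.sum(axis=1) == 0).any():
            w[0, 1] = w[1, 0] = 0.5
        g = WeightedGraph(weights=w)
        part = walktrap(g, t=4)
        assert part.modularity == pytest.approx(
            modularity_by_edge_sum(w, part.membership), abs=1e-10)

    def test_node_permutation_permutes_membership(self, partition_helpers):
        w = two_cliques_graph()
        rng = np.random.default_rng(0)
        perm = rng.permutation(10)
        part = walktrap(WeightedGraph(weights=w), t=4)
        part_perm = walktrap(WeightedGraph(weights=w[np.ix_(perm, perm)]), t=4)
        _, same = partition_helpers
        assert same(part.membership[perm], part_perm.membership)

    def test_no_community_spans_components(self):
        w = np.zeros((8, 8))
        w[:4, :4] = two_triangles_graph()[:4, :4] * 0  # keep zero
        # two separate 4-cycles
        for base in (0, 4):
            for i in range(4):
                j = base + i
                k = base + (i + 1) % 4
                w[j, k] = w[k, j] = 1.0
        part = walktrap(WeightedGraph(weights=w), t=4)
        assert len(set(part.membership[:4]) & set(part.membership[4:])) == 0

    def test_matches_igraph_reference(self):
        ig = pytest.importorskip("igraph")
        rng = np.random.default_rng(12)
        for _ in range(5):
            p = 12
            w = np.zeros((p, p))
            for i in range(p):
                for j in range(i + 1, p):
                    same_block = (i < 6) == (j < 6)
                    if rng.random() < (0.8 if same_block else 0.2):
                        w[i, j] = w[j, i] = rng.uniform(0.3, 1.0)
            if (w.sum(axis=1) == 0).any():
                continue
            part = walktrap(WeightedGraph(weights=w), t=4)
            src, tgt = np.triu_indices(p, 1)
            mask = w[src, tgt] > 0
            g = ig.Graph(list(zip(src[mask], tgt[mask])),
                         edge_attrs={"weight": w[src, tgt][mask]})
            ref = g.community_walktrap(weights="weight", steps=4).as_clustering()
            q_ref = g.modularity(ref.membership, weights="weight")
            # merge order can differ at near-ties, but the chosen cut must
            # never fall below the reference implementation's modularity
            assert part.modularity >= q_ref - 1e-9

    def test_zero_weight_graph_rejected(self):
        with pytest.raises(ValueError, match="isolated"):
            walktrap(WeightedGraph(weights=np.zeros((3, 3))))


class TestEGA:
    def test_recovers_four_dimensions(self, online_dataset, partition_helpers):
        res = ega(online_dataset.responses)
        _, same = partition_helpers
        assert res.n_dimensions == 4
        assert same(res.membership, online_dataset.true_membership)

    def test_unidimensional_data_gives_one(self):
        ds = simulate_dataset(scenario_config("unidimensional", n=2000, seed=21))
        assert ega(ds.responses).n_dimensions == 1

    def test_independent_items_give_empty_network(self, caplog):
        rng = np.random.default_rng(8)
        z = rng.standard_normal((2000, 10))
        with caplog.at_level("WARNING", logger="netdim"):
            res = ega(z)
        assert res.n_dimensions == 0
        assert len(res.isolated_nodes) == 10


class TestBootstrapEGA:
    def test_median_and_frequency_table(self, online_dataset):
        boot = bootstrap_ega(online_dataset.responses, B=20, seed=5)
        assert boot.median_dimensions == 4.0
        assert boot.n_dimensions == 4
        assert sum(boot.frequency_table.values()) == pytest.approx(1.0)
        assert len(boot.dimension_counts) == 20

    def test_median_order_statistics(self):
        # fractional median {3,4,4,5} -> 4; hand order statistics
        counts = np.array([3, 4, 4, 5])
        assert float(np.median(counts)) == 4.0

    def test_deterministic_given_seed(self, online_dataset):
        a = bootstrap_ega(online_dataset.responses, B=10, seed=3)
        b = bootstrap_ega(online_dataset.responses, B=10, seed=3)
        assert np.array_equal(a.dimension_counts, b.dimension_counts)
        assert a.frequency_table == b.frequency_table

    def test_default_replicate_count_is_1000(self):
        import inspect

        sig = inspect.signature(bootstrap_ega)
        assert sig.parameters["B"].default == 1000


class TestRecoveryContrast:
    @pytest.mark.parametrize("phi12", [0.5, 0.7])
    def test_two_factor_recovery_moderate_overlap(self, phi12):
        hits = 0
        for seed in range(10):
            ds = simulate_dataset(two_factor_config(phi12, n=2000, seed=seed))
            hits += ega(ds.responses).n_dimensions == 2
        assert hits >= 9

    def test_high_overlap_ega_beats_scree(self):
        from netdim import eigen_spectrum, pearson_correlation, scree_elbow

        ega_hits = scree_ones = 0
        n_seeds = 10
        for seed in range(n_seeds):
            ds = simulate_dataset(two_factor_config(0.8, n=2000, seed=seed))
            ega_hits += ega(ds.responses).n_dimensions == 2
            ev = eigen_spectrum(pearson_correlation(ds.responses))
            scree_ones += scree_elbow(ev) == 1
        assert ega_hits >= 9
        assert scree_ones > n_seeds / 2
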