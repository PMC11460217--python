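"""Walktrap communities, node centralities and bridge centralities."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from symptomnet.network_metrics import (
    ClusterAssignment,
    bridge_centralities,
    centrality_table,
    node_centralities,
    walktrap_communities,
)
from symptomnet.preprocess import nonparanormal_transform
from symptomnet.ggm import select_network
from symptomnet.synthetic_data import DEFAULT_THRESHOLDS

from conftest import make_network, two_clique_weights


def nx_graph(W):
    G = nx.Graph()
    G.add_nodes_from(range(W.shape[0]))
    for i in range(W.shape[0]):
        for j in range(i + 1, W.shape[0]):
            if W[i, j] > 0:
                G.add_edge(i, j, length=1.0 / W[i, j])
    return G


def brute_betweenness(W, pair_filter=None):
    """Enumerate all shortest paths per pair; fractional credit to interior nodes."""
    G = nx_graph(W)
    p = W.shape[0]
    out = np.zeros(p)
    for s in range(p):
        for t in range(s + 1, p):
            if pair_filter and not pair_filter(s, t):
                continue
            if not nx.has_path(G, s, t):
                continue
            paths = list(nx.all_shortest_paths(G, s, t, weight="length"))
            for path in paths:
                for v in path[1:-1]:
                    out[v] += 1.0 / len(paths)
    return out


class TestWalktrap:
    def test_two_disconnected_cliques(self):
        net = make_network(two_clique_weights())
        cl = walktrap_communities(net)
        assert cl.n_communities == 2
        assert len({cl.labels[f"n{i}"] for i in range(4)}) == 1
        assert len({cl.labels[f"n{i}"] for i in range(4, 8)}) == 1

    def test_weak_bridge_preserves_cliques(self):
        net = make_network(two_clique_weights(bridge=0.05))
        cl = walktrap_communities(net)
        assert cl.n_communities == 2
        assert cl.labels["n0"] == cl.labels["n3"] != cl.labels["n4"]

    def test_isolated_node_becomes_singleton(self):
        W = two_clique_weights()
        W2 = np.zeros((9, 9))
        W2[:8, :8] = W
        cl = walktrap_communities(make_network(W2))
        assert cl.n_communities == 3
        assert cl.labels["n8"] not in {cl.labels["n0"], cl.labels["n4"]}

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="no edges"):
            walktrap_communities(make_network(np.zeros((4, 4))))

    def test_recovers_planted_blocks(self, block_cohort, block_network):
        cl = walktrap_communities(block_network)
        truth = [block_cohort.true_symptom_clusters[s] for s in block_network.nodes]
        est = [cl.labels[s] for s in block_network.nodes]
        assert adjusted_rand_score(truth, est) == 1.0


class TestNodeCentralities:
    def test_star_center_dominates(self):
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 0.4
        tab = node_centralities(make_network(W))
        for col in ("strength", "closeness", "betweenness"):
            assert tab[col].idxmax() == "n0"

    def test_path_betweenness(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[1, 2] = W[2, 1] = 0.5
        tab = node_centralities(make_network(W))
        assert tab.loc["n1", "betweenness"] == 1.0
        assert tab.loc["n0", "betweenness"] == 0.0

    def test_random_graph_matches_shortest_path_oracle(self):
        rng = np.random.default_rng(5)
        W = rng.random((8, 8)) * (rng.random((8, 8)) < 0.4)
        W = np.triu(W, 1)
        W = W + W.T
        net = make_network(W)
        tab = node_centralities(net)
        G = nx_graph(W)
        for i in range(8):
            lengths = nx.single_source_dijkstra_path_length(G, i, weight="length")
            total = sum(v for k, v in lengths.items() if k != i)
            expected = 1.0 / total if total > 0 else 0.0
            assert tab["closeness"].iloc[i] == pytest.approx(expected, abs=1e-10)
        np.testing.assert_allclose(
            tab["betweenness"].to_numpy(), brute_betweenness(W), atol=1e-10
        )

    def test_neglog_distance_variant(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[1, 2] = W[2, 1] = 0.5
        tab = node_centralities(make_network(W), distance="neglog")
        d = -np.log(0.5)
        assert tab.loc["n1", "closeness"] == pytest.approx(1.0 / (2 * d))
        assert tab.loc["n0", "closeness"] == pytest.approx(1.0 / (3 * d))
        with pytest.raises(ValueError, match="neglog"):
            node_centralities(make_network(two_clique_weights() * 3), distance="neglog")

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        W = rng.random((6, 6)) * (rng.random((6, 6)) < 0.5)
        W = np.triu(W, 1)
        W = W + W.T
        perm = rng.permutation(6)
        tab = node_centralities(make_network(W))
        tab_p = node_centralities(
            make_network(W[np.ix_(perm, perm)], nodes=[f"n{i}" for i in perm])
        )
        for node in tab.index:
            np.testing.assert_allclose(
                tab.loc[node].to_numpy(), tab_p.loc[node].to_numpy(), atol=1e-10
            )


class TestBridgeCentralities:
    def two_community_fixture(self):
        W = np.zeros((6, 6))
        edges = {(0, 1): 0.5, (1, 2): 0.4, (3, 4): 0.5, (4, 5): 0.4, (2, 3): 0.2, (0, 5): 0.1}
        for (i, j), v in edges.items():
            W[i, j] = W[j, i] = v
        comm = ClusterAssignment(
            labels={f"n{i}": 1 if i < 3 else 2 for i in range(6)}, n_communities=2
        )
        return W, comm

    def test_all_cross_edges_equal_strength(self):
        W = np.zeros((4, 4))
        W[0, 2] = W[2, 0] = 0.3
        W[0, 3] = W[3, 0] = 0.2
        W[2, 3] = W[3, 2] = 0.4
        comm = ClusterAssignment(labels={"n0": 1, "n1": 1, "n2": 2, "n3": 2}, n_communities=2)
        net = make_network(W)
        tab = bridge_centralities(net, comm)
        full = node_centralities(net)
        assert tab.loc["n0", "bridge_strength"] == pytest.approx(full.loc["n0", "strength"])

    def test_all_internal_edges_give_zero_bridge_strength(self):
        W, comm = self.two_community_fixture()
        W = W.copy()
        W[2, 3] = W[3, 2] = 0.0
        W[0, 5] = W[5, 0] = 0.0
        tab = bridge_centralities(make_network(W), comm)
        assert tab.loc["n1", "bridge_strength"] == 0.0

    def test_fixture_matches_brute_force(self):
        W, comm = self.two_community_fixture()
        net = make_network(W)
        tab = bridge_centralities(net, comm)
        c = comm.as_array(net.nodes)
        expected_bb = brute_betweenness(W, pair_filter=lambda s, t: c[s] != c[t])
        np.testing.assert_allclose(tab["bridge_betweenness"].to_numpy(), expected_bb, atol=1e-10)
        G = nx_graph(W)
        for i in range(6):
            lengths = nx.single_source_dijkstra_path_length(G, i, weight="length")
            total = sum(v for k, v in lengths.items() if k != i and c[k] != c[i])
            assert tab["bridge_closeness"].iloc[i] == pytest.approx(
                1.0 / total if total > 0 else 0.0, abs=1e-10
            )

    def test_bridge_strength_bounded_by_strength(self, block_network):
        cl = walktrap_communities(block_network)
        tab = centrality_table(block_network, cl)
        assert (tab["bridge_strength"] <= tab["strength"] + 1e-12).all()

    def test_single_community_rejected(self):
        W, _ = self.two_community_fixture()
        comm = ClusterAssignment(labels={f"n{i}": 1 for i in range(6)}, n_communities=1)
        with pytest.raises(ValueError, match="2 communities"):
            bridge_centralities(make_network(W), comm)


class TestCentralityTable:
    def test_zscores_standardized(self, block_network):
        cl = walktrap_communities(block_network)
        tab = centrality_table(block_network, cl)
        for col in tab.columns:
            if col.endswith("_z") and tab[col].std(ddof=1) > 0:
                assert tab[col].mean() == pytest.approx(0.0, abs=1e-9)
                assert tab[col].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_planted_hub_attains_top_strength(self):
        # hub symptom correlated with every other symptom dominates strength
        p = 11
        R = np.full((p, p), 0.05)
        for block in ((0, 1, 2, 3, 4), (5, 6, 7, 8, 9)):
            R[np.ix_(block, block)] = 0.35
        R[10, :] = R[:, 10] = 0.3
        np.fill_diagonal(R, 1.0)
        assert np.linalg.eigvalsh(R).min() > 0
        rng = np.random.default_rng(2)
        z = rng.standard_normal((1500, p)) @ np.linalg.cholesky(R).T
        sev = pd.DataFrame(
            np.digitize(z, np.asarray(DEFAULT_THRESHOLDS)), columns=[f"s{i}" for i in range(p)]
        )
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            net, _ = select_network(nonparanormal_transform(sev))
        tab = centrality_table(net, walktrap_communities(net))
        assert tab["strength_z"].idxmax() == "s10"
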