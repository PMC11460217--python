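"""Community detection and (bridge) centralities on a symptom network.

Communities come from the walktrap algorithm on absolute edge weights; node
importance is summarized by strength, closeness and betweenness, and by the
bridge variants of the same three measures restricted to connections and
shortest paths that cross community boundaries. Shortest-path lengths use
the 1/|weight| distance transform so strong partial correlations mean short
distances.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

from .ggm import EDGE_TOL, SymptomNetwork

__all__ = [
    "ClusterAssignment",
    "walktrap_communities",
    "node_centralities",
    "bridge_centralities",
    "centrality_table",
]

DEFAULT_WALKTRAP_STEPS = 4


@dataclass
class ClusterAssignment:
    labels: dict[str, int]  # node -> community id, contiguous from 1
    n_communities: int
    method: str = "walktrap"

    def as_array(self, nodes: list[str]) -> np.ndarray:
        return np.array([self.labels[v] for v in nodes])


def _weighted_graph(network: SymptomNetwork) -> tuple[np.ndarray, np.ndarray]:
    W = np.abs(network.weights).copy()
    W[W <= EDGE_TOL] = 0.0
    return W, (W > 0)


def walktrap_communities(
    network: SymptomNetwork, steps: int = DEFAULT_WALKTRAP_STEPS
) -> ClusterAssignment:
    """Walktrap communities with the modularity-optimal dendrogram cut.

    Edge weights are absolute partial correlations; isolated nodes become
    singleton communities. Community ids are renumbered contiguously from 1
    in order of first appearance along the node ordering.
    """
    W, mask = _weighted_graph(network)
    p = len(network.nodes)
    iu = np.triu_indices(p, k=1)
    edges = [(int(i), int(j)) for i, j in zip(*iu) if mask[i, j]]
    if not edges:
        raise ValueError("network has no edges; community detection is not meaningful")
    g = ig.Graph(n=p, edges=edges)
    g.es["weight"] = [float(W[i, j]) for i, j in edges]
    membership = g.community_walktrap(weights="weight", steps=steps).as_clustering().membership
    return _contiguous(network.nodes, membership)


def _contiguous(nodes: list[str], membership: list[int] | np.ndarray) -> ClusterAssignment:
    remap: dict[int, int] = {}
    labels: dict[str, int] = {}
    for node, raw in zip(nodes, membership):
        if raw not in remap:
            remap[raw] = len(remap) + 1
        labels[node] = remap[raw]
    return ClusterAssignment(labels=labels, n_communities=len(remap))


def _edge_lengths(W: np.ndarray, distance: str) -> np.ndarray:
    """Edge length transform: 'inverse' -> 1/|w| (default, the convention of
    the network-psychometrics software family) or 'neglog' -> -log|w|."""
    if distance == "inverse":
        with np.errstate(divide="ignore"):
            return np.where(W > 0, 1.0 / W, 0.0)
    if distance == "neglog":
        if np.any(W >= 1.0):
            raise ValueError("neglog distances require |weights| < 1")
        with np.errstate(divide="ignore"):
            return np.where(W > 0, -np.log(W), 0.0)
    raise ValueError("distance must be 'inverse' or 'neglog'")


def _distance_matrix(W: np.ndarray, distance: str = "inverse") -> np.ndarray:
    """All-pairs shortest-path distances on the transformed length graph."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import dijkstra

    return dijkstra(csr_matrix(_edge_lengths(W, distance)), directed=False)


def node_centralities(network: SymptomNetwork, distance: str = "inverse") -> pd.DataFrame:
    """Strength, closeness and betweenness per node.

    Closeness is the inverse of the summed shortest-path distances to the
    other nodes of the same connected component (unreachable nodes are
    excluded rather than counted as infinite); betweenness counts shortest
    paths through a node, ties split fractionally, each unordered pair once.
    """
    W, _ = _weighted_graph(network)
    nodes = network.nodes
    strength = W.sum(axis=1)
    D = _distance_matrix(W, distance)
    finite = np.isfinite(D)
    np.fill_diagonal(finite, False)
    dist_sums = np.where(finite, D, 0.0).sum(axis=1)
    closeness = np.where(dist_sums > 0, 1.0 / np.where(dist_sums > 0, dist_sums, 1.0), 0.0)

    lengths = _edge_lengths(W, distance)
    G = nx.Graph()
    G.add_nodes_from(range(len(nodes)))
    iu = np.triu_indices(len(nodes), k=1)
    for i, j in zip(*iu):
        if W[i, j] > 0:
            G.add_edge(int(i), int(j), length=lengths[i, j])
    btw = nx.betweenness_centrality(G, weight="length", normalized=False)
    betweenness = np.array([btw[i] for i in range(len(nodes))])

    return pd.DataFrame(
        {"strength": strength, "closeness": closeness, "betweenness": betweenness},
        index=pd.Index(nodes, name="symptom"),
    )


def bridge_centralities(
    network: SymptomNetwork, assignment: ClusterAssignment, distance: str = "inverse"
) -> pd.DataFrame:
    """Strength/closeness/betweenness restricted to cross-community structure."""
    if assignment.n_communities < 2:
        raise ValueError("bridge centralities require at least 2 communities")
    W, _ = _weighted_graph(network)
    nodes = network.nodes
    comm = assignment.as_array(nodes)
    other = comm[None, :] != comm[:, None]

    bridge_strength = (W * other).sum(axis=1)

    D = _distance_matrix(W, distance)
    finite = np.isfinite(D) & other
    np.fill_diagonal(finite, False)
    dist_sums = np.where(finite, D, 0.0).sum(axis=1)
    bridge_closeness = np.where(dist_sums > 0, 1.0 / np.where(dist_sums > 0, dist_sums, 1.0), 0.0)

    bridge_betweenness = _bridge_betweenness(W, comm, distance)
    return pd.DataFrame(
        {
            "bridge_strength": bridge_strength,
            "bridge_closeness": bridge_closeness,
            "bridge_betweenness": bridge_betweenness,
        },
        index=pd.Index(nodes, name="symptom"),
    )


def _bridge_betweenness(W: np.ndarray, comm: np.ndarray, distance: str = "inverse") -> np.ndarray:
    """Brandes accumulation counting only source/target pairs in different communities."""
    p = W.shape[0]
    length = np.where(W > 0, _edge_lengths(W, distance), np.inf)
    adj = [np.flatnonzero(W[i] > 0) for i in range(p)]
    bb = np.zeros(p)
    for s in range(p):
        dist = np.full(p, np.inf)
        sigma = np.zeros(p)
        preds: list[list[int]] = [[] for _ in range(p)]
        dist[s] = 0.0
        sigma[s] = 1.0
        heap: list[tuple[float, int]] = [(0.0, s)]
        order: list[int] = []
        done = np.zeros(p, dtype=bool)
        while heap:
            d, v = heapq.heappop(heap)
            if done[v] or d > dist[v] + 1e-14:
                continue
            done[v] = True
            order.append(v)
            for u in adj[v]:
                nd = d + length[v, u]
                if nd < dist[u] - 1e-14:
                    dist[u] = nd
                    sigma[u] = sigma[v]
                    preds[u] = [v]
                    heapq.heappush(heap, (nd, int(u)))
                elif abs(nd - dist[u]) <= 1e-14 and v not in preds[u]:
                    sigma[u] += sigma[v]
                    preds[u].append(v)
        delta = np.zeros(p)
        for w in reversed(order):
            is_target = 1.0 if comm[w] != comm[s] else 0.0
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (is_target + delta[w])
        delta[s] = 0.0
        bb += delta
    return bb / 2.0  # each unordered pair visited from both endpoints


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1) if len(x) > 1 else 0.0
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def centrality_table(
    network: SymptomNetwork, assignment: ClusterAssignment | None = None
) -> pd.DataFrame:
    """Raw and z-scored node centralities, with bridge variants when communities exist."""
    table = node_centralities(network)
    if assignment is not None and assignment.n_communities >= 2:
        table = table.join(bridge_centralities(network, assignment))
    for col in list(table.columns):
        table[f"{col}_z"] = _zscore(table[col].to_numpy())
    return table
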