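"""Resampling-based accuracy and stability of edges, clusters and centralities.

The full estimation pipeline (EBIC graphical lasso, then walktrap) is re-run
on case resamples of the patient rows; edge-weight percentile intervals give
"significant" edges, and resampled cluster solutions are matched back to the
reference solution by greedy maximal Jaccard overlap to score how often each
symptom stays in its cluster.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ggm import EDGE_TOL, SymptomNetwork, select_network
from .network_metrics import DEFAULT_WALKTRAP_STEPS, ClusterAssignment, walktrap_communities

__all__ = ["StabilityReport", "resample_networks", "edge_significance", "cluster_stability"]

log = logging.getLogger(__name__)


@dataclass
class StabilityReport:
    n_resamples: int
    edge_ci: pd.DataFrame
    significant_edges: list[tuple[str, str]]
    per_symptom_same_cluster_prop: dict[str, float]
    cluster_count_distribution: dict[int, float]
    exact_cluster_replication_prop: dict[int, float]
    confidence: float = 0.95
    extras: dict = field(default_factory=dict)


def resample_networks(
    data: pd.DataFrame,
    B: int,
    seed: int,
    gamma: float = 0.5,
    n_lambdas: int = 100,
    mode: str = "bootstrap",
    subsample_frac: float = 0.9,
) -> list[SymptomNetwork]:
    """Re-estimate the network on ``B`` case resamples of the rows.

    ``mode="bootstrap"`` draws n rows with replacement; ``mode="subsample"``
    draws ``subsample_frac * n`` rows without replacement. A resample whose
    rows leave some column constant is redrawn (at most 10 times).
    """
    if mode not in {"bootstrap", "subsample"}:
        raise ValueError("mode must be 'bootstrap' or 'subsample'")
    rng = np.random.default_rng(seed)
    n = data.shape[0]
    m = n if mode == "bootstrap" else max(2, int(round(subsample_frac * n)))
    X = data.to_numpy(dtype=float)
    networks: list[SymptomNetwork] = []
    for b in range(B):
        for attempt in range(10):
            idx = (
                rng.integers(0, n, size=m)
                if mode == "bootstrap"
                else rng.permutation(n)[:m]
            )
            sub = X[idx]
            if np.all(sub.std(axis=0) > 0):
                break
            log.warning("resample %d attempt %d produced a constant column; redrawn", b, attempt)
        else:
            raise RuntimeError(f"resample {b}: constant column after 10 redraws")
        frame = pd.DataFrame(sub, columns=data.columns)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net, _ = select_network(frame, gamma=gamma, n_lambdas=n_lambdas)
        networks.append(net)
    return networks


def edge_significance(
    networks: list[SymptomNetwork],
    reference: SymptomNetwork,
    conf: float = 0.95,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Percentile interval per edge; significant iff the interval excludes 0
    and the reference weight is nonzero."""
    if not 0.0 < conf < 1.0:
        raise ValueError("conf must lie in (0, 1)")
    nodes = reference.nodes
    p = len(nodes)
    stack = np.stack([net.weights for net in networks])  # (B, p, p)
    alpha = (1.0 - conf) / 2.0
    lo = np.quantile(stack, alpha, axis=0)
    hi = np.quantile(stack, 1.0 - alpha, axis=0)
    iu = np.triu_indices(p, k=1)
    rows = []
    significant: list[tuple[str, str]] = []
    for i, j in zip(*iu):
        ref_w = reference.weights[i, j]
        sig = bool((lo[i, j] > 0 or hi[i, j] < 0) and abs(ref_w) > EDGE_TOL)
        rows.append(
            {
                "node_a": nodes[i],
                "node_b": nodes[j],
                "weight": ref_w,
                "ci_low": lo[i, j],
                "ci_high": hi[i, j],
                "significant": sig,
            }
        )
        if sig:
            significant.append((nodes[i], nodes[j]))
    return pd.DataFrame(rows), significant


def _greedy_jaccard_match(
    reference: dict[int, set[str]], resample: dict[int, set[str]]
) -> dict[int, int]:
    """Map resample cluster id -> reference cluster id, largest Jaccard first."""
    pairs = []
    for ref_id, ref_set in reference.items():
        for res_id, res_set in resample.items():
            inter = len(ref_set & res_set)
            union = len(ref_set | res_set)
            if union:
                pairs.append((inter / union, ref_id, res_id))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_ref: set[int] = set()
    mapping: dict[int, int] = {}
    for jac, ref_id, res_id in pairs:
        if jac == 0 or ref_id in used_ref or res_id in mapping:
            continue
        mapping[res_id] = ref_id
        used_ref.add(ref_id)
    return mapping


def cluster_stability(
    networks: list[SymptomNetwork],
    reference: ClusterAssignment,
    steps: int = DEFAULT_WALKTRAP_STEPS,
) -> tuple[dict[str, float], dict[int, float], dict[int, float]]:
    """Per-symptom same-cluster proportions, cluster-count distribution and
    exact replication proportion per reference cluster, across resamples."""
    symptoms = list(reference.labels)
    ref_sets: dict[int, set[str]] = {}
    for node, cid in reference.labels.items():
        ref_sets.setdefault(cid, set()).add(node)

    same = {s: 0 for s in symptoms}
    counts: dict[int, int] = {}
    exact = {cid: 0 for cid in ref_sets}
    B = len(networks)
    for net in networks:
        try:
            assignment = walktrap_communities(net, steps=steps)
        except ValueError:  # empty network
            counts[0] = counts.get(0, 0) + 1
            continue
        counts[assignment.n_communities] = counts.get(assignment.n_communities, 0) + 1
        res_sets: dict[int, set[str]] = {}
        for node, cid in assignment.labels.items():
            res_sets.setdefault(cid, set()).add(node)
        mapping = _greedy_jaccard_match(ref_sets, res_sets)
        for node in symptoms:
            res_id = assignment.labels[node]
            if mapping.get(res_id) == reference.labels[node]:
                same[node] += 1
        for cid, ref_set in ref_sets.items():
            if any(res_set == ref_set for res_set in res_sets.values()):
                exact[cid] += 1
    return (
        {s: c / B for s, c in same.items()},
        {k: c / B for k, c in sorted(counts.items())},
        {cid: c / B for cid, c in exact.items()},
    )


def stability_report(
    data: pd.DataFrame,
    reference_network: SymptomNetwork,
    reference_clusters: ClusterAssignment,
    B: int = 1000,
    seed: int = 0,
    conf: float = 0.95,
    gamma: float = 0.5,
    n_lambdas: int = 100,
    steps: int = DEFAULT_WALKTRAP_STEPS,
    mode: str = "bootstrap",
) -> StabilityReport:
    """Convenience wrapper running the full resampling assessment."""
    nets = resample_networks(data, B=B, seed=seed, gamma=gamma, n_lambdas=n_lambdas, mode=mode)
    edge_ci, significant = edge_significance(nets, reference_network, conf=conf)
    same, count_dist, exact = cluster_stability(nets, reference_clusters, steps=steps)
    return StabilityReport(
        n_resamples=B,
        edge_ci=edge_ci,
        significant_edges=significant,
        per_symptom_same_cluster_prop=same,
        cluster_count_distribution=count_dist,
        exact_cluster_replication_prop=exact,
        confidence=conf,
    )
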