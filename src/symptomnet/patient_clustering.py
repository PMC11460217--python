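"""Second-order patient clustering from symptom co-severity structure.

Each patient's severity vector x is summarized by the concordance matrix
x x^T / 100, which encodes which symptom pairs are jointly severe for that
patient. Pairwise patient similarity is the Adjusted Rand Index between the
discrete labelings the two concordance matrices induce on the p(p+1)/2
upper-triangle cells (severity products are integers 0..16 scaled by 1/100,
so labels are exact). The similarity matrix is then treated as a weighted
complete graph and walktrap community detection yields patient subgroups.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd

from .network_metrics import DEFAULT_WALKTRAP_STEPS, ClusterAssignment

__all__ = [
    "concordance_matrix",
    "ari_between_matrices",
    "patient_similarity",
    "detect_patient_subgroups",
    "subgroup_profiles",
]

_MAX_PRODUCT = 16  # 4 * 4


def concordance_matrix(x: np.ndarray) -> np.ndarray:
    """Outer product x x^T / 100 of one patient's severity vector."""
    x = np.asarray(x, dtype=float)
    return np.outer(x, x) / 100.0


def _cell_labels_from_matrix(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    iu = np.triu_indices(A.shape[0])
    labels = np.rint(A[iu] * 100.0).astype(np.int64)
    return labels


def _cell_labels_from_vector(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.int64)
    iu = np.triu_indices(x.size)
    return x[iu[0]] * x[iu[1]]


def _ari_from_labels(a: np.ndarray, b: np.ndarray) -> float:
    """Adjusted Rand Index of two labelings via the contingency-table formula.

    Degenerate case (denominator 0, e.g. both labelings constant): 1 if the
    two partitions are identical, 0 otherwise.
    """
    if a.size != b.size:
        raise ValueError("labelings must have the same length")
    n = a.size
    width = max(_MAX_PRODUCT, int(a.max()), int(b.max())) + 1
    cont = np.bincount(a * width + b, minlength=width * width).astype(np.float64)
    sum_sq = float(cont @ cont)
    a_marg = np.bincount(a, minlength=width).astype(np.float64)
    b_marg = np.bincount(b, minlength=width).astype(np.float64)
    sum_a = float(a_marg @ a_marg - n) / 2.0
    sum_b = float(b_marg @ b_marg - n) / 2.0
    index = (sum_sq - n) / 2.0
    total = n * (n - 1) / 2.0
    expected = sum_a * sum_b / total if total > 0 else 0.0
    max_index = (sum_a + sum_b) / 2.0
    denom = max_index - expected
    if abs(denom) < 1e-12:
        return 1.0 if abs(index - max_index) < 1e-12 else 0.0
    return float((index - expected) / denom)


def ari_between_matrices(A: np.ndarray, B: np.ndarray) -> float:
    """ARI between the cell labelings of two concordance matrices.

    The upper triangle including the diagonal of each matrix is read as a
    labeling of its cell positions by the (discrete) severity product; the
    standard chance-corrected pair-counting agreement is applied.
    """
    A = np.asarray(A)
    B = np.asarray(B)
    if A.shape != B.shape:
        raise ValueError(f"dimension mismatch: {A.shape} vs {B.shape}")
    return _ari_from_labels(_cell_labels_from_matrix(A), _cell_labels_from_matrix(B))


def patient_similarity(severity: pd.DataFrame) -> np.ndarray:
    """n x n matrix of pairwise concordance-matrix ARI values."""
    n = severity.shape[0]
    if n < 3:
        raise ValueError("need at least 3 patients")
    X = severity.to_numpy()
    if not np.issubdtype(X.dtype, np.integer):
        X = np.rint(X).astype(np.int64)
    labels = [_cell_labels_from_vector(X[i]) for i in range(n)]
    S = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = _ari_from_labels(labels[i], labels[j])
    return S


def detect_patient_subgroups(
    similarity: np.ndarray,
    runs: int = 11,
    seed: int = 0,
    steps: int = DEFAULT_WALKTRAP_STEPS,
) -> tuple[ClusterAssignment, np.ndarray]:
    """Walktrap subgroups on the (nonnegative) similarity graph.

    Negative ARI values are floored at 0 and the matrix is used as the
    weighted adjacency of a complete graph. Walktrap's merge procedure is
    deterministic given a node order, so the extra ``runs`` permute the node
    ordering as the randomization; final labels come from run 1 (identity
    order) and the returned consistency matrix holds the pairwise ARI
    between the runs' labelings.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    S = np.asarray(similarity, dtype=float)
    n = S.shape[0]
    W = np.clip(S, 0.0, None)
    np.fill_diagonal(W, 0.0)
    if not np.any(W > 0):
        raise ValueError("all-zero similarity matrix: no structure to cluster")
    rng = np.random.default_rng(seed)

    memberships: list[np.ndarray] = []
    for r in range(runs):
        perm = np.arange(n) if r == 0 else rng.permutation(n)
        Wp = W[np.ix_(perm, perm)]
        iu = np.triu_indices(n, k=1)
        mask = Wp[iu] > 0
        edges = list(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))
        g = ig.Graph(n=n, edges=edges)
        g.es["weight"] = Wp[iu][mask].tolist()
        member = np.asarray(
            g.community_walktrap(weights="weight", steps=steps).as_clustering().membership
        )
        unperm = np.empty(n, dtype=np.int64)
        unperm[perm] = member
        memberships.append(unperm)

    consistency = np.ones((runs, runs))
    for i in range(runs):
        for j in range(i + 1, runs):
            consistency[i, j] = consistency[j, i] = _ari_from_labels(
                memberships[i], memberships[j]
            )

    final = memberships[0]
    remap: dict[int, int] = {}
    labels: dict[str, int] = {}
    for k, raw in enumerate(final):
        if raw not in remap:
            remap[int(raw)] = len(remap) + 1
        labels[str(k)] = remap[int(raw)]
    return ClusterAssignment(labels=labels, n_communities=len(remap), method="walktrap"), consistency


def subgroup_labels_series(assignment: ClusterAssignment, index: pd.Index) -> pd.Series:
    """Relabel the positional assignment onto patient ids."""
    return pd.Series(
        [assignment.labels[str(i)] for i in range(len(index))], index=index, name="subgroup"
    )


def subgroup_profiles(severity: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-subgroup mean severity with normal-approximation 95% CIs.

    Returns a long table (subgroup, symptom, mean, ci_low, ci_high, n) plus
    rows for the whole cohort under subgroup id 0. Size-1 subgroups get
    missing CIs.
    """
    labels = labels.loc[severity.index]
    rows = []

    def block(frame: pd.DataFrame, gid: int) -> None:
        ng = frame.shape[0]
        means = frame.mean(axis=0)
        if ng > 1:
            half = 1.96 * frame.std(axis=0, ddof=1) / np.sqrt(ng)
        else:
            half = pd.Series(np.nan, index=frame.columns)
        for sym in frame.columns:
            rows.append(
                {
                    "subgroup": gid,
                    "symptom": sym,
                    "mean": means[sym],
                    "ci_low": means[sym] - half[sym],
                    "ci_high": means[sym] + half[sym],
                    "n": ng,
                }
            )

    block(severity, 0)
    for gid in sorted(labels.unique()):
        sub = severity.loc[labels == gid]
        if sub.empty:
            raise ValueError(f"subgroup {gid} is empty")
        block(sub, int(gid))
    return pd.DataFrame(rows)
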