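"""Redundancy screening and rank-based Gaussianization of severity data.

Before a Gaussian graphical model is estimated, near-duplicate symptom pairs
are detected by weighted topological overlap (the unique-variable-analysis
idea), each flagged pair is consolidated into a single latent severity score
via an equal-loading one-factor model, and every column is passed through a
nonparanormal (rank -> normal quantile) transform so that a Gaussian model
is appropriate for the ordinal 0-4 data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RedundancyReport",
    "ConsolidationMap",
    "weighted_topological_overlap",
    "detect_redundant_pairs",
    "consolidate_pair",
    "consolidate",
    "nonparanormal_transform",
    "shapiro_screen",
]

#: conventional wTO cutoff for flagging a redundant pair
DEFAULT_UVA_THRESHOLD = 0.25


@dataclass
class RedundancyReport:
    pairwise_overlap: pd.DataFrame
    flagged_pairs: list[tuple[str, str, float]]
    threshold_used: float


@dataclass
class ConsolidationMap:
    merged: list[tuple[tuple[str, str], str]]  # (pair, new latent name)
    resulting_symptom_count: int


def _check_columns(X: pd.DataFrame, min_rows: int = 10) -> None:
    if X.shape[1] < 2:
        raise ValueError("need at least 2 symptoms")
    if X.shape[0] < min_rows:
        raise ValueError(f"need at least {min_rows} patients")
    for col in X.columns:
        if X[col].nunique() < 2:
            raise ValueError(f"symptom column {col!r} is constant")


def weighted_topological_overlap(severity: pd.DataFrame) -> pd.DataFrame:
    """Pairwise wTO of the zero-diagonal Pearson association matrix.

    wTO_ij = |sum_k w_ik w_jk + w_ij| / (min(s_i, s_j) + 1 - |w_ij|) with
    s_i = sum_k |w_ik|; high overlap means two symptoms share the same
    neighbourhood of associations and likely measure one construct.
    """
    _check_columns(severity)
    w = np.corrcoef(severity.to_numpy(dtype=float), rowvar=False)
    np.fill_diagonal(w, 0.0)
    num = np.abs(w @ w + w)
    s = np.abs(w).sum(axis=1)
    den = np.minimum.outer(s, s) + 1.0 - np.abs(w)
    wto = num / den
    np.fill_diagonal(wto, 0.0)
    return pd.DataFrame(wto, index=severity.columns, columns=severity.columns)


def detect_redundant_pairs(overlap: pd.DataFrame, threshold: float = DEFAULT_UVA_THRESHOLD) -> RedundancyReport:
    """Greedy selection of disjoint symptom pairs with overlap >= threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    cols = list(overlap.columns)
    vals = overlap.to_numpy()
    candidates = [
        (vals[i, j], i, j)
        for i in range(len(cols))
        for j in range(i + 1, len(cols))
        if vals[i, j] >= threshold
    ]
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used: set[int] = set()
    flagged: list[tuple[str, str, float]] = []
    for value, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        flagged.append((cols[i], cols[j], float(value)))
    return RedundancyReport(pairwise_overlap=overlap, flagged_pairs=flagged, threshold_used=float(threshold))


def consolidate_pair(x_a: np.ndarray, x_b: np.ndarray) -> np.ndarray:
    """Merge two severity columns into one latent severity score on [0, 4].

    Fits the tau-equivalent (equal-loading) one-factor model to the
    standardized pair by maximum likelihood — the minimal identified
    two-indicator factor model — and returns the regression-method factor
    score, affinely rescaled to the 0-4 severity range. Under the equal
    loading lambda^2 = r the score is proportional to z_a + z_b.
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    r = np.corrcoef(x_a, x_b)[0, 1]
    if not np.isfinite(r) or r <= 0:
        raise ValueError(
            f"severity pair correlates non-positively (r={r:.3f}); consolidation is not advised"
        )
    z_a = (x_a - x_a.mean()) / x_a.std(ddof=1)
    z_b = (x_b - x_b.mean()) / x_b.std(ddof=1)
    lam = np.sqrt(r)
    # regression factor score lambda' Sigma^{-1} z for Sigma = [[1, r], [r, 1]]
    score = lam * (z_a + z_b) / (1.0 + r)
    lo, hi = score.min(), score.max()
    return (score - lo) / (hi - lo) * 4.0


def consolidate(
    severity: pd.DataFrame, report: RedundancyReport
) -> tuple[pd.DataFrame, ConsolidationMap]:
    """Apply every flagged merge, replacing each pair by one latent column."""
    out = severity.copy()
    merged: list[tuple[tuple[str, str], str]] = []
    for a, b, _ in report.flagged_pairs:
        new_name = f"{a}+{b}"
        out[new_name] = consolidate_pair(out[a].to_numpy(), out[b].to_numpy())
        out = out.drop(columns=[a, b])
        merged.append(((a, b), new_name))
    return out, ConsolidationMap(merged=merged, resulting_symptom_count=out.shape[1])


def nonparanormal_transform(
    severity: pd.DataFrame, npn_variant: str = "simple"
) -> pd.DataFrame:
    """Map each column through average ranks to normal quantiles.

    Column values get average ranks r_i (ties share the mean rank), are
    mapped to Phi^{-1}(r_i / (n + 1)) and rescaled to unit sample variance.
    The output depends only on within-column ranks, so any strictly monotone
    recoding of a column leaves it unchanged.

    ``npn_variant="winsorized"`` clamps the rank probabilities to
    [delta, 1 - delta] with delta = 1/(4 n^(1/4) sqrt(pi log n)), the
    truncation used in nonparanormal estimation theory; the simple n+1
    denominator is the default.
    """
    n = severity.shape[0]
    if npn_variant not in {"simple", "winsorized"}:
        raise ValueError("npn_variant must be 'simple' or 'winsorized'")
    out = {}
    for col in severity.columns:
        x = severity[col].to_numpy(dtype=float)
        if np.all(x == x[0]):
            raise ValueError(f"symptom column {col!r} is constant")
        u = stats.rankdata(x, method="average") / (n + 1)
        if npn_variant == "winsorized":
            delta = 1.0 / (4.0 * n**0.25 * np.sqrt(np.pi * np.log(n)))
            u = np.clip(u, delta, 1.0 - delta)
        q = stats.norm.ppf(u)
        out[col] = q / q.std(ddof=1)
    return pd.DataFrame(out, index=severity.index)


def shapiro_screen(severity: pd.DataFrame) -> pd.DataFrame:
    """Per-column Shapiro-Wilk statistic and p-value (reported, never gating)."""
    rows = []
    for col in severity.columns:
        res = stats.shapiro(severity[col].to_numpy(dtype=float))
        rows.append({"symptom": col, "W": float(res.statistic), "p": float(res.pvalue)})
    return pd.DataFrame(rows).set_index("symptom")
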