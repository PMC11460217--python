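"""Reproducible recovery experiments on planted synthetic cohorts.

Each function runs one self-contained experiment at a fixed, documented
problem size and returns plain numbers: ground-truth recovery rates for
symptom clusters and patient subgroups, solver-vs-oracle agreement gaps,
stability proportions and regression coverage. They are the computational
backbone of the analysis scripts and the acceptance checks.
"""

from __future__ import annotations

import hashlib
import warnings
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .ggm import glasso_fit, sample_correlation, select_network
from .network_metrics import walktrap_communities
from .patient_clustering import (
    ari_between_matrices,
    concordance_matrix,
    detect_patient_subgroups,
    patient_similarity,
    subgroup_labels_series,
)
from .pipeline import PipelineConfig, run_pipeline
from .preprocess import (
    detect_redundant_pairs,
    consolidate,
    nonparanormal_transform,
    weighted_topological_overlap,
)
from .stability import cluster_stability, resample_networks
from .subgroup_stats import fit_multinomial
from .synthetic_data import CohortSpec, generate_cohort

THREE_BLOCKS_P12 = ((0, 1, 2, 3), (4, 5, 6, 7), (8, 9, 10, 11))


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def block_cohort(seed: int, n_patients: int = 1000) -> "CohortSpec":
    return CohortSpec(
        n_patients=n_patients,
        n_symptoms=12,
        symptom_blocks=THREE_BLOCKS_P12,
        within_block_corr=0.4,
        seed=seed,
    )


def consolidation_experiment(seed: int, n_patients: int = 600):
    """32-symptom cohort with one planted near-duplicate pair.

    Returns (n pairs evaluated by the consolidated network, symptoms analyzed
    after consolidation): the combinatorics the preprocessing stage implies.
    """
    p = 31
    cohort = generate_cohort(
        CohortSpec(n_patients=n_patients, n_symptoms=p, symptom_blocks=(), seed=seed)
    )
    sev = cohort.severity.copy()
    rng = np.random.default_rng(seed + 1)
    dup = sev.iloc[:, 0].to_numpy().copy()
    flip = rng.random(n_patients) < 0.05
    dup[flip] = rng.integers(0, 5, size=int(flip.sum()))
    sev["symptom_32"] = dup  # 32 symptoms, one redundant pair
    report = detect_redundant_pairs(weighted_topological_overlap(sev))
    merged, cmap = consolidate(sev, report)
    p_final = cmap.resulting_symptom_count
    n_pairs = p_final * (p_final - 1) // 2
    return n_pairs, p_final


def glasso_inverse_gap(seed: int, n_patients: int = 500) -> float:
    """Max |K_glasso(lambda=0) - S^-1| on a well-conditioned p=5 input."""
    cohort = generate_cohort(
        CohortSpec(
            n_patients=n_patients,
            n_symptoms=5,
            symptom_blocks=((0, 1, 2),),
            within_block_corr=0.4,
            seed=seed,
        )
    )
    S = sample_correlation(nonparanormal_transform(cohort.severity))
    return float(np.abs(glasso_fit(S, 0.0) - np.linalg.inv(S)).max())


def pair_counting_ari(a: np.ndarray, b: np.ndarray) -> float:
    """Definition-level ARI by exhaustive enumeration of element pairs."""
    n = len(a)
    n11 = sum(
        (a[i] == a[j]) and (b[i] == b[j]) for i, j in combinations(range(n), 2)
    )
    sum_a = sum(a[i] == a[j] for i, j in combinations(range(n), 2))
    sum_b = sum(b[i] == b[j] for i, j in combinations(range(n), 2))
    total = n * (n - 1) / 2
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    if abs(max_index - expected) < 1e-12:
        return 1.0 if abs(n11 - max_index) < 1e-12 else 0.0
    return (n11 - expected) / (max_index - expected)


def ari_oracle_gap(seed: int, trials: int = 1000) -> float:
    """Max |matrix-ARI - brute-force pair-counting ARI| over random pairs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(trials):
        p = int(rng.integers(2, 7))
        x = rng.integers(0, 5, size=p)
        y = rng.integers(0, 5, size=p)
        A, B = concordance_matrix(x), concordance_matrix(y)
        got = ari_between_matrices(A, B)
        iu = np.triu_indices(p)
        expected = pair_counting_ari(
            np.rint(A[iu] * 100).astype(int), np.rint(B[iu] * 100).astype(int)
        )
        worst = max(worst, abs(got - expected))
    return worst


def symptom_cluster_recovery(seed: int, n_seeds: int = 20, n_patients: int = 1000) -> float:
    """Proportion of cohorts whose walktrap solution matches the planted
    3-block structure exactly (ARI = 1)."""
    hits = 0
    for s in _child_seeds(seed, n_seeds):
        cohort = generate_cohort(block_cohort(s, n_patients))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net, _ = select_network(nonparanormal_transform(cohort.severity))
        cl = walktrap_communities(net)
        truth = [cohort.true_symptom_clusters[v] for v in net.nodes]
        est = [cl.labels[v] for v in net.nodes]
        hits += adjusted_rand_score(truth, est) == 1.0
    return hits / n_seeds


def subgroup_cohort(seed: int, n_patients: int = 300, p: int = 20) -> CohortSpec:
    prof = np.zeros((3, p))
    prof[0, : p // 3] = 2.0
    prof[1, p // 3 : 2 * p // 3] = 2.0
    prof[2, 2 * p // 3 :] = 2.0
    return CohortSpec(
        n_patients=n_patients,
        n_symptoms=p,
        symptom_blocks=(),
        subgroup_profiles=tuple(map(tuple, prof)),
        subgroup_proportions=(1 / 3, 1 / 3, 1 / 3),
        seed=seed,
    )


def patient_subgroup_recovery(seed: int, n_seeds: int = 20) -> float:
    """Proportion of cohorts where detected subgroups reach ARI >= 0.8 vs truth."""
    hits = 0
    for s in _child_seeds(seed, n_seeds):
        cohort = generate_cohort(subgroup_cohort(s))
        sim = patient_similarity(cohort.severity)
        assignment, _ = detect_patient_subgroups(sim, runs=1, seed=s)
        labels = subgroup_labels_series(assignment, cohort.severity.index)
        hits += adjusted_rand_score(cohort.true_subgroups, labels) >= 0.8
    return hits / n_seeds


def cluster_stability_experiment(seed: int, B: int = 200, n_patients: int = 1000):
    """Bootstrap cluster stability of the well-separated 3-block cohort.

    Returns (min per-symptom same-cluster proportion, proportion of
    resamples with exactly 3 clusters).
    """
    cohort = generate_cohort(block_cohort(seed, n_patients))
    data = nonparanormal_transform(cohort.severity)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net, _ = select_network(data)
    reference = walktrap_communities(net)
    nets = resample_networks(data, B=B, seed=seed + 1)
    same, count_dist, _ = cluster_stability(nets, reference)
    return min(same.values()), count_dist.get(3, 0.0)


def regression_recovery(seed: int, n_seeds: int = 20, n_patients: int = 2000):
    """Planted treatment log-odds 1.2 (OR 3.32): Wald-CI coverage of the truth
    and the proportion of fits whose AIC beats the intercept-only model."""
    beta_true = 1.2
    beta = np.zeros((3, 4))
    beta[1, 1] = beta_true
    beta[2, 0] = -0.8
    covered = aic_better = 0
    for s in _child_seeds(seed, n_seeds):
        cohort = generate_cohort(
            CohortSpec(
                n_patients=n_patients,
                n_symptoms=2,
                symptom_blocks=(),
                subgroup_profiles=((0.0, 0.0),) * 3,
                subgroup_proportions=(0.4, 0.3, 0.3),
                covariate_effects=tuple(map(tuple, beta)),
                seed=s,
            )
        )
        model = fit_multinomial(cohort.covariates, cohort.true_subgroups, reference=1)
        row = model.coefficients.query("subgroup == 2 and term == 'on_treatment'").iloc[0]
        lo, hi = row["coef"] - 1.96 * row["se"], row["coef"] + 1.96 * row["se"]
        covered += lo <= beta_true <= hi
        n_null_params = 2  # intercepts of the two non-reference equations
        null_aic = -2 * model.null_log_likelihood + 2 * n_null_params
        aic_better += model.aic < null_aic
    return covered / n_seeds, aic_better / n_seeds


def pipeline_cohort(seed: int, n_patients: int = 400) -> CohortSpec:
    """End-to-end cohort: 3 symptom blocks plus 3 patient subgroups with
    block-aligned severity profiles and planted covariate effects."""
    p = 12
    prof = np.zeros((3, p))
    prof[0, :4] = 1.5
    prof[1, 4:8] = 1.5
    prof[2, 8:] = 1.5
    beta = np.zeros((3, 4))
    beta[1, 1] = 1.2
    beta[2, 0] = -0.8
    return CohortSpec(
        n_patients=n_patients,
        n_symptoms=p,
        symptom_blocks=THREE_BLOCKS_P12,
        within_block_corr=0.4,
        subgroup_profiles=tuple(map(tuple, prof)),
        subgroup_proportions=(0.34, 0.33, 0.33),
        covariate_effects=tuple(map(tuple, beta)),
        seed=seed,
    )


def demo_cohort(seed: int, n_patients: int = 1000):
    """Demonstration cohort for the analysis walk-through.

    30 symptoms sharing a general burden factor (latent correlation 0.15),
    three equal patient subgroups each elevating an interleaved third of the
    symptoms by 0.9 sigma (so symptom clusters emerge from co-elevation, the
    way severity clusters arise from patient heterogeneity in real cohorts),
    planted covariate effects on subgroup membership, and one planted
    near-duplicate symptom (5% corrupted copy of symptom 1) for the
    redundancy stage. Returns (severity with duplicate, covariates, truth).
    """
    p = 30
    prof = np.zeros((3, p))
    for g in range(3):
        prof[g, [i for i in range(p) if i % 3 == g]] = 0.9
    beta = np.zeros((3, 4))
    beta[1, 1] = 1.2
    beta[2, 0] = -0.8
    spec = CohortSpec(
        n_patients=n_patients,
        n_symptoms=p,
        symptom_blocks=(tuple(range(p)),),
        within_block_corr=0.15,
        subgroup_profiles=tuple(map(tuple, prof)),
        subgroup_proportions=(0.34, 0.33, 0.33),
        covariate_effects=tuple(map(tuple, beta)),
        seed=seed,
    )
    cohort = generate_cohort(spec)
    severity = cohort.severity.copy()
    rng = np.random.default_rng(seed + 1)
    dup = severity.iloc[:, 0].to_numpy().copy()
    flip = rng.random(n_patients) < 0.05
    dup[flip] = rng.integers(0, 5, size=int(flip.sum()))
    severity["symptom_31"] = dup
    truth = {
        "true_symptom_clusters": {
            name: (i % 3) + 1 for i, name in enumerate(cohort.severity.columns)
        },
        "true_subgroups": cohort.true_subgroups.to_dict(),
    }
    return severity, cohort.covariates, truth


def _tree_digest(directory: Path) -> dict[str, str]:
    return {
        f.name: hashlib.sha256(f.read_bytes()).hexdigest()
        for f in sorted(Path(directory).iterdir())
        if f.is_file()
    }


def determinism_check(seed: int, workdir: str | Path, B: int = 200) -> bool:
    """Run the full pipeline twice with one seed; True iff byte-identical."""
    workdir = Path(workdir)
    cohort = generate_cohort(pipeline_cohort(seed))
    cfg = PipelineConfig(
        seed=seed, b_resamples=B, n_lambdas=20, consistency_runs=3, write_similarity=True
    )
    run_pipeline(cohort.severity, cohort.covariates, cfg, workdir / "run1")
    run_pipeline(cohort.severity, cohort.covariates, cfg, workdir / "run2")
    return _tree_digest(workdir / "run1") == _tree_digest(workdir / "run2")
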