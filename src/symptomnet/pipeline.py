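"""End-to-end orchestration: preprocess -> network -> metrics -> stability ->
patient subgroups -> subgroup regression, with a reproducibility manifest.

All randomness flows from a single root seed that is split per stage, so any
stage can be reproduced in isolation and the whole run is byte-identical for
a fixed seed and configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .ggm import select_network
from .network_metrics import (
    DEFAULT_WALKTRAP_STEPS,
    centrality_table,
    walktrap_communities,
)
from .patient_clustering import (
    detect_patient_subgroups,
    patient_similarity,
    subgroup_labels_series,
    subgroup_profiles,
)
from .preprocess import (
    DEFAULT_UVA_THRESHOLD,
    consolidate,
    detect_redundant_pairs,
    nonparanormal_transform,
    shapiro_screen,
    weighted_topological_overlap,
)
from .stability import stability_report
from .subgroup_stats import fit_multinomial, select_reference_group

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int
    uva_threshold: float = DEFAULT_UVA_THRESHOLD
    gamma: float = 0.5
    n_lambdas: int = 100
    walktrap_steps: int = DEFAULT_WALKTRAP_STEPS
    b_resamples: int = 1000
    confidence: float = 0.95
    consistency_runs: int = 11
    reference_group: int | None = None
    resample_mode: str = "bootstrap"
    subgroup_min_edges_frac: float = 0.5  # gate: per-subgroup network needs >= frac * p edges
    write_similarity: bool = True

    def validate(self) -> None:
        if not 0 < self.uva_threshold <= 1:
            raise ValueError("uva_threshold must lie in (0, 1]")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must lie in (0, 1)")
        if self.gamma < 0 or self.n_lambdas < 2 or self.b_resamples < 1:
            raise ValueError("invalid gamma / n_lambdas / b_resamples")
        if self.consistency_runs < 1 or self.walktrap_steps < 1:
            raise ValueError("invalid consistency_runs / walktrap_steps")


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(3)
    names = ["stability", "subgroups", "spare"]
    return {name: int(child.generate_state(1)[0] % (2**31)) for name, child in zip(names, children)}


def _float_fmt(x: float) -> str:
    return f"{x:.10g}"


def run_pipeline(
    severity: pd.DataFrame,
    covariates: pd.DataFrame,
    config: PipelineConfig,
    outdir: str | Path,
) -> dict:
    """Run every stage, writing artifacts under ``outdir``; returns the manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)

    complete = severity.dropna()
    dropped = severity.index.difference(complete.index)
    if len(dropped):
        log.info("dropped %d incomplete patient rows", len(dropped))
    severity = complete.astype(int)
    covariates = covariates.loc[severity.index]
    log.info("stage preprocess: %d patients, %d symptoms", *severity.shape)

    shapiro = shapiro_screen(severity)
    shapiro.to_csv(outdir / "shapiro_screen.csv", float_format="%.10g")

    overlap = weighted_topological_overlap(severity)
    report = detect_redundant_pairs(overlap, threshold=config.uva_threshold)
    consolidated, cmap = consolidate(severity, report)
    io.write_json(
        {
            "flagged_pairs": [list(t) for t in report.flagged_pairs],
            "threshold_used": report.threshold_used,
        },
        outdir / "redundancy_report.json",
    )
    io.write_json(
        {
            "merged": [[list(pair), name] for pair, name in cmap.merged],
            "resulting_symptom_count": cmap.resulting_symptom_count,
        },
        outdir / "consolidation_map.json",
    )
    transformed = nonparanormal_transform(consolidated)
    transformed.to_csv(outdir / "transformed.csv", index_label="patient_id", float_format="%.10g")

    log.info("stage network: p=%d after consolidation", transformed.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        network, _path = select_network(transformed, gamma=config.gamma, n_lambdas=config.n_lambdas)
    io.write_network_json(network, outdir / "network.json")
    network.edge_list().to_csv(outdir / "edges.tsv", sep="\t", index=False, float_format="%.10g")
    log.info("stage network: %d edges at lambda=%.4g", network.edge_count, network.lambda_selected)

    clusters = walktrap_communities(network, steps=config.walktrap_steps)
    io.write_json(
        {"labels": clusters.labels, "n_communities": clusters.n_communities, "method": clusters.method},
        outdir / "symptom_clusters.json",
    )
    table = centrality_table(network, clusters)
    table.to_csv(outdir / "centralities.csv", float_format="%.10g")
    log.info("stage metrics: %d symptom clusters", clusters.n_communities)

    log.info("stage stability: B=%d", config.b_resamples)
    stab = stability_report(
        transformed,
        network,
        clusters,
        B=config.b_resamples,
        seed=seeds["stability"],
        conf=config.confidence,
        gamma=config.gamma,
        n_lambdas=config.n_lambdas,
        steps=config.walktrap_steps,
        mode=config.resample_mode,
    )
    stab.edge_ci.to_csv(outdir / "edge_ci.csv", index=False, float_format="%.10g")
    io.write_json(
        {
            "n_resamples": stab.n_resamples,
            "confidence": stab.confidence,
            "n_significant_edges": len(stab.significant_edges),
            "per_symptom_same_cluster_prop": stab.per_symptom_same_cluster_prop,
            "cluster_count_distribution": {str(k): v for k, v in stab.cluster_count_distribution.items()},
            "exact_cluster_replication_prop": {
                str(k): v for k, v in stab.exact_cluster_replication_prop.items()
            },
        },
        outdir / "stability.json",
    )

    log.info("stage subgroups: similarity over %d patients", severity.shape[0])
    sim = patient_similarity(severity)
    if config.write_similarity:
        pd.DataFrame(sim, index=severity.index, columns=severity.index).to_csv(
            outdir / "patient_similarity.csv", float_format="%.10g"
        )
    assignment, consistency = detect_patient_subgroups(
        sim, runs=config.consistency_runs, seed=seeds["subgroups"], steps=config.walktrap_steps
    )
    subgroups = subgroup_labels_series(assignment, severity.index)
    subgroups.to_frame().to_csv(outdir / "patient_subgroups.csv", index_label="patient_id")
    io.write_json(
        {"n_subgroups": assignment.n_communities, "consistency_ari": consistency.tolist()},
        outdir / "subgroup_consistency.json",
    )
    profiles = subgroup_profiles(severity, subgroups)
    profiles.to_csv(outdir / "subgroup_profiles.csv", index=False, float_format="%.10g")
    log.info("stage subgroups: %d patient subgroups", assignment.n_communities)

    # per-subgroup networks, skipping sparse/unstable subgroups
    subgroup_networks: dict[int, int] = {}
    skipped: dict[int, str] = {}
    for gid in sorted(subgroups.unique()):
        sub = consolidated.loc[subgroups == gid]
        p = sub.shape[1]
        try:
            sub_t = nonparanormal_transform(sub)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sub_net, _ = select_network(sub_t, gamma=config.gamma, n_lambdas=config.n_lambdas)
        except ValueError as exc:
            skipped[int(gid)] = f"estimation failed: {exc}"
            log.info("subgroup %d network skipped (%s)", gid, exc)
            continue
        min_edges = config.subgroup_min_edges_frac * p
        if sub_net.edge_count < min_edges:
            skipped[int(gid)] = (
                f"sparse/unstable: {sub_net.edge_count} edges < required {min_edges:.0f}"
            )
            log.info("subgroup %d network skipped: %s", gid, skipped[int(gid)])
            continue
        io.write_network_json(sub_net, outdir / f"network_subgroup_{gid}.json")
        sub_table = centrality_table(sub_net)
        sub_table.to_csv(outdir / f"centralities_subgroup_{gid}.csv", float_format="%.10g")
        subgroup_networks[int(gid)] = sub_net.edge_count
    io.write_json(
        {"built": subgroup_networks, "skipped": skipped}, outdir / "subgroup_networks.json"
    )

    regression = None
    if assignment.n_communities >= 2:
        reference = (
            config.reference_group
            if config.reference_group is not None
            else select_reference_group(covariates, subgroups)
        )
        model = fit_multinomial(covariates, subgroups, reference=reference)
        model.coefficients.to_csv(outdir / "regression_table.csv", index=False, float_format="%.10g")
        regression = {
            "reference_group": model.reference_group,
            "aic": model.aic,
            "pseudo_r2_cragg_uhler": model.pseudo_r2_cragg_uhler,
            "lr_chi2": model.lr_chi2,
            "lr_p": model.lr_p,
            "n": model.n,
        }
        io.write_json(regression, outdir / "regression_fit.json")
        log.info("stage regression: reference subgroup %d, AIC %.1f", reference, model.aic)
    else:
        log.info("stage regression skipped: only one subgroup detected")

    config_dict = asdict(config)
    manifest = {
        "config": config_dict,
        "config_hash": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_patients": int(severity.shape[0]),
        "n_symptoms_input": int(severity.shape[1]),
        "n_symptoms_analyzed": int(transformed.shape[1]),
        "n_edges": network.edge_count,
        "n_symptom_clusters": clusters.n_communities,
        "n_subgroups": assignment.n_communities,
        "versions": _versions(),
    }
    io.write_json(manifest, outdir / "manifest.json")
    return manifest


def _versions() -> dict[str, str]:
    import igraph
    import sklearn
    import statsmodels

    import symptomnet

    return {
        "symptomnet": symptomnet.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "python-igraph": igraph.__version__,
        "statsmodels": statsmodels.__version__,
    }
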