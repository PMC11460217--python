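"""Synthetic oncology-cohort generator with known ground truth.

Severity data on the 0-4 ordinal scale are produced by a Gaussian copula:
each patient's latent symptom vector is multivariate normal with a planted
block-exchangeable correlation structure (symptom clusters) and a
subgroup-specific mean shift (patient subgroups); the latent values are cut
at fixed thresholds into the five severity categories. Covariates are drawn
first and subgroup membership follows a multinomial-logit model in those
covariates, so the generator's covariate coefficients are the *population*
log-odds that the regression stage should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "planted_precision",
    "generate_cohort",
    "default_symptom_names",
]

#: thresholds giving roughly 54% zeros per symptom and a long right tail,
#: the zero-inflated shape typical of symptom-severity checklists
DEFAULT_THRESHOLDS: tuple[float, ...] = (0.1, 0.9, 1.6, 2.3)


def default_symptom_names(p: int) -> list[str]:
    return [f"symptom_{i:02d}" for i in range(1, p + 1)]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``symptom_blocks`` are disjoint 0-based index sets planting the symptom
    clusters; symptoms outside every block behave as singleton blocks.
    ``subgroup_profiles`` is a (G, p) array of latent mean shifts in units of
    the latent standard deviation. ``covariate_effects`` is a (G, 4) array of
    multinomial log-odds (vs. subgroup 0) for the design
    [age_std, on_treatment, diag_gi, diag_other]; ``None`` draws subgroups
    directly from ``subgroup_proportions``.
    """

    n_patients: int
    n_symptoms: int
    symptom_blocks: tuple[tuple[int, ...], ...]
    within_block_corr: float = 0.4
    between_block_corr: float = 0.0
    subgroup_profiles: tuple[tuple[float, ...], ...] = ((0.0,),)
    subgroup_proportions: tuple[float, ...] = (1.0,)
    covariate_effects: tuple[tuple[float, ...], ...] | None = None
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    seed: int = 0
    symptom_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        p = self.n_symptoms
        if self.n_patients <= 0 or p <= 0:
            raise ValueError("n_patients and n_symptoms must be positive")
        seen: set[int] = set()
        for block in self.symptom_blocks:
            if len(block) == 0:
                raise ValueError("empty symptom block")
            for idx in block:
                if not 0 <= idx < p:
                    raise ValueError(f"symptom index {idx} outside 0..{p - 1}")
                if idx in seen:
                    raise ValueError(f"symptom index {idx} appears in two blocks")
                seen.add(idx)
        props = np.asarray(self.subgroup_proportions, dtype=float)
        if abs(props.sum() - 1.0) > 1e-12:
            raise ValueError("subgroup_proportions must sum to 1 within 1e-12")
        if np.any(props <= 0):
            raise ValueError("zero-probability subgroup")
        profiles = np.asarray(self.subgroup_profiles, dtype=float)
        if profiles.ndim != 2 and not (profiles.ndim == 1 and len(props) == 1):
            raise ValueError("subgroup_profiles must be a (G, p) array")
        profiles = np.atleast_2d(profiles)
        if profiles.shape[0] != len(props):
            raise ValueError("one profile per subgroup required")
        thr = np.asarray(self.thresholds, dtype=float)
        if thr.size != 4 or np.any(np.diff(thr) <= 0):
            raise ValueError("thresholds must be 4 strictly increasing reals")
        if self.covariate_effects is not None:
            eff = np.asarray(self.covariate_effects, dtype=float)
            if eff.shape != (len(props), 4):
                raise ValueError("covariate_effects must have shape (n_subgroups, 4)")
        if self.symptom_names and len(self.symptom_names) != p:
            raise ValueError("symptom_names length must equal n_symptoms")

    @property
    def names(self) -> list[str]:
        return list(self.symptom_names) if self.symptom_names else default_symptom_names(self.n_symptoms)

    @property
    def profiles_array(self) -> np.ndarray:
        prof = np.atleast_2d(np.asarray(self.subgroup_profiles, dtype=float))
        if prof.shape[1] == 1 and self.n_symptoms > 1:
            prof = np.repeat(prof, self.n_symptoms, axis=1)
        return prof


@dataclass
class SyntheticCohort:
    severity: pd.DataFrame                 # n x p integers 0..4, patient ids as index
    true_symptom_clusters: dict[str, int]  # symptom name -> planted block id (1-based)
    true_subgroups: pd.Series              # patient id -> planted subgroup id (1-based)
    covariates: pd.DataFrame
    latent_precision: np.ndarray


def planted_precision(
    symptom_blocks: tuple[tuple[int, ...], ...],
    within_block_corr: float,
    between_block_corr: float,
    n_symptoms: int,
) -> np.ndarray:
    """Precision matrix whose inverse is the planted block correlation matrix.

    Inside each block every pair correlates at ``within_block_corr``; every
    other pair correlates at ``between_block_corr``. When the between-block
    correlation is zero the inverse is taken block by block so off-block
    precision entries are exactly zero.
    """
    R = _block_correlation(symptom_blocks, within_block_corr, between_block_corr, n_symptoms)
    eigvals = np.linalg.eigvalsh(R)
    if eigvals[0] <= 1e-10:
        raise ValueError(
            "requested block correlations are not positive definite "
            f"(smallest eigenvalue {eigvals[0]:.3e})"
        )
    if between_block_corr == 0.0:
        K = np.zeros_like(R)
        for block in _full_partition(symptom_blocks, n_symptoms):
            idx = np.asarray(block)
            K[np.ix_(idx, idx)] = np.linalg.inv(R[np.ix_(idx, idx)])
    else:
        K = np.linalg.inv(R)
    return (K + K.T) / 2.0


def _full_partition(blocks: tuple[tuple[int, ...], ...], p: int) -> list[tuple[int, ...]]:
    covered = {i for b in blocks for i in b}
    out = [tuple(sorted(b)) for b in blocks]
    out.extend((i,) for i in range(p) if i not in covered)
    return out


def _block_correlation(
    blocks: tuple[tuple[int, ...], ...], within: float, between: float, p: int
) -> np.ndarray:
    R = np.full((p, p), float(between))
    for block in blocks:
        idx = np.asarray(block)
        R[np.ix_(idx, idx)] = within
    np.fill_diagonal(R, 1.0)
    return R


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Age-like continuous, treatment-like binary, diagnosis-like categorical."""
    age = rng.normal(60.0, 12.0, size=n)
    on_treatment = rng.integers(0, 2, size=n)
    diagnosis = rng.choice(["breast", "gi", "other"], size=n, p=[0.5, 0.25, 0.25])
    return pd.DataFrame(
        {"age": age, "on_treatment": on_treatment, "diagnosis": diagnosis},
        index=[f"patient_{i + 1:05d}" for i in range(n)],
    )


def covariate_design(covariates: pd.DataFrame) -> np.ndarray:
    """Design [age_std, on_treatment, diag_gi, diag_other] used by the planted logit."""
    age_std = (covariates["age"].to_numpy() - 60.0) / 12.0
    diag = covariates["diagnosis"].to_numpy()
    return np.column_stack(
        [
            age_std,
            covariates["on_treatment"].to_numpy().astype(float),
            (diag == "gi").astype(float),
            (diag == "other").astype(float),
        ]
    )


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw one cohort; identical spec and seed give byte-identical output."""
    ss = np.random.SeedSequence(spec.seed)
    rng_cov, rng_grp, rng_lat = (np.random.default_rng(s) for s in ss.spawn(3))

    p = spec.n_symptoms
    n = spec.n_patients
    props = np.asarray(spec.subgroup_proportions, dtype=float)
    G = len(props)

    K = planted_precision(spec.symptom_blocks, spec.within_block_corr, spec.between_block_corr, p)
    R = np.linalg.inv(K)
    R = (R + R.T) / 2.0

    covariates = _draw_covariates(rng_cov, n)

    if spec.covariate_effects is None:
        groups = rng_grp.choice(G, size=n, p=props)
    else:
        beta = np.asarray(spec.covariate_effects, dtype=float)  # (G, 4)
        X = covariate_design(covariates)
        eta = np.log(props)[None, :] + X @ beta.T
        eta -= eta.max(axis=1, keepdims=True)
        prob = np.exp(eta)
        prob /= prob.sum(axis=1, keepdims=True)
        u = rng_grp.random(n)
        groups = (prob.cumsum(axis=1) < u[:, None]).sum(axis=1)

    L = np.linalg.cholesky(R)
    eps = rng_lat.standard_normal((n, p))
    latent = eps @ L.T + spec.profiles_array[groups]
    severity = np.digitize(latent, np.asarray(spec.thresholds, dtype=float)).astype(np.int64)

    names = spec.names
    severity_df = pd.DataFrame(severity, index=covariates.index, columns=names)

    labels: dict[str, int] = {}
    for cid, block in enumerate(_full_partition(spec.symptom_blocks, p), start=1):
        for idx in block:
            labels[names[idx]] = cid

    return SyntheticCohort(
        severity=severity_df,
        true_symptom_clusters=labels,
        true_subgroups=pd.Series(groups + 1, index=covariates.index, name="subgroup"),
        covariates=covariates,
        latent_precision=K,
    )
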