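import warnings

import numpy as np
import pandas as pd
import pytest

from symptomnet.ggm import SymptomNetwork, select_network
from symptomnet.preprocess import nonparanormal_transform
from symptomnet.synthetic_data import CohortSpec, generate_cohort

THREE_BLOCKS = ((0, 1, 2, 3), (4, 5, 6, 7), (8, 9, 10, 11))


def block_cohort_spec(seed: int = 0, n: int = 1000) -> CohortSpec:
    """Three planted 4-symptom blocks, within-block correlation 0.4."""
    return CohortSpec(
        n_patients=n,
        n_symptoms=12,
        symptom_blocks=THREE_BLOCKS,
        within_block_corr=0.4,
        seed=seed,
    )


def subgroup_cohort_spec(seed: int = 0, n: int = 300, p: int = 20) -> CohortSpec:
    """Three patient subgroups with disjoint 2-sigma elevated symptom sets."""
    prof = np.zeros((3, p))
    prof[0, : p // 3] = 2.0
    prof[1, p // 3 : 2 * p // 3] = 2.0
    prof[2, 2 * p // 3 :] = 2.0
    return CohortSpec(
        n_patients=n,
        n_symptoms=p,
        symptom_blocks=(),
        subgroup_profiles=tuple(map(tuple, prof)),
        subgroup_proportions=(1 / 3, 1 / 3, 1 / 3),
        seed=seed,
    )


def fit_network(severity: pd.DataFrame, **kwargs) -> SymptomNetwork:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net, _ = select_network(nonparanormal_transform(severity), **kwargs)
    return net


def make_network(weights: np.ndarray, nodes: list[str] | None = None) -> SymptomNetwork:
    p = weights.shape[0]
    nodes = nodes or [f"n{i}" for i in range(p)]
    return SymptomNetwork(
        nodes=nodes, weights=weights, lambda_selected=0.1, gamma=0.5, n_used=100
    )


def two_clique_weights(bridge: float = 0.0) -> np.ndarray:
    W = np.zeros((8, 8))
    for block in ((0, 1, 2, 3), (4, 5, 6, 7)):
        for i in block:
            for j in block:
                if i != j:
                    W[i, j] = 0.5
    if bridge:
        W[3, 4] = W[4, 3] = bridge
    return W


@pytest.fixture(scope="session")
def block_cohort():
    return generate_cohort(block_cohort_spec(seed=0))


@pytest.fixture(scope="session")
def block_network(block_cohort):
    return fit_network(block_cohort.severity)
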