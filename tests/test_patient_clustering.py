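"""Concordance matrices, matrix-ARI similarity and patient subgroup detection."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from symptomnet.patient_clustering import (
    _ari_from_labels,
    ari_between_matrices,
    concordance_matrix,
    detect_patient_subgroups,
    patient_similarity,
    subgroup_labels_series,
    subgroup_profiles,
)
from symptomnet.synthetic_data import generate_cohort

from conftest import subgroup_cohort_spec


def pair_counting_ari(a: np.ndarray, b: np.ndarray) -> float:
    """Brute-force ARI: enumerate all element pairs and count co-assignments."""
    n = len(a)
    n11 = n10 = n01 = n00 = 0
    for i, j in combinations(range(n), 2):
        same_a = a[i] == a[j]
        same_b = b[i] == b[j]
        n11 += same_a and same_b
        n10 += same_a and not same_b
        n01 += same_b and not same_a
        n00 += not same_a and not same_b
    total = n * (n - 1) / 2
    sum_a = n11 + n10
    sum_b = n11 + n01
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    if abs(max_index - expected) < 1e-12:
        return 1.0 if abs(n11 - max_index) < 1e-12 else 0.0
    return (n11 - expected) / (max_index - expected)


class TestConcordanceMatrix:
    def test_all_zero_vector(self):
        np.testing.assert_array_equal(concordance_matrix(np.zeros(3)), np.zeros((3, 3)))

    def test_four_zero_pair(self):
        np.testing.assert_allclose(
            concordance_matrix(np.array([4, 0])), np.array([[0.16, 0.0], [0.0, 0.0]])
        )

    def test_direct_arithmetic(self):
        C = concordance_matrix(np.array([1, 2, 3]))
        assert C[1, 2] == pytest.approx(0.06)
        assert C[0, 0] == pytest.approx(0.01)


class TestAriBetweenMatrices:
    def test_identical_matrices_give_one(self):
        x = np.array([0, 1, 2, 3, 4])
        A = concordance_matrix(x)
        assert ari_between_matrices(A, A) == 1.0

    def test_both_constant_defined_as_one(self):
        A = concordance_matrix(np.zeros(4))
        B = concordance_matrix(np.zeros(4))
        assert ari_between_matrices(A, B) == 1.0

    def test_small_pair_matches_pair_counting_oracle(self):
        x, y = np.array([1, 2, 0]), np.array([2, 1, 0])
        A, B = concordance_matrix(x), concordance_matrix(y)
        iu = np.triu_indices(3)
        a = np.rint(A[iu] * 100).astype(int)
        b = np.rint(B[iu] * 100).astype(int)
        assert ari_between_matrices(A, B) == pytest.approx(pair_counting_ari(a, b), abs=1e-12)

    def test_random_pairs_match_oracles(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.integers(2, 7)
            x, y = rng.integers(0, 5, size=p), rng.integers(0, 5, size=p)
            A, B = concordance_matrix(x), concordance_matrix(y)
            got = ari_between_matrices(A, B)
            iu = np.triu_indices(p)
            a = np.rint(A[iu] * 100).astype(int)
            b = np.rint(B[iu] * 100).astype(int)
            assert got == pytest.approx(pair_counting_ari(a, b), abs=1e-12)
            if len(set(a)) > 1 or len(set(b)) > 1:
                assert got == pytest.approx(adjusted_rand_score(a, b), abs=1e-12)

    def test_invariant_to_scaling_divisor(self):
        rng = np.random.default_rng(1)
        x, y = rng.integers(0, 5, size=6), rng.integers(0, 5, size=6)
        scaled = ari_between_matrices(concordance_matrix(x), concordance_matrix(y))
        unscaled = ari_between_matrices(np.outer(x, x), np.outer(y, y))
        assert scaled == pytest.approx(unscaled, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            ari_between_matrices(np.zeros((2, 2)), np.zeros((3, 3)))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(st.integers(0, 16), min_size=3, max_size=25),
        st.data(),
    )
    def test_label_ari_matches_sklearn(self, a, data):
        b = data.draw(st.lists(st.integers(0, 16), min_size=len(a), max_size=len(a)))
        a, b = np.array(a), np.array(b)
        got = _ari_from_labels(a, b)
        if len(set(a)) == 1 and len(set(b)) == 1:
            assert got == 1.0
        else:
            assert got == pytest.approx(adjusted_rand_score(a, b), abs=1e-12)


class TestPatientSimilarity:
    def test_duplicated_rows_have_similarity_one(self):
        rng = np.random.default_rng(2)
        rows = rng.integers(0, 5, size=(3, 6))
        sev = pd.DataFrame(np.vstack([rows, rows[0]]), columns=[f"s{i}" for i in range(6)])
        S = patient_similarity(sev)
        assert S[0, 3] == pytest.approx(1.0)

    def test_three_patient_consistency(self):
        sev = pd.DataFrame(
            [[1, 2, 0], [2, 1, 0], [0, 0, 4]], columns=["a", "b", "c"]
        )
        S = patient_similarity(sev)
        for i in range(3):
            for j in range(3):
                expected = ari_between_matrices(
                    concordance_matrix(sev.iloc[i].to_numpy()),
                    concordance_matrix(sev.iloc[j].to_numpy()),
                )
                assert S[i, j] == pytest.approx(expected, abs=1e-12)

    def test_planted_subgroups_more_similar_within(self):
        cohort = generate_cohort(subgroup_cohort_spec(seed=3, n=90, p=12))
        S = patient_similarity(cohort.severity)
        g = cohort.true_subgroups.to_numpy()
        same = g[:, None] == g[None, :]
        off_diag = ~np.eye(len(g), dtype=bool)
        assert S[same & off_diag].mean() > S[~same].mean()


class TestDetectPatientSubgroups:
    def test_block_diagonal_similarity(self):
        S = np.zeros((6, 6))
        S[:3, :3] = 1.0
        S[3:, 3:] = 1.0
        assignment, consistency = detect_patient_subgroups(S, runs=11, seed=0)
        assert assignment.n_communities == 2
        assert np.all(consistency == 1.0)

    def test_negative_similarities_floored(self):
        S = np.full((4, 4), -0.5)
        S[:2, :2] = 1.0
        S[2:, 2:] = 1.0
        assignment, _ = detect_patient_subgroups(S, runs=2, seed=0)
        assert assignment.n_communities == 2

    def test_all_zero_similarity_rejected(self):
        with pytest.raises(ValueError, match="no structure"):
            detect_patient_subgroups(np.zeros((5, 5)), runs=1, seed=0)

    def test_recovers_planted_subgroups(self):
        cohort = generate_cohort(subgroup_cohort_spec(seed=4))
        S = patient_similarity(cohort.severity)
        assignment, _ = detect_patient_subgroups(S, runs=1, seed=0)
        labels = subgroup_labels_series(assignment, cohort.severity.index)
        assert adjusted_rand_score(cohort.true_subgroups, labels) >= 0.8

    def test_invariant_to_patient_reordering(self):
        cohort = generate_cohort(subgroup_cohort_spec(seed=5, n=90, p=12))
        S = patient_similarity(cohort.severity)
        a1, _ = detect_patient_subgroups(S, runs=1, seed=0)
        rng = np.random.default_rng(6)
        perm = rng.permutation(90)
        a2, _ = detect_patient_subgroups(S[np.ix_(perm, perm)], runs=1, seed=0)
        l1 = np.array([a1.labels[str(i)] for i in range(90)])
        l2 = np.array([a2.labels[str(k)] for k in np.argsort(perm)])
        assert adjusted_rand_score(l1, l2) == 1.0


class TestSubgroupProfiles:
    def test_single_subgroup_equals_column_means(self):
        rng = np.random.default_rng(7)
        sev = pd.DataFrame(rng.integers(0, 5, size=(20, 3)), columns=["a", "b", "c"])
        labels = pd.Series(1, index=sev.index)
        prof = subgroup_profiles(sev, labels)
        sub = prof[prof["subgroup"] == 1].set_index("symptom")
        np.testing.assert_allclose(sub["mean"], sev.mean(), atol=1e-12)

    def test_identical_rows_have_zero_ci_width(self):
        sev = pd.DataFrame([[2, 3, 1]] * 8, columns=["a", "b", "c"])
        labels = pd.Series(1, index=sev.index)
        prof = subgroup_profiles(sev, labels)
        assert ((prof["ci_high"] - prof["ci_low"]).abs() < 1e-12).all()

    def test_hand_computed_small_fixture(self):
        sev = pd.DataFrame(
            {"a": [0, 2, 4, 1, 1, 1], "b": [1, 1, 1, 3, 3, 3], "c": [0, 0, 0, 4, 4, 4]}
        )
        labels = pd.Series([1, 1, 1, 2, 2, 2], index=sev.index)
        prof = subgroup_profiles(sev, labels).set_index(["subgroup", "symptom"])
        assert prof.loc[(1, "a"), "mean"] == pytest.approx(2.0)
        sd = np.std([0, 2, 4], ddof=1)
        assert prof.loc[(1, "a"), "ci_high"] == pytest.approx(2.0 + 1.96 * sd / np.sqrt(3))
        assert prof.loc[(2, "c"), "ci_low"] == pytest.approx(4.0)

    def test_singleton_subgroup_ci_missing(self):
        sev = pd.DataFrame({"a": [0, 1, 2, 3], "b": [1, 1, 2, 2]})
        labels = pd.Series([1, 1, 1, 2], index=sev.index)
        prof = subgroup_profiles(sev, labels)
        single = prof[prof["subgroup"] == 2]
        assert single["ci_low"].isna().all()
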