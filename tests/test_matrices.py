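"""AHP core: validation, weights, lambda_max, RI/CR and option ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ahp_refine import (
    CR_THRESHOLD,
    ScoreMatrix,
    WeightVector,
    compute_weights,
    consistency,
    consistent_from_weights,
    lambda_max,
    random_index,
    rank_options,
    validate_matrix,
)
from ahp_refine.matrices import MatrixValidationError

from .conftest import random_reciprocal


class TestValidateMatrix:
    def test_accepts_client_matrix(self, c1_initial):
        assert c1_initial.n == 4
        assert c1_initial.labels == ("GC", "ND", "P", "C")
        assert c1_initial.entries[0, 3] == 9.0

    def test_strict_reciprocity(self):
        validate_matrix([[1, 2], [0.5, 1]])
        with pytest.raises(MatrixValidationError, match="reciprocity"):
            validate_matrix([[1, 2], [0.4, 1]])

    def test_repair_reciprocal_overwrites_lower_triangle(self):
        M = validate_matrix([[1, 2], [0.4, 1]], mode="repair_reciprocal")
        assert M.entries[1, 0] == 0.5

    @pytest.mark.parametrize(
        "raw,match",
        [
            ([[1, 2, 3], [0.5, 1, 2]], "square"),
            ([[1, -2], [-0.5, 1]], "positive"),
            ([[2, 2], [0.5, 1]], "diagonal"),
            ([[1]], "at least 2"),
        ],
    )
    def test_rejects_malformed_input(self, raw, match):
        with pytest.raises((MatrixValidationError, ValueError), match=match):
            validate_matrix(raw)

    def test_saaty_mode_rejects_off_scale_entry(self):
        validate_matrix([[1, 3], [1 / 3, 1]], mode="saaty")
        with pytest.raises(MatrixValidationError, match="Saaty"):
            validate_matrix([[1, 2.5], [1 / 2.5, 1]], mode="saaty")


class TestComputeWeights:
    def test_two_by_two(self):
        M = validate_matrix([[1, 3], [1 / 3, 1]])
        assert np.allclose(compute_weights(M).weights, [0.75, 0.25])

    def test_client1_initial_weights_match_hand_oracle(self, c1_initial):
        # independent oracle: plain-python column normalization + row average
        a = c1_initial.entries.tolist()
        n = 4
        colsums = [sum(a[i][j] for i in range(n)) for j in range(n)]
        oracle = [sum(a[i][j] / colsums[j] for j in range(n)) / n for i in range(n)]
        w = compute_weights(c1_initial, "column_norm").weights
        assert np.allclose(w, oracle, atol=1e-12)
        assert np.allclose(np.round(w, 3), [0.659, 0.190, 0.106, 0.045])

    @pytest.mark.parametrize("method", ["column_norm", "eigen"])
    def test_recovers_generating_weights_on_consistent_matrix(self, method):
        u = np.array([0.4, 0.3, 0.2, 0.1])
        M = consistent_from_weights(u)
        assert np.allclose(compute_weights(M, method).weights, u, atol=1e-9)

    def test_methods_agree_on_client_fixtures(self, all_client_matrices):
        # empirical bound: the largest component gap across the four client
        # matrices is 0.028 (client-2 initial, BPM component); the two
        # estimators agree exactly only on consistent matrices
        for M in all_client_matrices:
            w1 = compute_weights(M, "column_norm").weights
            w2 = compute_weights(M, "eigen").weights
            assert np.all(np.abs(w1 - w2) < 0.03)

    def test_weights_sum_to_one(self, all_client_matrices):
        for M in all_client_matrices:
            for method in ("column_norm", "eigen"):
                assert compute_weights(M, method).weights.sum() == pytest.approx(1.0)


class TestLambdaMax:
    def test_consistent_matrix_gives_n(self):
        M = consistent_from_weights([0.5, 0.25, 0.15, 0.1])
        assert lambda_max(M) == pytest.approx(4.0, abs=1e-9)
        assert lambda_max(M, method="power") == pytest.approx(4.0, abs=1e-9)

    def test_client2_refined_value(self, c2_refined):
        # frozen from an independent power-iteration oracle (sum-normalized)
        assert lambda_max(c2_refined) == pytest.approx(4.041, abs=5e-3)

    def test_order_two_always_consistent(self):
        M = validate_matrix([[1, 1], [1, 1]])
        assert lambda_max(M) == pytest.approx(2.0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(2, 7), st.integers(0, 10_000))
    def test_principal_eigenvalue_at_least_n(self, n, seed):
        M = random_reciprocal(n, np.random.default_rng(seed))
        assert lambda_max(M) >= n - 1e-9
        assert lambda_max(M, method="power") >= n - 1e-9


class TestRandomIndex:
    def test_tabulated_values(self):
        expected = {3: 0.58, 4: 0.9, 5: 1.12, 6: 1.24,
                    7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}
        for n, ri in expected.items():
            assert random_index(n) == ri

    def test_small_orders_are_consistent_by_definition(self):
        assert random_index(1) == 0.0
        assert random_index(2) == 0.0
        M = validate_matrix([[1, 5], [1 / 5, 1]])
        rep = consistency(M)
        assert rep.cr == 0.0 and rep.consistent

    def test_unsupported_order(self):
        with pytest.raises(ValueError, match="order 10"):
            random_index(11)


class TestConsistency:
    def test_client1_refined_cr(self, c1_refined):
        assert round(consistency(c1_refined).cr, 3) == 0.017

    def test_client2_refined_cr(self, c2_refined):
        assert round(consistency(c2_refined).cr, 3) == 0.015

    def test_consistent_matrix_has_zero_cr(self):
        M = consistent_from_weights([0.6, 0.25, 0.15])
        assert consistency(M).cr == pytest.approx(0.0, abs=1e-9)

    def test_ci_definition_holds(self, all_client_matrices):
        for M in all_client_matrices:
            rep = consistency(M)
            assert rep.ci == pytest.approx(
                (rep.lambda_max - rep.n) / (rep.n - 1), abs=1e-9
            )
            assert rep.cr == pytest.approx(rep.ci / rep.ri, abs=1e-9)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(3, 6), st.integers(0, 10_000), st.integers(0, 1000))
    def test_cr_invariant_under_relabeling(self, n, seed, perm_seed):
        M = random_reciprocal(n, np.random.default_rng(seed))
        perm = list(np.random.default_rng(perm_seed).permutation(n))
        rep, rep_p = consistency(M), consistency(M.permuted(perm))
        assert rep_p.lambda_max == pytest.approx(rep.lambda_max, abs=1e-9)
        assert rep_p.cr == pytest.approx(rep.cr, abs=1e-9)


class TestRankOptions:
    def test_direct_product(self):
        P = ScoreMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]), ("a", "b"), ("x", "y"))
        w = WeightVector(np.array([0.8, 0.2]))
        ranked = rank_options(P, w)
        assert np.allclose(ranked.values, [0.8, 0.2])
        assert ranked.winner == 0

    def test_tie_broken_by_lowest_index(self):
        P = ScoreMatrix(np.full((2, 2), 0.5), ("a", "b"), ("x", "y"))
        w = WeightVector(np.array([0.5, 0.5]))
        assert rank_options(P, w).order == (0, 1)

    def test_values_sum_to_one_for_normalized_inputs(self):
        rng = np.random.default_rng(7)
        raw = rng.random((3, 4))
        P = ScoreMatrix(
            raw / raw.sum(0), ("a", "b", "c"), ("w", "x", "y", "z")
        )
        w = WeightVector(rng.dirichlet(np.ones(4)))
        assert rank_options(P, w).values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_dimension_mismatch(self):
        P = ScoreMatrix(np.array([[1.0], [0.0]]), ("a", "b"), ("x",))
        with pytest.raises(ValueError, match="criteria"):
            rank_options(P, WeightVector(np.array([0.5, 0.5])))


def test_verdicts_agree_between_lambda_methods(all_client_matrices):
    for M in all_client_matrices:
        assert (
            (consistency(M, "mean_ratio").cr <= CR_THRESHOLD)
            == (consistency(M, "power").cr <= CR_THRESHOLD)
        )
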