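"""Exhaustive subset-search estimator: losses, argmin, recovery guarantees."""

import itertools
from functools import reduce

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anchorq.estimator import (
    combine_anchor_columns,
    estimate_qmatrix,
    estimate_qvector,
    nonempty_subsets,
    subset_loss,
)
from anchorq.models import design_support, simulate_responses
from anchorq.structures import ideal_responses, reduced_qmatrix, student_matrix


def brute_force_min_loss(X, y, model):
    """Independent oracle: enumerate subsets with python sets and reduce()."""
    K = X.shape[1]
    op = np.minimum if model == "dina" else np.maximum
    best = None
    for size in range(1, K + 1):
        for S in itertools.combinations(range(K), size):
            pred = reduce(op, [X[:, k] for k in S])
            loss = int(np.sum(np.abs(pred - y)))
            if best is None or loss < best:
                best = loss
    return best


class TestSubsetLoss:
    def test_identical_column_has_zero_loss(self, rng):
        X = rng.integers(0, 2, size=(20, 3))
        assert subset_loss(X, X[:, 1], [1], "dina") == 0

    def test_worked_example_losses(self, example1):
        # noiseless anchor responses of all four profiles, K = 2
        profiles = example1["Q_s"].T
        X = ideal_responses(example1["R"], profiles, "conjunctive")
        y = np.array([0, 0, 0, 1])  # item requiring both attributes
        assert subset_loss(X, y, [0, 1], "dina") == 0
        assert subset_loss(X, y, [0], "dina") == 1
        assert subset_loss(X, y, [1], "dina") == 1

    def test_complement_gives_maximal_loss(self, rng):
        X = rng.integers(0, 2, size=(30, 3))
        pred = combine_anchor_columns(X, [0, 2], "dino")
        assert subset_loss(X, 1 - pred, [0, 2], "dino") == 30

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            subset_loss(np.eye(2, dtype=int), np.array([0, 1]), [], "dina")


class TestEnumeration:
    def test_order_is_cardinality_then_lexicographic(self):
        assert nonempty_subsets(3) == [
            (0,), (1,), (2,), (0, 1), (0, 2), (1, 2), (0, 1, 2),
        ]

    def test_cap_guards_exponential_blowup(self):
        with pytest.raises(ValueError, match="cap"):
            nonempty_subsets(25)
        assert len(nonempty_subsets(21, cap=21)) == 2**21 - 1


class TestEstimateQvector:
    @pytest.mark.parametrize("model", ["dina", "dino"])
    def test_noiseless_full_profiles_recover_exactly(self, model):
        # executable content of the identifiability theory (K = 2 case)
        K = 2
        R = np.eye(K, dtype=int)
        profiles = student_matrix(K).T
        gate = "conjunctive" if model == "dina" else "disjunctive"
        X = ideal_responses(R, profiles, gate)
        y = ideal_responses(np.array([[1], [1]]), profiles, gate)[:, 0]
        sol = estimate_qvector(X, y, R, model)
        assert sol.subset == (0, 1)
        assert sol.loss == 0
        assert np.array_equal(sol.q_hat, [1, 1])

    @pytest.mark.parametrize("model", ["dina", "dino"])
    def test_optimal_design_profiles_suffice(self, model):
        # only the K discriminating profiles, no noise: unique zero-loss minimizer
        K = 5
        R = np.eye(K, dtype=int)
        profiles = design_support("optimal", model, K)
        gate = "conjunctive" if model == "dina" else "disjunctive"
        Q_t = np.concatenate([R, reduced_qmatrix(K)], axis=1)
        L = ideal_responses(Q_t, profiles, gate)
        X, Y = L[:, :K], L[:, K:]
        # all 31 subset predictions are distinct over these profiles
        preds = [tuple(combine_anchor_columns(X, S, model)) for S in nonempty_subsets(K)]
        assert len(set(preds)) == len(preds)
        Q_hat, sols = estimate_qmatrix(L, R, model)
        assert np.array_equal(Q_hat, reduced_qmatrix(K))
        assert all(s.loss == 0 for s in sols)

    def test_ties_resolve_to_smallest_earliest_subset(self):
        # two identical anchor columns: subsets {0}, {1}, {0,1} tie at loss 0
        X = np.array([[0, 0], [1, 1], [1, 1], [0, 0]])
        y = X[:, 0]
        sol = estimate_qvector(X, y, np.eye(2, dtype=int), "dina")
        assert sol.subset == (0,)
        assert sol.loss == 0
        assert sol.loss_gap == 0  # runner-up also achieves the minimum

    def test_loss_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(200):
            K = int(rng.integers(2, 5))
            n = int(rng.integers(5, 25))
            X = rng.integers(0, 2, size=(n, K))
            y = rng.integers(0, 2, size=n)
            model = ("dina", "dino")[int(rng.integers(2))]
            sol = estimate_qvector(X, y, np.eye(K, dtype=int), model)
            assert sol.loss == brute_force_min_loss(X, y, model)
            assert sol.loss == subset_loss(X, y, sol.subset, model)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.sampled_from(["dina", "dino"]))
    def test_permutation_equivariance(self, seed, model):
        rng = np.random.default_rng(seed)
        K, n = 4, 40
        R = np.eye(K, dtype=int)
        X = rng.integers(0, 2, size=(n, K))
        y = rng.integers(0, 2, size=n)
        perm = rng.permutation(K)
        sol = estimate_qvector(X, y, R, model)
        sol_p = estimate_qvector(X[:, perm], y, R[np.ix_(perm, perm)], model)
        assert np.array_equal(sol_p.q_hat, sol.q_hat[perm])
        assert sol_p.loss == sol.loss


class TestEstimateQmatrix:
    @pytest.mark.parametrize("model", ["dina", "dino"])
    def test_noiseless_reduced_matrix_recovery(self, model):
        # all 2^K profiles, no noise: the whole 2^K - 1 column block is exact
        K = 4
        R = np.eye(K, dtype=int)
        Q_r = reduced_qmatrix(K)
        Q_t = np.concatenate([R, Q_r], axis=1)
        profiles = student_matrix(K).T
        U = simulate_responses(Q_t, profiles, 0.0, 0.0, model, rng=0)
        Q_hat, sols = estimate_qmatrix(U, R, model)
        assert np.array_equal(Q_hat, Q_r)
        assert all(s.loss == 0 for s in sols)

    def test_duplicated_anchor_column_recovers_anchor_qvector(self, rng):
        K = 3
        R = np.eye(K, dtype=int)
        X = rng.integers(0, 2, size=(30, K))
        U = np.concatenate([X, X[:, [1]]], axis=1)
        Q_hat, sols = estimate_qmatrix(U, R, "dina")
        assert np.array_equal(Q_hat[:, 0], R[:, 1])
        assert sols[0].loss == 0

    def test_anchor_block_placement_is_respected(self, rng):
        # anchor columns need not be the leading block
        K = 3
        R = np.eye(K, dtype=int)
        X = rng.integers(0, 2, size=(25, K))
        y = X[:, 2]
        U = np.column_stack([y, X])
        Q_hat, _ = estimate_qmatrix(U, R, "dina", anchor_cols=[1, 2, 3])
        assert np.array_equal(Q_hat[:, 0], R[:, 2])

    def test_wrong_anchor_width_rejected(self, rng):
        U = rng.integers(0, 2, size=(10, 4))
        with pytest.raises(ValueError):
            estimate_qmatrix(U, np.eye(3, dtype=int), "dina", anchor_cols=[0, 1])

    def test_all_anchor_no_unknown_rejected(self, rng):
        U = rng.integers(0, 2, size=(10, 3))
        with pytest.raises(ValueError):
            estimate_qmatrix(U, np.eye(3, dtype=int), "dina")

    def test_snapshot_of_seeded_noisy_bundle(self, toy_noisy):
        # frozen output of an independent brute-force run on this bundle
        Q_hat, sols = estimate_qmatrix(toy_noisy["U"], toy_noisy["R"], toy_noisy["model"])
        assert np.array_equal(Q_hat, toy_noisy["Q_r"])
        assert [(s.subset, s.loss) for s in sols] == [((0,), 11), ((1,), 4), ((0, 1), 8)]
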