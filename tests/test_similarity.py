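"""Matching, the similarity index, and the shuffled-weight permutation null."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as stn
from scipy.optimize import linear_sum_assignment

from synergylab.similarity import (SimilarityError, direction_similarity_profiles,
                                   is_similar, match_synergies, shuffle_null,
                                   shuffle_space_size, similarity_index,
                                   SimilarityResult)


def _random_W(rng, R=4, n=8, alpha=0.5):
    return rng.dirichlet(np.ones(n) * alpha, size=R).T


def _one_hot(indices, n=8):
    W = np.zeros((n, len(indices)))
    for col, idx in enumerate(indices):
        W[idx, col] = 1.0
    return W


class TestMatching:
    def test_identity(self, rng):
        W = _random_W(rng)
        assert match_synergies(W, W) == (0, 1, 2, 3)

    def test_cyclic_shift_recovered(self, rng):
        W = _random_W(rng)
        shifted = np.roll(W, 1, axis=1)        # col j of shifted = col j-1 of W
        perm = match_synergies(W, shifted)
        np.testing.assert_allclose(shifted[:, perm], W, atol=1e-12)

    def test_equals_assignment_oracle(self, rng):
        """Exhaustive search agrees with the Hungarian algorithm's optimum."""
        for _ in range(20):
            Wa, Wb = _random_W(rng), _random_W(rng)
            perm = match_synergies(Wa, Wb)
            cost = 0.5 * np.array([[np.sum((Wa[:, i] - Wb[:, j]) ** 2)
                                    for j in range(4)] for i in range(4)])
            rows, cols = linear_sum_assignment(cost)
            ours = cost[np.arange(4), perm].sum()
            assert ours == pytest.approx(cost[rows, cols].sum(), abs=1e-12)

    def test_unequal_r_rejected(self, rng):
        with pytest.raises(SimilarityError, match="shape"):
            match_synergies(_random_W(rng, R=4), _random_W(rng, R=3))


class TestSimilarityIndex:
    def test_identical_sets_score_zero(self, rng):
        W = _random_W(rng)
        mean, per = similarity_index(W, W)
        assert mean == 0.0 and (per == 0).all()

    def test_disjoint_one_hot_scores_documented_maximum(self):
        mean, _ = similarity_index(_one_hot([0]), _one_hot([1]))
        assert mean == pytest.approx(1.0)

    def test_hand_example(self):
        Wa = np.array([[0.5, 0.5, 0, 0, 0, 0, 0, 0]]).T
        Wb = np.array([[0.25, 0.75, 0, 0, 0, 0, 0, 0]]).T
        mean, _ = similarity_index(Wa, Wb)
        assert mean == pytest.approx(0.0625)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(SimilarityError, match="sum to 1"):
            similarity_index(np.ones((8, 2)), np.ones((8, 2)))

    def test_symmetry_and_order_invariance(self, rng):
        Wa, Wb = _random_W(rng), _random_W(rng)
        ab, _ = similarity_index(Wa, Wb, matched=False)
        ba, _ = similarity_index(Wb, Wa, matched=False)
        assert ab == pytest.approx(ba, abs=1e-12)
        perm = rng.permutation(4)
        scrambled, _ = similarity_index(Wa, Wb[:, perm], matched=False)
        assert scrambled == pytest.approx(ab, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=stn.integers(min_value=0, max_value=10_000))
    def test_bounded_on_column_stochastic_sets(self, seed):
        rng = np.random.default_rng(seed)
        mean, per = similarity_index(_random_W(rng), _random_W(rng), matched=False)
        assert 0.0 <= per.min() and per.max() <= 1.0 and 0.0 <= mean <= 1.0

    def test_euclidean_variant_caps_below_one(self):
        mean, _ = similarity_index(_one_hot([0]), _one_hot([1]),
                                   metric="euclidean_over_2")
        assert mean == pytest.approx(np.sqrt(2) / 2)


class TestShuffleNull:
    def test_default_null_pair_count_is_1e6(self, rng):
        res = shuffle_null(_random_W(rng), _random_W(rng), n_shuffles=1000, seed=0)
        assert res.n_null_pairs == 1_000_000

    def test_identical_non_uniform_sets_beat_the_null(self, rng):
        W = _random_W(rng, alpha=0.3)
        res = shuffle_null(W, W.copy(), n_shuffles=200, seed=0)
        assert res.mean == 0.0
        assert res.percentile >= 90.0

    def test_uniform_weights_are_degenerate(self):
        W = np.full((8, 2), 1 / 8)
        res = shuffle_null(W, W.copy(), n_shuffles=50, seed=0)
        assert res.degenerate
        assert res.percentile == 0.0       # strict-greater counting over all ties

    def test_deterministic_given_seed(self, rng):
        Wa, Wb = _random_W(rng), _random_W(rng)
        a = shuffle_null(Wa, Wb, n_shuffles=100, seed=3)
        b = shuffle_null(Wa, Wb, n_shuffles=100, seed=3)
        assert a.percentile == b.percentile

    def test_corruption_lowers_percentile(self, rng):
        """A set scores at least as high against itself as against noisy copies."""
        diffs = []
        for seed in range(8):
            local = np.random.default_rng(seed)
            W = _random_W(local, alpha=0.3)
            noisy = W + local.uniform(0, 0.3, size=W.shape)
            noisy /= noisy.sum(axis=0)
            clean = shuffle_null(W, W.copy(), n_shuffles=100, seed=seed)
            corrupt = shuffle_null(W, noisy, n_shuffles=100, seed=seed)
            diffs.append(clean.percentile - corrupt.percentile)
        assert np.mean(diffs) >= 0.0

    def test_shuffle_space_is_8_factorial(self):
        assert shuffle_space_size(8) == 40320


class TestIsSimilar:
    @pytest.mark.parametrize("pct, expected", [(99.9, True), (89.999, False), (90.0, True)])
    def test_percentile_rule_boundary(self, pct, expected):
        res = SimilarityResult(permutation=(0,), per_synergy=np.zeros(1),
                               mean=0.0, percentile=pct)
        assert is_similar(res, rule=90) is expected

    def test_identical_sets_declared_similar(self, rng):
        W = _random_W(rng, alpha=0.3)
        assert is_similar(shuffle_null(W, W.copy(), n_shuffles=200, seed=0))


class TestDirectionProfiles:
    def test_exact_match_gives_zero_vector(self, rng):
        W = _random_W(rng)
        profiles = direction_similarity_profiles(
            {"s1": {t: W.copy() for t in range(1, 10)}}, W)
        np.testing.assert_allclose(profiles.loc["s1"].to_numpy(), 0.0, atol=1e-12)

    def test_identical_subjects_have_zero_sd(self, rng):
        W_rep = _random_W(rng)
        by_target = {t: _random_W(rng) for t in range(1, 10)}
        profiles = direction_similarity_profiles(
            {"a": by_target, "b": {t: w.copy() for t, w in by_target.items()}}, W_rep)
        np.testing.assert_allclose(profiles.std(axis=0).to_numpy(), 0.0, atol=1e-12)

    def test_missing_direction_left_nan(self, rng):
        W = _random_W(rng)
        profiles = direction_similarity_profiles({"s1": {1: W.copy()}}, W)
        assert profiles.loc["s1"].isna().sum() == 8
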