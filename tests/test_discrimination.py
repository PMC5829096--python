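"""Activation features, K-means direction discrimination, purity, correlations."""

import numpy as np
import pytest

from synergylab.discrimination import (DiscriminationError,
                                       direction_correlation_matrix,
                                       extract_features, kmeans_directions,
                                       purity)


def _burst_trace(peak_frac, m=2000, width_frac=0.08, amp=1.0):
    frac = np.arange(m) / m
    return amp * np.exp(-0.5 * ((frac - peak_frac) / width_frac) ** 2)


class TestExtractFeatures:
    def test_zero_trace_uses_substitution_rule(self):
        feats = extract_features(np.zeros((1, 2000)), min_peak_width=500)
        np.testing.assert_allclose(feats[:6], 0.0)       # samples
        assert feats[6] == 0.5 and feats[7] == 0.0       # first peak: mid-time, mean amp
        assert feats[8] == 0.5 and feats[9] == 0.0       # second peak substituted
        assert feats[10] == 0.0                          # area

    def test_single_burst_peak_time_and_substituted_second(self):
        H = _burst_trace(0.3)[None, :]
        feats = extract_features(H, min_peak_width=100)
        assert 0.29 <= feats[6] <= 0.31
        assert feats[7] == pytest.approx(1.0, abs=1e-6)
        assert feats[8] == 0.5                           # no second wide peak
        assert feats[9] == pytest.approx(H.mean(), rel=1e-9)

    def test_two_bursts_ordered_by_time(self):
        H = (_burst_trace(0.25) + 0.7 * _burst_trace(0.7))[None, :]
        feats = extract_features(H, min_peak_width=100)
        assert feats[6] < feats[8]
        assert feats[7] > feats[9]

    def test_four_synergies_give_44_features(self, rng):
        H = rng.gamma(1.0, 1.0, size=(4, 600))
        assert extract_features(H, min_peak_width=100).size == 44

    def test_narrow_peaks_ignored(self):
        trace = np.zeros(2000)
        trace[1000] = 5.0                                # 1-sample spike
        feats = extract_features(trace[None, :], min_peak_width=500)
        assert feats[6] == 0.5                           # spike too narrow to count

    def test_short_trace_rejected(self):
        with pytest.raises(DiscriminationError, match="min_peak_width"):
            extract_features(np.ones((2, 100)), min_peak_width=500)

    def test_time_rescaling_invariance(self):
        """Doubling the sampling of the same burst leaves features unchanged
        (times are duration fractions, area is duration-normalized)."""
        lo = extract_features(_burst_trace(0.4, m=1000)[None, :], min_peak_width=50)
        hi = extract_features(_burst_trace(0.4, m=2000)[None, :], min_peak_width=100)
        np.testing.assert_allclose(lo, hi, atol=0.01)


class TestPurity:
    def test_worked_example(self):
        """Per-row modal counts 8,9,9,9,6,8,9,7,9 on the 9x9 grid give 91.358 %."""
        counts = [8, 9, 9, 9, 6, 8, 9, 7, 9]
        grid = np.empty((9, 9), dtype=int)
        for r, c in enumerate(counts):
            grid[r, :c] = r + 1
            grid[r, c:] = (r + 1) % 9 + 1
        assert purity(grid) == pytest.approx(100 * 74 / 81)
        assert f"{purity(grid):.3f}" == "91.358"

    def test_uniform_rows_score_100(self):
        grid = np.tile(np.arange(1, 10)[:, None], (1, 9))
        assert purity(grid) == 100.0

    def test_single_label_pathology_scores_100(self):
        grid = np.ones((9, 9), dtype=int)
        assert purity(grid) == 100.0
        assert len(np.unique(grid)) == 1    # degeneracy detectable by label count

    def test_matches_brute_force_recount(self, rng):
        """Oracle equivalence on random label grids."""
        from collections import Counter
        for _ in range(25):
            grid = rng.integers(1, 7, size=(9, 9))
            expected = 0
            for row in grid:
                counter = Counter(row.tolist())
                top = max(counter.values())
                modal = min(l for l, c in counter.items() if c == top)
                expected += sum(1 for v in row if v == modal)
            assert purity(grid) == pytest.approx(100 * expected / 81)


class TestKmeans:
    def _archetype_features(self, rng, noise=0.01):
        archetypes = rng.uniform(0, 1, size=(9, 44)) * 10
        X = np.vstack([archetypes[i] + rng.normal(0, noise, 44)
                       for i in range(9) for _ in range(9)])
        return X

    def test_deterministic_given_seed(self, rng):
        X = self._archetype_features(rng, noise=1.0)
        a = kmeans_directions(X, K=5, n_runs=3, seed=9)
        b = kmeans_directions(X, K=5, n_runs=3, seed=9)
        for ga, gb in zip(a.label_grids, b.label_grids):
            np.testing.assert_array_equal(ga, gb)

    def test_separable_archetypes_near_perfect_purity(self, rng):
        X = self._archetype_features(rng, noise=0.01)
        res = kmeans_directions(X, K=9, n_runs=10, seed=0)
        assert res.mean_purity >= 95.0

    def test_structure_destruction_lowers_purity(self, rng):
        """Row-shuffling the features removes direction structure and drops
        purity relative to intact features (averaged over seeds)."""
        diffs = []
        for seed in range(10):
            local = np.random.default_rng(seed)
            X = self._archetype_features(local, noise=0.3)
            intact = kmeans_directions(X, K=6, n_runs=3, seed=seed).mean_purity
            destroyed = kmeans_directions(X[local.permutation(81)], K=6,
                                          n_runs=3, seed=seed).mean_purity
            diffs.append(intact - destroyed)
        assert np.mean(diffs) > 0

    def test_k_above_n_rejected(self, rng):
        with pytest.raises(DiscriminationError, match="exceeds"):
            kmeans_directions(rng.uniform(size=(81, 10)), K=82)

    def test_purity_trend_on_pipeline_features(self, crossval_result, fast_config):
        """On cross-validation activations, purity does not rise from K=4 to
        K=9 beyond noise."""
        from synergylab.discrimination import extract_features as ef
        cv, _ = crossval_result
        width = fast_config.effective_peak_width()
        feats = {k: ef(H, min_peak_width=width) for k, H in cv.activations.items()}
        p4 = kmeans_directions(feats, K=4, n_runs=5, seed=1).mean_purity
        p9 = kmeans_directions(feats, K=9, n_runs=5, seed=1).mean_purity
        assert p9 <= p4 + 10.0


class TestDirectionCorrelations:
    def test_identical_features_all_ones(self, rng):
        f = rng.uniform(size=20)
        corr = direction_correlation_matrix([f.copy() for _ in range(9)])
        np.testing.assert_allclose(corr, 1.0)

    def test_symmetric_unit_diagonal(self, rng):
        corr = direction_correlation_matrix([rng.uniform(size=15) for _ in range(9)])
        np.testing.assert_allclose(corr, corr.T)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_zero_variance_direction_recorded_missing(self, rng):
        feats = [rng.uniform(size=10) for _ in range(8)] + [np.ones(10)]
        corr = direction_correlation_matrix(feats)
        assert np.isnan(corr[8, :8]).all()
        assert corr[8, 8] == 1.0

    def test_height_structured_gains_yield_block_correlations(self):
        """When activation amplitude varies only with target height, same-row
        targets correlate more strongly than different-row targets."""
        m = 1200
        frac = np.arange(m) / m
        bumps = [np.exp(-0.5 * ((frac - p) / 0.06) ** 2) for p in (0.25, 0.5, 0.75)]
        feats = []
        for t in range(1, 10):
            height = (t - 1) // 3            # 0, 1, 2
            gains = np.roll([2.0, 1.0, 0.3], height)
            H = np.vstack([g * b for g, b in zip(gains, bumps)])
            feats.append(extract_features(H, min_peak_width=60))
        corr = direction_correlation_matrix(feats)
        same, cross = [], []
        for a in range(9):
            for b in range(a + 1, 9):
                (same if (a // 3) == (b // 3) else cross).append(corr[a, b])
        assert min(same) > max(cross)
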