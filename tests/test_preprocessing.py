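"""Filtering, RMS envelopes, baseline/MVC normalization, direction pooling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as stn

from synergylab.preprocessing import (MvcReference, PreprocessingError,
                                      bandpass, compute_mvc_reference,
                                      normalize_mvc, pool_by_direction,
                                      preprocess_dataset, rms_envelope,
                                      subtract_baseline)

FS = 2000.0


def _sine(freq, n=4000, fs=FS):
    t = np.arange(n) / fs
    return np.sin(2 * np.pi * freq * t)[:, None]


class TestBandpass:
    def test_dc_removed(self):
        y = bandpass(np.full((4000, 1), 3.0), 20, 450, FS)
        assert np.abs(y[500:-500]).max() < 1e-6 * 3.0

    def test_passband_tone_preserved(self):
        y = bandpass(_sine(100), 20, 450, FS)
        amp = np.abs(y[1000:-1000]).max()
        assert 0.95 <= amp <= 1.05

    def test_stopband_tone_attenuated(self):
        y = bandpass(_sine(600), 20, 450, FS)
        assert np.abs(y[1000:-1000]).max() < 0.5

    def test_short_signal_rejected(self):
        with pytest.raises(PreprocessingError, match="warm-up"):
            bandpass(np.zeros((10, 1)), 20, 450, FS)

    def test_invalid_band_rejected(self):
        with pytest.raises(PreprocessingError):
            bandpass(np.zeros((100, 1)), 450, 20, FS)


class TestRmsEnvelope:
    def test_alternating_signal_gives_unit_envelope(self):
        x = np.tile([1.0, -1.0], 500)[:, None]
        env = rms_envelope(x, 50)
        np.testing.assert_allclose(env[100:-100], 1.0, atol=1e-12)

    def test_zero_signal_gives_zero_envelope(self):
        assert not rms_envelope(np.zeros((200, 3)), 50).any()

    def test_sine_envelope_is_inv_sqrt2(self):
        env = rms_envelope(_sine(100, n=4000), 1000)  # window >> period
        np.testing.assert_allclose(env[1500:-1500], 1 / np.sqrt(2), atol=0.02)

    def test_output_length_matches_input(self):
        assert rms_envelope(np.ones((123, 2)) * 0.5, 50).shape == (123, 2)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=stn.floats(min_value=1e-3, max_value=1e3),
           seed=stn.integers(min_value=0, max_value=100))
    def test_amplitude_equivariance(self, scale, seed):
        x = np.random.default_rng(seed).standard_normal((300, 2))
        np.testing.assert_allclose(rms_envelope(scale * x, 50),
                                   scale * rms_envelope(x, 50), rtol=1e-9)


class TestBaselineAndMvc:
    def test_baseline_identical_gives_zeros(self, rng):
        base = rng.uniform(0.1, 0.2, size=(8, 100))
        env = np.tile(base.mean(axis=1, keepdims=True), (1, 50))
        assert not subtract_baseline(env, base).any()

    def test_constant_offset_preserved(self, rng):
        base = rng.uniform(0.1, 0.2, size=(8, 100))
        env = base.mean(axis=1, keepdims=True) + 0.3 * np.ones((8, 50))
        np.testing.assert_allclose(subtract_baseline(env, base), 0.3)

    def test_below_baseline_clipped_to_zero(self):
        base = np.ones((8, 10))
        env = np.full((8, 5), 0.5)
        corrected = subtract_baseline(env, base)
        assert (corrected == 0).all()

    def test_normalize_identity_and_scaling(self):
        names = [f"m{i}" for i in range(8)]
        ref = MvcReference(values=np.full(8, 2.0), muscle_names=names)
        env = np.full((8, 10), 2.0)
        np.testing.assert_allclose(normalize_mvc(env, ref), 1.0)
        ref2 = MvcReference(values=np.full(8, 4.0), muscle_names=names)
        np.testing.assert_allclose(normalize_mvc(env, ref2), 0.5)

    def test_zero_reference_names_muscle(self):
        names = [f"m{i}" for i in range(8)]
        values = np.ones(8)
        values[3] = 0.0
        with pytest.raises(PreprocessingError, match="m3"):
            MvcReference(values=values, muscle_names=names)

    def test_mvc_self_normalization_and_plateau_bound(self, small_dataset,
                                                      fast_config, ground_truth):
        """Normalizing a muscle's own MVC trial by the reference peaks at 1,
        and the reference overshoots the true plateau only boundedly (it is
        the max of a short-window RMS estimate, never an undershoot)."""
        from synergylab.preprocessing import _trial_envelope

        ref = compute_mvc_reference(small_dataset, fast_config, subject="s01")
        muscle = small_dataset.muscle_names[0]
        env = _trial_envelope(small_dataset, f"s01_mvc_{muscle}", fast_config)
        normalized = normalize_mvc(env, ref)
        assert normalized[0].max() == pytest.approx(1.0, abs=1e-9)
        ratio = ref.values / ground_truth.mvc_amplitudes["s01"]
        assert (ratio >= 1.0).all() and (ratio < 2.0).all()


class TestPooling:
    def test_column_count_is_sum_of_trial_lengths(self, preprocessed, small_dataset,
                                                  fast_config):
        direction_V = preprocessed["direction_V"]
        env = preprocessed["envelopes"]
        md = small_dataset.trials_of_type("reach")
        for target, V in enumerate(direction_V, start=1):
            ids = md.index[md["target"] == target]
            assert V.values.shape[1] == sum(env[t].shape[1] for t in ids)

    def test_provenance_recovers_each_trial(self, preprocessed):
        V = preprocessed["direction_V"][4]
        env = preprocessed["envelopes"]
        for trial_id, start, stop in V.provenance:
            np.testing.assert_array_equal(V.values[:, start:stop], env[trial_id])

    def test_pipeline_output_non_negative(self, preprocessed):
        for V in preprocessed["direction_V"]:
            assert (V.values >= 0).all()

    def test_missing_direction_errors(self, small_dataset, fast_config):
        trimmed = small_dataset.metadata[
            ~((small_dataset.metadata["trial_type"] == "reach")
              & (small_dataset.metadata["target"] == 9))]
        signals = {t: small_dataset.signals[t] for t in trimmed.index}
        from synergylab.io import EmgDataset
        ds = EmgDataset(signals=signals, metadata=trimmed,
                        sampling_rate=small_dataset.sampling_rate,
                        muscle_names=small_dataset.muscle_names)
        env = preprocess_dataset(ds, fast_config)
        with pytest.raises(PreprocessingError, match="target 9"):
            pool_by_direction(env, ds, fast_config)

    def test_missing_baseline_names_subject(self, small_dataset, fast_config):
        keep = ~((small_dataset.metadata["subject"] == "s02")
                 & (small_dataset.metadata["trial_type"] == "baseline"))
        md = small_dataset.metadata[keep]
        signals = {t: small_dataset.signals[t] for t in md.index}
        from synergylab.io import EmgDataset
        ds = EmgDataset(signals=signals, metadata=md,
                        sampling_rate=small_dataset.sampling_rate,
                        muscle_names=small_dataset.muscle_names)
        with pytest.raises(PreprocessingError, match="s02"):
            preprocess_dataset(ds, fast_config)
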