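"""Raw EMG to MVC-normalized envelope matrices.

The chain per trial: zero-phase band-pass (20-450 Hz Butterworth), per-channel
demeaning plus a centred sliding-window RMS (50 samples = 25 ms around each
time point at 2 kHz, truncated symmetrically at the edges), subtraction of the
subject's mean resting envelope with clipping at zero, and division by each
muscle's MVC reference. The result is the non-negative matrix V (8 x M,
fraction-of-MVC units) that the factorization consumes, pooled per movement
direction across subjects and repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import signal as sps

from .config import RunConfig
from .io import EmgDataset, N_MUSCLES


class PreprocessingError(ValueError):
    pass


@dataclass
class EnvelopeMatrix:
    """8 x M non-negative envelope in fraction-of-MVC units.

    ``provenance`` lists (trial_id, start, stop) column spans so each
    contributing trial can be recovered by slicing.
    """

    values: np.ndarray
    muscle_names: List[str]
    sample_rate: float
    provenance: List[Tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.muscle_names):
            raise PreprocessingError(
                f"envelope must be muscles x samples with {len(self.muscle_names)} rows, "
                f"got {self.values.shape}"
            )
        if (self.values < 0).any():
            raise PreprocessingError("envelope must be non-negative")
        if self.provenance:
            total = sum(stop - start for _, start, stop in self.provenance)
            if total != self.values.shape[1]:
                raise PreprocessingError("provenance spans do not cover the column count")

    def trial_slice(self, trial_id: str) -> np.ndarray:
        for tid, start, stop in self.provenance:
            if tid == trial_id:
                return self.values[:, start:stop]
        raise KeyError(trial_id)


@dataclass
class MvcReference:
    """Per-muscle maximum envelope attained during that muscle's MVC trials."""

    values: np.ndarray  # shape (8,), volts
    muscle_names: List[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        for name, v in zip(self.muscle_names, self.values):
            if not v > 0:
                raise PreprocessingError(f"MVC reference for muscle {name!r} must be positive, got {v}")


def bandpass(raw: np.ndarray, low: float, high: float, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass applied per channel (columns)."""
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if not 0 < low < high < fs / 2:
        raise PreprocessingError(f"need 0 < low < high < fs/2, got ({low}, {high}) at fs={fs}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    # sosfiltfilt needs padlen < n; require a margin of 3x the filter order.
    min_len = 3 * (2 * order + 1)
    if raw.shape[0] <= min_len:
        raise PreprocessingError(
            f"signal of {raw.shape[0]} samples shorter than filter warm-up ({min_len})"
        )
    return sps.sosfiltfilt(sos, raw, axis=0)


def rms_envelope(signal: np.ndarray, window: int) -> np.ndarray:
    """Centred sliding-window RMS after per-channel demeaning.

    One output sample per input sample; at the edges the window is truncated
    symmetrically to the available samples.
    """
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    if window < 2:
        raise PreprocessingError("window must be >= 2 samples")
    x = x - x.mean(axis=0, keepdims=True)
    sq = x * x
    n = x.shape[0]
    csum = np.vstack([np.zeros((1, x.shape[1])), np.cumsum(sq, axis=0)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - window // 2)
    hi = np.minimum(n, idx + (window - window // 2))
    counts = (hi - lo).astype(float)[:, None]
    return np.sqrt((csum[hi] - csum[lo]) / counts)


def subtract_baseline(envelope: np.ndarray, baseline_envelope: np.ndarray) -> np.ndarray:
    """Subtract each muscle's mean resting envelope; clip negatives to zero.

    Both arrays are muscles x samples. Values below baseline are meaningless
    for the non-negative synergy model and are clipped at exactly zero.
    """
    envelope = np.asarray(envelope, dtype=float)
    baseline_mean = np.asarray(baseline_envelope, dtype=float).mean(axis=1, keepdims=True)
    return np.clip(envelope - baseline_mean, 0.0, None)


def normalize_mvc(envelope: np.ndarray, ref: MvcReference) -> np.ndarray:
    """Divide each muscle row by its MVC reference (units: fraction of MVC)."""
    envelope = np.asarray(envelope, dtype=float)
    return envelope / ref.values[:, None]


def _trial_envelope(dataset: EmgDataset, trial_id: str, config: RunConfig) -> np.ndarray:
    """Band-pass + RMS for one trial, returned muscles x samples (volts)."""
    raw = dataset.signals[trial_id]
    low, high = config.bandpass_hz
    filtered = bandpass(raw, low, high, dataset.sampling_rate)
    env = rms_envelope(filtered, config.rms_window_samples)
    return env.T  # muscles x samples


def compute_mvc_reference(dataset: EmgDataset, config: RunConfig,
                          subject: Optional[str] = None) -> MvcReference:
    """Max RMS envelope per muscle over that muscle's MVC trials."""
    md = dataset.trials_of_type("mvc")
    if subject is not None:
        md = md[md["subject"] == subject]
    values = np.full(N_MUSCLES, np.nan)
    for trial_id, row in md.iterrows():
        env = _trial_envelope(dataset, trial_id, config)
        m = dataset.muscle_names.index(row["mvc_muscle"])
        peak = env[m].max()
        values[m] = peak if np.isnan(values[m]) else max(values[m], peak)
    missing = [n for n, v in zip(dataset.muscle_names, values) if np.isnan(v)]
    if missing:
        raise PreprocessingError(f"no MVC trial found for muscles: {missing}")
    return MvcReference(values=values, muscle_names=dataset.muscle_names)


def preprocess_dataset(dataset: EmgDataset, config: RunConfig) -> Dict[str, np.ndarray]:
    """Full per-trial chain for every reach trial of every subject.

    Returns trial_id -> 8 x M envelope in fraction-of-MVC units, baseline
    corrected using the subject's rest trial and optionally decimated by
    ``config.envelope_decimate``.
    """
    envelopes: Dict[str, np.ndarray] = {}
    md = dataset.metadata
    for subject in dataset.subjects:
        sub_md = md[md["subject"] == subject]
        rest_ids = sub_md.index[sub_md["trial_type"] == "baseline"]
        if len(rest_ids) == 0:
            raise PreprocessingError(f"subject {subject!r} has no baseline (rest) trial")
        baseline_env = np.hstack([_trial_envelope(dataset, tid, config) for tid in rest_ids])
        ref = compute_mvc_reference(dataset, config, subject=subject)
        reach_ids = sub_md.index[sub_md["trial_type"] == "reach"]
        for trial_id in reach_ids:
            env = _trial_envelope(dataset, trial_id, config)
            env = subtract_baseline(env, baseline_env)
            env = normalize_mvc(env, ref)
            if config.envelope_decimate > 1:
                env = env[:, :: config.envelope_decimate]
            envelopes[trial_id] = env
    return envelopes


def envelope_rate(dataset: EmgDataset, config: RunConfig) -> float:
    return dataset.sampling_rate / config.envelope_decimate


def pool_by_direction(envelopes: Dict[str, np.ndarray], dataset: EmgDataset,
                      config: RunConfig, group: Optional[str] = None) -> List[EnvelopeMatrix]:
    """Build the nine direction matrices V_1..V_9.

    For each target, columns are the concatenation over subjects (sorted by
    id) and repetitions (sorted) of that direction's preprocessed trials.
    """
    md = dataset.trials_of_type("reach")
    if group is not None:
        md = md[md["group"] == group]
    out: List[EnvelopeMatrix] = []
    rate = envelope_rate(dataset, config)
    for target in range(1, 10):
        rows = md[md["target"] == target].reset_index()
        rows = rows.sort_values(["subject", "repetition"])
        if len(rows) == 0:
            raise PreprocessingError(f"no reach trials for target {target}")
        blocks, provenance, offset = [], [], 0
        for trial_id in rows["trial_id"]:
            env = envelopes[trial_id]
            blocks.append(env)
            provenance.append((trial_id, offset, offset + env.shape[1]))
            offset += env.shape[1]
        out.append(EnvelopeMatrix(
            values=np.hstack(blocks), muscle_names=dataset.muscle_names,
            sample_rate=rate, provenance=provenance,
        ))
    return out


def pool_by_subject(envelopes: Dict[str, np.ndarray], dataset: EmgDataset,
                    config: RunConfig, group: Optional[str] = None
                    ) -> Dict[str, EnvelopeMatrix]:
    """Per-subject pooled (all-direction) envelope matrices, targets and
    repetitions in sorted order."""
    md = dataset.trials_of_type("reach")
    if group is not None:
        md = md[md["group"] == group]
    rate = envelope_rate(dataset, config)
    out: Dict[str, EnvelopeMatrix] = {}
    for subject in sorted(md["subject"].unique()):
        rows = md[md["subject"] == subject].reset_index().sort_values(["target", "repetition"])
        blocks, provenance, offset = [], [], 0
        for trial_id in rows["trial_id"]:
            env = envelopes[trial_id]
            blocks.append(env)
            provenance.append((trial_id, offset, offset + env.shape[1]))
            offset += env.shape[1]
        out[subject] = EnvelopeMatrix(
            values=np.hstack(blocks), muscle_names=dataset.muscle_names,
            sample_rate=rate, provenance=provenance,
        )
    return out


def pool_by_subject_direction(envelopes: Dict[str, np.ndarray], dataset: EmgDataset,
                              config: RunConfig, group: Optional[str] = None
                              ) -> Dict[str, Dict[int, EnvelopeMatrix]]:
    """subject -> target -> pooled envelope of that subject's trials there."""
    md = dataset.trials_of_type("reach")
    if group is not None:
        md = md[md["group"] == group]
    rate = envelope_rate(dataset, config)
    out: Dict[str, Dict[int, EnvelopeMatrix]] = {}
    for subject in sorted(md["subject"].unique()):
        out[subject] = {}
        sub = md[md["subject"] == subject]
        for target in sorted(sub["target"].unique()):
            rows = sub[sub["target"] == target].reset_index().sort_values("repetition")
            blocks, provenance, offset = [], [], 0
            for trial_id in rows["trial_id"]:
                env = envelopes[trial_id]
                blocks.append(env)
                provenance.append((trial_id, offset, offset + env.shape[1]))
                offset += env.shape[1]
            out[subject][int(target)] = EnvelopeMatrix(
                values=np.hstack(blocks), muscle_names=dataset.muscle_names,
                sample_rate=rate, provenance=provenance,
            )
    return out
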