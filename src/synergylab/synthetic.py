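"""Synthetic multi-direction reaching EMG with known ground truth.

Emulates the study design the analysis assumes: 8 muscles, 9 targets on a
3x3 spatial grid, 5 repetitions per target, per-muscle MVC trials and a rest
recording per subject. EMG is generated from the same non-negative model the
analysis fits: a ground-truth synergy matrix W (8 x R, column-stochastic),
per-direction burst activations H, and raw signals built as a band-limited
(20-450 Hz) Gaussian carrier amplitude-modulated so its RMS envelope tracks

    baseline_level + W_subject @ H_target,

in fraction-of-MVC units, scaled to volts by per-muscle MVC amplitudes.
Direction structure enters through a smooth linear gain surface over the
target grid whose centroid is the central target (target 5), so the centre
direction expresses every synergy at its average amplitude. Per-subject
variation is multiplicative log-normal jitter on the W entries
(renormalized); measurement imperfection is slow multiplicative envelope
jitter of relative scale ``noise_sd`` (signal-dependent, as surface-EMG
amplitude noise is) on top of the carrier's intrinsic RMS fluctuation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .io import DEFAULT_MUSCLES, EmgDataset, N_MUSCLES


class SynthesisError(ValueError):
    pass


def _pair_distance(a: np.ndarray, b: np.ndarray) -> float:
    # same half-sum-of-squares metric used to compare extracted synergies
    return 0.5 * float(np.sum((a - b) ** 2))


def target_grid_coords(target: int) -> tuple[int, int]:
    """(x, y) in {-1,0,1}^2 for target 1..9; target 1 is left-down, 9 right-up."""
    if not 1 <= target <= 9:
        raise SynthesisError(f"target must be 1..9, got {target}")
    row, col = divmod(target - 1, 3)
    return col - 1, row - 1


@dataclass
class SyntheticGroundTruth:
    """Everything needed to regenerate a dataset and score recovery."""

    true_W: np.ndarray                   # 8 x R, columns sum to 1
    burst_peaks: np.ndarray              # per synergy, peak time fraction in (0,1)
    burst_widths: np.ndarray             # per synergy, width fraction
    base_amplitude: float                # overall burst scale, fraction of MVC
    burst_amplitudes: np.ndarray         # per synergy, equalized envelope energy
    direction_gains: np.ndarray          # 9 x R, non-negative
    noise_sd: float
    baseline_level: float
    seed: int
    second_peaks: Optional[np.ndarray] = None   # optional bimodal bursts
    subject_W: Dict[str, np.ndarray] = field(default_factory=dict)
    mvc_amplitudes: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.true_W = np.asarray(self.true_W, dtype=float)
        if (self.true_W < 0).any():
            raise SynthesisError("true_W must be non-negative")
        if not np.allclose(self.true_W.sum(axis=0), 1.0, atol=1e-9):
            raise SynthesisError("true_W columns must sum to 1")
        if (np.asarray(self.direction_gains) < 0).any():
            raise SynthesisError("direction_gains must be non-negative")

    @property
    def n_synergies(self) -> int:
        return self.true_W.shape[1]


def make_ground_truth(n_synergies: int, seed: int, *, n_muscles: int = N_MUSCLES,
                      min_separation: float = 0.05, noise_sd: float = 0.05,
                      baseline_level: float = 0.02, base_amplitude: float = 0.5,
                      gain_amplitude: float = 0.8, max_tries: int = 500
                      ) -> SyntheticGroundTruth:
    """Sample an identifiable ground truth, deterministic given ``seed``.

    W columns are drawn from a sparse non-negative (gamma) prior and
    column-normalized, rejection-resampled until every column pair is at
    least ``min_separation`` apart in the half-sum-of-squares metric.
    """
    if not 1 <= n_synergies <= n_muscles:
        raise SynthesisError(f"n_synergies must lie in [1, {n_muscles}]")
    rng = np.random.default_rng(seed)
    W = None
    for _ in range(max_tries):
        cand = rng.gamma(shape=0.45, scale=1.0, size=(n_muscles, n_synergies))
        cand = np.maximum(cand, 1e-6)
        cand /= cand.sum(axis=0)
        ok = all(
            _pair_distance(cand[:, i], cand[:, j]) >= min_separation
            for i in range(n_synergies) for j in range(i + 1, n_synergies)
        )
        if ok:
            W = cand
            break
    if W is None:
        raise SynthesisError(
            f"could not separate {n_synergies} synergies by {min_separation} "
            f"after {max_tries} tries; use fewer synergies or a lower floor"
        )

    # narrow bursts evenly spread over the movement with slight jitter, so
    # activation rows are weakly correlated and the synergies identifiable
    base = np.linspace(0.2, 0.8, n_synergies) if n_synergies > 1 else np.array([0.5])
    burst_peaks = np.clip(base + rng.uniform(-0.03, 0.03, n_synergies), 0.08, 0.92)
    burst_widths = rng.uniform(0.05, 0.08, n_synergies)

    # smooth linear gain surface over the 3x3 grid: centre target = mean gain
    phis = 2 * np.pi * (np.arange(n_synergies) + 0.2) / n_synergies
    phis += rng.uniform(-0.2, 0.2, n_synergies)
    slopes_x = gain_amplitude * np.cos(phis)
    slopes_y = gain_amplitude * np.sin(phis)
    gains = np.empty((9, n_synergies))
    for t in range(1, 10):
        x, y = target_grid_coords(t)
        gains[t - 1] = 1.0 + slopes_x * x + slopes_y * y
    gains = np.clip(gains, 0.05, None)

    # per-synergy amplitudes equalize each synergy's envelope energy: a
    # column-stochastic weight vector concentrated on few muscles has a larger
    # 2-norm, so without this the sparsest synergy would dominate the variance
    norms = np.linalg.norm(W, axis=0)
    burst_amplitudes = base_amplitude * np.exp(np.log(norms).mean()) / norms

    return SyntheticGroundTruth(
        true_W=W, burst_peaks=burst_peaks, burst_widths=burst_widths,
        base_amplitude=base_amplitude, burst_amplitudes=burst_amplitudes,
        direction_gains=gains, noise_sd=noise_sd, baseline_level=baseline_level,
        seed=seed,
    )


def synthesize_activations(gt: SyntheticGroundTruth, target: int,
                           duration_s: float, fs: float) -> np.ndarray:
    """R x M activation template for one direction: smooth unimodal (or
    bimodal) bursts scaled by that target's direction gains."""
    if duration_s <= 0:
        raise SynthesisError("duration must be positive")
    m = int(round(duration_s * fs))
    frac = np.arange(m) / m
    gains = gt.direction_gains[target - 1]
    H = np.zeros((gt.n_synergies, m))
    for r in range(gt.n_synergies):
        bump = np.exp(-0.5 * ((frac - gt.burst_peaks[r]) / gt.burst_widths[r]) ** 2)
        if gt.second_peaks is not None and np.isfinite(gt.second_peaks[r]):
            bump = bump + 0.6 * np.exp(
                -0.5 * ((frac - gt.second_peaks[r]) / gt.burst_widths[r]) ** 2
            )
        H[r] = gt.burst_amplitudes[r] * gains[r] * bump
    return H


def _jitter_W(true_W: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    W = true_W * rng.lognormal(0.0, sd, size=true_W.shape)
    return W / W.sum(axis=0)


def _carrier(n: int, n_ch: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Band-limited (20-450 Hz) unit-RMS Gaussian carrier, samples x channels."""
    white = rng.standard_normal((n, n_ch))
    sos = sps.butter(4, [20.0, min(450.0, 0.45 * fs)], btype="bandpass", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, white, axis=0)
    return band / band.std(axis=0, keepdims=True)


def _smooth_noise(n: int, n_ch: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Slow unit-variance noise for envelope corruption (~10 Hz bandwidth)."""
    raw = rng.standard_normal((n_ch, n))
    win = max(3, int(fs / 10))
    smooth = uniform_filter1d(raw, size=win, axis=1, mode="reflect")
    sd = smooth.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return smooth / sd


def synthesize_dataset(gt: SyntheticGroundTruth, n_subjects: int, reps: int = 5,
                       duration_s: float = 1.0, *, fs: float = 2000.0,
                       group: str = "control", subject_prefix: str = "s",
                       subject_jitter_sd: float = 0.1, mvc_duration_s: float = 1.0,
                       seed: Optional[int] = None) -> EmgDataset:
    """Generate the full study design for one group.

    Per subject: 9 targets x ``reps`` reach trials, one MVC trial per muscle
    (a plateau at that muscle's reference maximum), and one rest trial.
    Subject-specific synergy matrices and MVC amplitudes are stored on ``gt``
    for recovery scoring.
    """
    if n_subjects < 1 or reps < 1:
        raise SynthesisError("need n_subjects >= 1 and reps >= 1")
    rng = np.random.default_rng(gt.seed + 1 if seed is None else seed)
    signals: Dict[str, np.ndarray] = {}
    rows = []
    m_reach = int(round(duration_s * fs))
    m_mvc = int(round(mvc_duration_s * fs))

    for s in range(1, n_subjects + 1):
        subject = f"{subject_prefix}{s:02d}"
        W_s = _jitter_W(gt.true_W, subject_jitter_sd, rng)
        mvc_amp = rng.uniform(0.5, 1.5, size=N_MUSCLES)
        gt.subject_W[subject] = W_s
        gt.mvc_amplitudes[subject] = mvc_amp

        for target in range(1, 10):
            H = synthesize_activations(gt, target, duration_s, fs)
            for rep in range(1, reps + 1):
                env = gt.baseline_level + W_s @ H          # 8 x M, fraction of MVC
                if gt.noise_sd > 0:
                    # signal-dependent (multiplicative) jitter: noise_sd is a
                    # relative scale, so weak muscles stay proportionally clean
                    env = env * (1.0 + gt.noise_sd * _smooth_noise(
                        m_reach, N_MUSCLES, fs, rng))
                env = np.clip(env, 0.0, None)
                volts = env * mvc_amp[:, None]
                raw = _carrier(m_reach, N_MUSCLES, fs, rng) * volts.T
                trial_id = f"{subject}_t{target}_r{rep}"
                signals[trial_id] = raw
                rows.append((trial_id, subject, group, target, rep, "reach", ""))

        for m, muscle in enumerate(DEFAULT_MUSCLES):
            frac = np.full((N_MUSCLES, m_mvc), gt.baseline_level)
            ramp = int(0.2 * m_mvc)
            plateau = np.ones(m_mvc)
            plateau[:ramp] = np.linspace(0.0, 1.0, ramp)
            plateau[-ramp:] = np.linspace(1.0, 0.0, ramp)
            frac[m] = gt.baseline_level + plateau
            volts = frac * mvc_amp[:, None]
            raw = _carrier(m_mvc, N_MUSCLES, fs, rng) * volts.T
            trial_id = f"{subject}_mvc_{muscle}"
            signals[trial_id] = raw
            rows.append((trial_id, subject, group, np.nan, np.nan, "mvc", muscle))

        volts = np.full((N_MUSCLES, m_reach), gt.baseline_level) * mvc_amp[:, None]
        raw = _carrier(m_reach, N_MUSCLES, fs, rng) * volts.T
        trial_id = f"{subject}_rest"
        signals[trial_id] = raw
        rows.append((trial_id, subject, group, np.nan, np.nan, "baseline", ""))

    metadata = pd.DataFrame(
        rows, columns=["trial_id", "subject", "group", "target", "repetition",
                       "trial_type", "mvc_muscle"],
    ).set_index("trial_id")
    return EmgDataset(signals=signals, metadata=metadata, sampling_rate=fs,
                      muscle_names=list(DEFAULT_MUSCLES))
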