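"""Run configuration: every tunable of the pipeline with validated defaults.

Defaults reproduce the study conditions of the analysis: a 50-sample RMS
window at 2000 Hz (25 ms around each time point), a 20-450 Hz band-pass,
the 85 % / 6 % VAF rule with the MSE < 0.02 diagnostic, 4 synergies in the
9x9 cross-validation, a 1000-shuffle permutation null with the
90th-percentile similarity rule, and K-means over K = 4..9 with 10 runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Tuple

import yaml


@dataclass
class RunConfig:
    """All pipeline tunables.

    Numeric fields are validated at construction; a :class:`ValueError`
    names the offending field.
    """

    # preprocessing
    rms_window_samples: int = 50          # 25 ms around each time point at 2 kHz
    bandpass_hz: Tuple[float, float] = (20.0, 450.0)
    envelope_decimate: int = 1            # keep every n-th envelope sample (1 = off)

    # model order selection
    vaf_threshold_pct: float = 85.0
    vaf_increment_pct: float = 6.0
    mse_threshold: float = 0.02           # advisory concordance diagnostic
    r_range: Tuple[int, int] = (1, 7)

    # cross-validation
    crossval_r: int = 4

    # NMF numerics
    n_restarts: int = 20
    max_iter: int = 1000
    tol: float = 1e-6

    # similarity / permutation null
    n_shuffles: int = 1000
    similarity_percentile_rule: float = 90.0
    similarity_metric: str = "half_squared"   # or "euclidean_over_2"

    # clustering
    linkage_method: str = "ward"
    pairing_rule: str = "keep_more_similar"   # or "keep_less_similar"

    # direction discrimination
    kmeans_k_range: Tuple[int, int] = (4, 9)
    kmeans_runs: int = 10
    min_peak_width_samples: int = 500     # 0.25 s at the 2 kHz envelope rate

    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        positive_ints = {
            "rms_window_samples": self.rms_window_samples,
            "envelope_decimate": self.envelope_decimate,
            "crossval_r": self.crossval_r,
            "n_restarts": self.n_restarts,
            "max_iter": self.max_iter,
            "n_shuffles": self.n_shuffles,
            "kmeans_runs": self.kmeans_runs,
            "min_peak_width_samples": self.min_peak_width_samples,
        }
        for name, value in positive_ints.items():
            if int(value) != value or value < 1:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if self.rms_window_samples < 2:
            raise ValueError("rms_window_samples must be >= 2")
        low, high = self.bandpass_hz
        if not (0 < low < high):
            raise ValueError(f"bandpass_hz must satisfy 0 < low < high, got {self.bandpass_hz}")
        if not (0 < self.vaf_threshold_pct < 100):
            raise ValueError("vaf_threshold_pct must lie in (0, 100)")
        if not (0 < self.vaf_increment_pct < 100):
            raise ValueError("vaf_increment_pct must lie in (0, 100)")
        if self.mse_threshold <= 0:
            raise ValueError("mse_threshold must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        r_lo, r_hi = self.r_range
        if not (1 <= r_lo <= r_hi <= 8):
            raise ValueError(f"r_range must satisfy 1 <= lo <= hi <= 8, got {self.r_range}")
        if not (1 <= self.crossval_r <= 8):
            raise ValueError("crossval_r must lie in [1, 8]")
        if not (0 <= self.similarity_percentile_rule <= 100):
            raise ValueError("similarity_percentile_rule must lie in [0, 100]")
        if self.similarity_metric not in ("half_squared", "euclidean_over_2"):
            raise ValueError(f"unknown similarity_metric {self.similarity_metric!r}")
        if self.linkage_method not in ("ward", "single", "complete", "average"):
            raise ValueError(f"unknown linkage_method {self.linkage_method!r}")
        if self.pairing_rule not in ("keep_more_similar", "keep_less_similar"):
            raise ValueError(f"unknown pairing_rule {self.pairing_rule!r}")
        k_lo, k_hi = self.kmeans_k_range
        if not (1 <= k_lo <= k_hi):
            raise ValueError(f"kmeans_k_range must satisfy 1 <= lo <= hi, got {self.kmeans_k_range}")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @property
    def r_values(self) -> range:
        return range(self.r_range[0], self.r_range[1] + 1)

    def effective_peak_width(self) -> int:
        """MinPeakWidth in decimated-envelope samples (0.25 s regardless of rate)."""
        return max(1, round(self.min_peak_width_samples / self.envelope_decimate))

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key, value in data.items():
            if isinstance(value, tuple):
                data[key] = list(value)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, value in data.items():
            if isinstance(value, list):
                data[key] = tuple(value)
        return cls(**data)
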