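"""Direction discrimination from activation-coefficient features.

Each of the 81 cross-validation coefficient matrices H_ij is summarized by
11 features per synergy row: six equally spaced trace samples, time to the
first and second wide peaks with their amplitudes (times as fractions of
trace duration, so cells of different lengths are comparable), and the
duration-normalized area under the trace. Peaks must exceed a minimum width
(default 500 samples at 2 kHz = 0.25 s); a missing peak is substituted by
the trace's mean amplitude at the middle time point. With R = 4 synergies
the feature vector has 44 entries.

K-means (random centroids from distinct data points, 10 runs per K, K from
4 to 9) clusters the 81 standardized feature vectors; labels are laid out on
the 9x9 grid (rows = data direction i, columns = synergy source j) and
scored by purity: the share of cells carrying their row's modal label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks
from sklearn.cluster import KMeans

from .nmf import ActivationSet


class DiscriminationError(ValueError):
    pass


N_POINTS_DEFAULT = 6
FEATURES_PER_SYNERGY = 11


def _trace_features(trace: np.ndarray, min_peak_width: int, n_points: int) -> np.ndarray:
    m = trace.size
    positions = np.round(np.arange(1, n_points + 1) / (n_points + 1) * (m - 1)).astype(int)
    samples = trace[positions]
    peaks, _ = find_peaks(trace, width=min_peak_width)
    peaks = np.sort(peaks)
    mean_amp = float(trace.mean())
    if len(peaks) >= 1:
        t1, a1 = peaks[0] / m, trace[peaks[0]]
    else:
        t1, a1 = 0.5, mean_amp
    if len(peaks) >= 2:
        t2, a2 = peaks[1] / m, trace[peaks[1]]
    else:
        t2, a2 = 0.5, mean_amp
    area = float(trace.sum()) / m
    return np.concatenate([samples, [t1, a1, t2, a2, area]])


def extract_features(H: np.ndarray | ActivationSet, min_peak_width: int = 500,
                     n_points: int = N_POINTS_DEFAULT) -> np.ndarray:
    """11-per-synergy feature vector of an activation matrix (length 11*R)."""
    if isinstance(H, ActivationSet):
        H = H.H
    H = np.asarray(H, dtype=float)
    if H.ndim != 2:
        raise DiscriminationError("H must be 2-D (synergies x samples)")
    if (H < 0).any():
        raise DiscriminationError("H must be non-negative")
    if H.shape[1] <= min_peak_width:
        raise DiscriminationError(
            f"trace of {H.shape[1]} samples is not longer than min_peak_width="
            f"{min_peak_width}; use longer traces or a smaller width"
        )
    return np.concatenate([_trace_features(row, min_peak_width, n_points) for row in H])


@dataclass
class KmeansResult:
    k: int
    label_grids: List[np.ndarray]       # one 9x9 grid per run
    purities: np.ndarray                # per run
    seed: int

    @property
    def mean_purity(self) -> float:
        return float(self.purities.mean())

    @property
    def sd_purity(self) -> float:
        return float(self.purities.std(ddof=1)) if len(self.purities) > 1 else 0.0


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise DiscriminationError("all feature dimensions are constant")
    return (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]


def kmeans_directions(features: Dict[Tuple[int, int], np.ndarray] | np.ndarray,
                      K: int, n_runs: int = 10, seed: int = 0) -> KmeansResult:
    """Cluster the 81 cross-validation cells and lay labels on the 9x9 grid.

    ``features`` maps (data direction i, synergy source j) to a feature
    vector, or is an 81 x d array in row-major (i, j) order. Each run uses
    random centroid initialization from distinct data points followed by
    Lloyd iterations; deterministic given ``seed``.
    """
    if isinstance(features, dict):
        if len(features) != 81:
            raise DiscriminationError(f"expected 81 feature vectors, got {len(features)}")
        X = np.vstack([features[(i, j)] for i in range(1, 10) for j in range(1, 10)])
    else:
        X = np.asarray(features, dtype=float)
        if X.shape[0] != 81:
            raise DiscriminationError(f"expected 81 feature rows, got {X.shape[0]}")
    if K > X.shape[0]:
        raise DiscriminationError(f"K={K} exceeds the {X.shape[0]} data points")
    Xs = _standardize(X)
    seeds = np.random.SeedSequence(seed).spawn(n_runs)
    grids, purities = [], []
    for sub_seq in seeds:
        run_seed = int(sub_seq.generate_state(1)[0] % (2**31 - 1))
        km = KMeans(n_clusters=K, init="random", n_init=1, algorithm="lloyd",
                    random_state=run_seed)
        labels = km.fit_predict(Xs) + 1
        grid = labels.reshape(9, 9)
        grids.append(grid)
        purities.append(purity(grid))
    return KmeansResult(k=K, label_grids=grids, purities=np.asarray(purities), seed=seed)


def purity(label_grid: np.ndarray) -> float:
    """Percent of grid cells carrying their row's modal label.

    Ties in the row mode break toward the smallest label. A grid with a
    single distinct label scores 100 (a known pathology of the metric;
    callers can detect it from the label count).
    """
    grid = np.asarray(label_grid)
    if grid.ndim != 2:
        raise DiscriminationError("label grid must be 2-D")
    correct = 0
    for row in grid:
        labels, counts = np.unique(row, return_counts=True)
        modal = labels[np.argmax(counts)]        # np.unique sorts: ties -> smallest
        correct += int((row == modal).sum())
    return 100.0 * correct / grid.size


def direction_correlation_matrix(per_direction_features: Sequence[np.ndarray]) -> np.ndarray:
    """Pearson correlations between the 9 per-direction feature vectors.

    Symmetric with unit diagonal; a zero-variance vector yields NaN against
    every other direction (recorded as missing).
    """
    X = np.vstack([np.asarray(f, dtype=float) for f in per_direction_features])
    n = X.shape[0]
    corr = np.ones((n, n))
    sds = X.std(axis=1)
    for a in range(n):
        for b in range(a + 1, n):
            if sds[a] == 0 or sds[b] == 0:
                corr[a, b] = corr[b, a] = np.nan
            else:
                corr[a, b] = corr[b, a] = float(np.corrcoef(X[a], X[b])[0, 1])
    for a in range(n):
        if sds[a] == 0:
            corr[a, a] = 1.0            # self-correlation defined as 1 by convention
    return corr
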