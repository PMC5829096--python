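"""Synergy matching, the similarity index, and its permutation null.

Two synergy sets (column-stochastic 8 x R matrices) are first matched by the
column permutation minimizing the total pairwise distance (exhaustive over
all R! orderings). The similarity index of a matched pair of synergies is

    d(a, b) = 1/2 * sum_m (a_m - b_m)^2,

averaged over the R matched pairs; it is 0 for identical sets and exactly 1
for disjoint one-hot weight vectors, the documented maximum for columns that
sum to one. An alternative reading (plain Euclidean distance over two) is
available as ``metric="euclidean_over_2"``.

Chance level is calibrated by shuffling: each synergy's 8 weights are
randomly reordered ``n_shuffles`` times in both sets (the shuffle space per
synergy is 8! = 40320 orderings), and all n_shuffles^2 cross pairs of the
two random ensembles are scored. The percentile is the share of null pairs
strictly *worse* (larger index) than the observed mean; sets are declared
similar when that percentile reaches the 90th-percentile rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .nmf import SynergySet


class SimilarityError(ValueError):
    pass


@dataclass
class SimilarityResult:
    permutation: Tuple[int, ...]          # columns of B reordered to match A
    per_synergy: np.ndarray
    mean: float
    percentile: Optional[float] = None
    n_shuffles: Optional[int] = None
    n_null_pairs: Optional[int] = None
    null_ties: Optional[int] = None
    degenerate: bool = False
    seed: Optional[int] = None

    def is_similar(self, rule: float = 90.0) -> bool:
        if self.percentile is None:
            raise SimilarityError("percentile not computed; run shuffle_null first")
        return self.percentile >= rule


def _as_W(W) -> np.ndarray:
    if isinstance(W, SynergySet):
        W = W.W
    W = np.asarray(W, dtype=float)
    if W.ndim != 2:
        raise SimilarityError("synergy set must be 2-D (muscles x synergies)")
    if not np.allclose(W.sum(axis=0), 1.0, atol=1e-6):
        raise SimilarityError("synergy columns must sum to 1; normalize first")
    return W


def _pair_values(A: np.ndarray, B: np.ndarray, metric: str) -> np.ndarray:
    sq = np.sum((A - B) ** 2, axis=0)
    if metric == "half_squared":
        return 0.5 * sq
    if metric == "euclidean_over_2":
        return np.sqrt(sq) / 2.0
    raise SimilarityError(f"unknown metric {metric!r}")


def shuffle_space_size(n_muscles: int = 8) -> int:
    """Number of distinct weight orderings of one synergy (n! permutations)."""
    return factorial(n_muscles)


def match_synergies(Wa, Wb, metric: str = "half_squared") -> Tuple[int, ...]:
    """Column permutation of Wb minimizing the total matched distance.

    Exhaustive over all R! orderings (R <= 8). Returns ``perm`` such that
    ``Wb[:, perm]`` pairs column-for-column with ``Wa``.
    """
    A, B = _as_W(Wa), _as_W(Wb)
    if A.shape != B.shape:
        raise SimilarityError(f"synergy sets differ in shape: {A.shape} vs {B.shape}")
    R = A.shape[1]
    dist = cdist(A.T, B.T, "sqeuclidean")
    if metric == "euclidean_over_2":
        dist = np.sqrt(dist) / 2.0
    else:
        dist = 0.5 * dist
    best, best_total = None, np.inf
    for perm in permutations(range(R)):
        total = dist[np.arange(R), perm].sum()
        if total < best_total - 1e-15:
            best, best_total = perm, total
    return best


def similarity_index(Wa, Wb, metric: str = "half_squared",
                     matched: bool = True) -> Tuple[float, np.ndarray]:
    """Mean and per-synergy similarity-index values of two matched sets.

    With ``matched=False`` the optimal matching is applied first. Values lie
    in [0, 1] for column-stochastic inputs under the half-squared metric.
    """
    A, B = _as_W(Wa), _as_W(Wb)
    if A.shape != B.shape:
        raise SimilarityError(f"synergy sets differ in shape: {A.shape} vs {B.shape}")
    if not matched:
        perm = match_synergies(A, B, metric)
        B = B[:, perm]
    values = _pair_values(A, B, metric)
    return float(values.mean()), values


def shuffle_null(Wa, Wb, n_shuffles: int = 1000, seed: int = 0,
                 metric: str = "half_squared") -> SimilarityResult:
    """Match the sets, score them, and calibrate against the shuffled null.

    For each synergy of each set, ``n_shuffles`` random reorderings of its 8
    weights form a random ensemble; all ``n_shuffles**2`` cross pairs are
    scored with the set-level mean similarity. The percentile is the share
    of null pairs strictly greater than the observed mean (larger index =
    less similar), so high percentiles mean the observed sets are closer
    than chance. Ties with the observed value are counted and, when every
    null pair ties (e.g. uniform weights, which shuffling cannot change),
    the result is flagged degenerate.
    """
    A, B = _as_W(Wa), _as_W(Wb)
    perm = match_synergies(A, B, metric)
    B = B[:, perm]
    observed_mean, per_synergy = similarity_index(A, B, metric)

    rng = np.random.default_rng(seed)
    R, n_m = A.shape[1], A.shape[0]
    null_sq = np.zeros((n_shuffles, n_shuffles))
    for r in range(R):
        a_perms = rng.permuted(np.tile(A[:, r], (n_shuffles, 1)), axis=1)
        b_perms = rng.permuted(np.tile(B[:, r], (n_shuffles, 1)), axis=1)
        null_sq += cdist(a_perms, b_perms, "sqeuclidean")
    if metric == "half_squared":
        null = 0.5 * null_sq / R
    else:
        # mean of per-synergy euclidean/2 needs per-synergy distances
        null = np.zeros((n_shuffles, n_shuffles))
        rng = np.random.default_rng(seed)
        for r in range(R):
            a_perms = rng.permuted(np.tile(A[:, r], (n_shuffles, 1)), axis=1)
            b_perms = rng.permuted(np.tile(B[:, r], (n_shuffles, 1)), axis=1)
            null += np.sqrt(cdist(a_perms, b_perms, "sqeuclidean")) / 2.0
        null /= R

    greater = int((null > observed_mean + 1e-12).sum())
    ties = int((np.abs(null - observed_mean) <= 1e-12).sum())
    n_pairs = null.size
    return SimilarityResult(
        permutation=perm, per_synergy=per_synergy, mean=observed_mean,
        percentile=100.0 * greater / n_pairs, n_shuffles=n_shuffles,
        n_null_pairs=n_pairs, null_ties=ties, degenerate=(ties == n_pairs),
        seed=seed,
    )


def is_similar(result: SimilarityResult, rule: float = 90.0) -> bool:
    """True iff the observed similarity beats ``rule`` percent of null pairs."""
    return result.is_similar(rule)


def direction_similarity_profiles(per_subject_direction_W: Dict[str, Dict[int, np.ndarray]],
                                  W_rep, metric: str = "half_squared") -> pd.DataFrame:
    """Per-subject 9-vectors of similarity to the representative set.

    ``per_subject_direction_W`` maps subject -> target -> synergy matrix
    extracted from that subject's trials toward that target. Subjects
    missing a direction get NaN there (excluded from group statistics).
    Returns a DataFrame (subjects x targets 1..9).
    """
    rows = {}
    for subject, by_target in per_subject_direction_W.items():
        vec = np.full(9, np.nan)
        for target, W in by_target.items():
            mean, _ = similarity_index(W_rep, W, metric, matched=False)
            vec[int(target) - 1] = mean
        rows[subject] = vec
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"target_{t}" for t in range(1, 10)])
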