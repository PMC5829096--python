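"""Hierarchical clustering of per-subject synergies and between-group pairing.

Each subject contributes R synergy weight vectors (rows of a stacked
(n_subjects * R) x 8 matrix). A dendrogram (Euclidean distance, Ward linkage
by default) is cut at increasing k until the flat clustering puts no two
synergies of the same subject in one cluster; that minimal k is the number
of clusters reported for the group. Few clusters mean subjects share
synergies; many mean subjects recruit idiosyncratic ones.

Between groups, cluster centroids (mean synergy per cluster, renormalized to
sum one) are paired greedily by global minimum similarity-index distance
until every cluster of the smaller group is paired; each pair is scored by
the similarity index and its permutation percentile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Dict, List, Optional, Sequence, Tuple
import warnings

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .nmf import SynergySet
from .similarity import shuffle_null, similarity_index


class ClusteringError(ValueError):
    pass


@dataclass
class ClusterPartition:
    stacked: np.ndarray                 # (n_subjects * R) x 8
    subject_labels: List[str]
    assignments: np.ndarray             # cluster id per row, 1..n_clusters
    n_clusters: int
    centroids: np.ndarray               # n_clusters x 8, rows sum to 1
    subjects_per_cluster: np.ndarray
    linkage_method: str = "ward"

    def __post_init__(self) -> None:
        if not _satisfies_subject_constraint(self.assignments, self.subject_labels):
            raise ClusteringError("partition puts two synergies of one subject in a cluster")


def _satisfies_subject_constraint(assignments: np.ndarray,
                                  subject_labels: Sequence[str]) -> bool:
    seen = set()
    for cluster, subject in zip(assignments, subject_labels):
        key = (int(cluster), subject)
        if key in seen:
            return False
        seen.add(key)
    return True


def stack_synergies(per_subject: Dict[str, np.ndarray | SynergySet]
                    ) -> Tuple[np.ndarray, List[str]]:
    """Stack each subject's R synergies as rows; all subjects must agree on R.

    12 subjects x 4 synergies gives the 48 x 8 layout; 13 give 52 x 8.
    """
    blocks, labels = [], []
    r_expected = None
    for subject in sorted(per_subject):
        W = per_subject[subject]
        W = W.W if isinstance(W, SynergySet) else np.asarray(W, dtype=float)
        if r_expected is None:
            r_expected = W.shape[1]
        elif W.shape[1] != r_expected:
            raise ClusteringError(
                f"subject {subject!r} contributes {W.shape[1]} synergies, expected {r_expected}"
            )
        blocks.append(W.T)              # rows = synergies
        labels.extend([subject] * W.shape[1])
    return np.vstack(blocks), labels


def min_valid_partition(stacked: np.ndarray, subject_labels: Sequence[str],
                        linkage_method: str = "ward") -> ClusterPartition:
    """Smallest dendrogram cut with at most one synergy per subject per cluster.

    Scans k upward from R (synergies per subject). If even n_rows - 1
    clusters violate the constraint, the trivial all-singleton partition is
    returned with a warning.
    """
    stacked = np.asarray(stacked, dtype=float)
    subject_labels = list(subject_labels)
    n = stacked.shape[0]
    if n != len(subject_labels):
        raise ClusteringError("subject_labels length must match stacked rows")
    r_per_subject = max(np.bincount(
        np.unique(subject_labels, return_inverse=True)[1]))
    Z = linkage(stacked, method=linkage_method, metric="euclidean")
    chosen = None
    for k in range(int(r_per_subject), n + 1):
        assignments = fcluster(Z, t=k, criterion="maxclust")
        if _satisfies_subject_constraint(assignments, subject_labels):
            chosen = (k, assignments)
            break
    if chosen is None:
        chosen = (n, np.arange(1, n + 1))
    if chosen[0] == n and n > r_per_subject:
        warnings.warn("subject constraint only satisfiable by the all-singleton partition",
                      RuntimeWarning, stacklevel=2)
    k, assignments = chosen
    ids = np.unique(assignments)
    centroids = np.vstack([stacked[assignments == c].mean(axis=0) for c in ids])
    centroids = centroids / centroids.sum(axis=1, keepdims=True)
    subjects_per_cluster = np.array([
        len(set(s for s, a in zip(subject_labels, assignments) if a == c)) for c in ids
    ])
    return ClusterPartition(
        stacked=stacked, subject_labels=subject_labels, assignments=assignments,
        n_clusters=len(ids), centroids=centroids,
        subjects_per_cluster=subjects_per_cluster, linkage_method=linkage_method,
    )


@dataclass
class ClusterPair:
    cluster_a: int
    cluster_b: int
    similarity: float
    percentile: Optional[float] = None


def _greedy_min_matching(dist: np.ndarray) -> List[Tuple[int, int]]:
    """Repeatedly take the globally closest unmatched cross-group pair."""
    n_a, n_b = dist.shape
    n_pairs = min(n_a, n_b)
    used_a, used_b, pairs = set(), set(), []
    order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
    for a, b in order:
        if a in used_a or b in used_b:
            continue
        pairs.append((int(a), int(b)))
        used_a.add(a)
        used_b.add(b)
        if len(pairs) == n_pairs:
            break
    return pairs


def exhaustive_min_matching(dist: np.ndarray) -> List[Tuple[int, int]]:
    """Brute-force minimum-total-distance injection (oracle for small inputs)."""
    n_a, n_b = dist.shape
    if n_a <= n_b:
        best, best_total = None, np.inf
        for perm in permutations(range(n_b), n_a):
            total = sum(dist[a, b] for a, b in enumerate(perm))
            if total < best_total:
                best, best_total = list(enumerate(perm)), total
        return [(int(a), int(b)) for a, b in best]
    flipped = exhaustive_min_matching(dist.T)
    return [(b, a) for a, b in flipped]


def pair_clusters_between_groups(pa: ClusterPartition, pb: ClusterPartition, *,
                                 metric: str = "half_squared",
                                 pairing_rule: str = "keep_more_similar",
                                 n_shuffles: int = 1000, seed: int = 0
                                 ) -> List[ClusterPair]:
    """Pair each cluster of the smaller group with its closest counterpart.

    ``keep_more_similar`` (default) resolves conflicts in favour of the
    closer pair and re-matches the loser — the greedy global-minimum
    procedure. ``keep_less_similar`` keeps the *farther* pair instead,
    preserving the alternative reading of the pairing rule.
    """
    dist = np.empty((pa.n_clusters, pb.n_clusters))
    for a in range(pa.n_clusters):
        for b in range(pb.n_clusters):
            mean, _ = similarity_index(pa.centroids[a][:, None],
                                       pb.centroids[b][:, None], metric)
            dist[a, b] = mean
    effective = dist if pairing_rule == "keep_more_similar" else -dist
    pairs = _greedy_min_matching(effective)
    out = []
    for a, b in pairs:
        null = shuffle_null(pa.centroids[a][:, None], pb.centroids[b][:, None],
                            n_shuffles=n_shuffles, seed=seed, metric=metric)
        out.append(ClusterPair(cluster_a=a + 1, cluster_b=b + 1,
                               similarity=dist[a, b], percentile=null.percentile))
    return out
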