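"""End-to-end orchestration of the synergy analysis on one dataset.

Stages mirror the analysis order: preprocess -> order selection ->
cross-validation / representative set -> similarity profiling + tests ->
clustering -> direction discrimination. Each stage is a plain function so
drivers (CLI, analysis scripts, tests) can run any prefix of the chain.
"""

from __future__ import annotations

import logging
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import clustering as clu
from . import discrimination as disc
from . import model_selection as ms
from . import preprocessing as pp
from . import similarity as sim
from . import stats as st
from .config import RunConfig
from .io import EmgDataset
from .nmf import fit_fixed_basis, nmf

log = logging.getLogger("synergylab")


def preprocess_stage(dataset: EmgDataset, config: RunConfig, group: Optional[str] = None):
    envelopes = pp.preprocess_dataset(dataset, config)
    direction_V = pp.pool_by_direction(envelopes, dataset, config, group=group)
    subject_V = pp.pool_by_subject(envelopes, dataset, config, group=group)
    subject_dir_V = pp.pool_by_subject_direction(envelopes, dataset, config, group=group)
    log.info("preprocess: %d trials -> 9 direction matrices (%d cols total), %d subjects",
             len(envelopes), sum(v.values.shape[1] for v in direction_V), len(subject_V))
    return envelopes, direction_V, subject_V, subject_dir_V


def order_stage(subject_V, config: RunConfig):
    curve = ms.vaf_curve(
        {s: v.values for s, v in subject_V.items()}, config.r_values,
        n_restarts=config.n_restarts, max_iter=config.max_iter,
        tol=config.tol, seed=config.seed,
    )
    ms.mse_linear_fit(curve)
    r_star, diagnostics = ms.select_order(
        curve, vaf_threshold=config.vaf_threshold_pct,
        increment=config.vaf_increment_pct, mse_threshold=config.mse_threshold,
    )
    log.info("order selection: R*=%d (curve means %s)", r_star,
             np.round(curve.mean, 2).tolist())
    return curve, r_star, diagnostics


def crossval_stage(direction_V, config: RunConfig, R: Optional[int] = None):
    R = config.crossval_r if R is None else R
    cv = ms.crossval_matrix(
        [v.values for v in direction_V], R,
        n_restarts=config.n_restarts, max_iter=config.max_iter,
        tol=config.tol, seed=config.seed,
    )
    rep = ms.select_representative(cv)
    log.info("cross-validation: representative direction j*=%d (row mean %.2f)",
             rep, cv.row_means[rep - 1])
    return cv, rep


def similarity_stage(subject_dir_V, W_rep, config: RunConfig, R: int):
    per_subject_direction_W: Dict[str, Dict[int, np.ndarray]] = {}
    for subject, by_target in subject_dir_V.items():
        per_subject_direction_W[subject] = {}
        for target, V in by_target.items():
            res = nmf(V.values, R, n_restarts=config.n_restarts,
                      max_iter=config.max_iter, tol=config.tol, seed=config.seed,
                      source=f"subject:{subject}:target:{target}")
            per_subject_direction_W[subject][target] = res.synergies.W
    profiles = sim.direction_similarity_profiles(
        per_subject_direction_W, W_rep, metric=config.similarity_metric)
    log.info("similarity: %d subjects profiled against the representative set",
             len(profiles))
    return per_subject_direction_W, profiles


def subject_synergies_stage(subject_V, config: RunConfig, R: int):
    """Per-subject pooled (all-direction) synergy sets, for clustering and
    representative-set comparisons."""
    out = {}
    for subject, V in subject_V.items():
        res = nmf(V.values, R, n_restarts=config.n_restarts,
                  max_iter=config.max_iter, tol=config.tol, seed=config.seed,
                  source=f"subject:{subject}")
        out[subject] = res.synergies.W
    return out


def clustering_stage(per_subject_W, config: RunConfig):
    stacked, labels = clu.stack_synergies(per_subject_W)
    partition = clu.min_valid_partition(stacked, labels, config.linkage_method)
    log.info("clustering: %d rows -> %d clusters (%s linkage)",
             stacked.shape[0], partition.n_clusters, config.linkage_method)
    return partition


def discrimination_stage(cv: ms.CrossValMatrix, direction_V, W_rep, config: RunConfig):
    width = config.effective_peak_width()
    features = {
        key: disc.extract_features(H, min_peak_width=width)
        for key, H in cv.activations.items()
    }
    k_lo, k_hi = config.kmeans_k_range
    kmeans_results = {
        k: disc.kmeans_directions(features, k, n_runs=config.kmeans_runs,
                                  seed=config.seed + k)
        for k in range(k_lo, k_hi + 1)
    }
    per_direction = []
    for i, V in enumerate(direction_V, start=1):
        res = fit_fixed_basis(V.values, W_rep, n_restarts=config.n_restarts,
                              max_iter=config.max_iter, tol=config.tol, seed=config.seed)
        per_direction.append(disc.extract_features(res.activations.H, min_peak_width=width))
    corr = disc.direction_correlation_matrix(per_direction)
    log.info("discrimination: purity by K = %s",
             {k: round(r.mean_purity, 2) for k, r in kmeans_results.items()})
    return features, kmeans_results, corr


def run_all(dataset: EmgDataset, config: RunConfig, group: Optional[str] = None) -> dict:
    """Run the full chain and return a results dictionary.

    The cross-validation uses the selected order R* when it falls inside
    [3, 5] (the scanned range), otherwise ``config.crossval_r``.
    """
    _, direction_V, subject_V, subject_dir_V = preprocess_stage(dataset, config, group)
    curve, r_star, diagnostics = order_stage(subject_V, config)
    r_cv = r_star if 3 <= r_star <= 5 else config.crossval_r
    cv, rep = crossval_stage(direction_V, config, R=r_cv)
    W_rep = cv.synergies[rep - 1]
    _, profiles = similarity_stage(subject_dir_V, W_rep, config, r_cv)
    tests = st.pairwise_direction_tests(profiles) if len(profiles.dropna()) >= 2 else None
    per_subject_W = subject_synergies_stage(subject_V, config, r_cv)
    partition = clustering_stage(per_subject_W, config)
    features, kmeans_results, corr = discrimination_stage(cv, direction_V, W_rep, config)
    purity_table = pd.DataFrame({
        "K": list(kmeans_results),
        "mean_purity": [r.mean_purity for r in kmeans_results.values()],
        "sd_purity": [r.sd_purity for r in kmeans_results.values()],
    }).set_index("K")
    return {
        "selected_order": r_star,
        "order_diagnostics": diagnostics,
        "crossval_r": r_cv,
        "vaf_curve": curve,
        "crossval": cv,
        "representative_direction": rep,
        "representative_W": W_rep.W,
        "similarity_profiles": profiles,
        "pairwise_tests": tests,
        "per_subject_W": per_subject_W,
        "partition": partition,
        "n_clusters": partition.n_clusters,
        "kmeans": kmeans_results,
        "purity_table": purity_table,
        "direction_correlations": corr,
    }


def results_to_report(results: dict) -> dict:
    """Flatten run_all output into write_report-compatible artifacts."""
    out = {
        "selected_order": results["selected_order"],
        "crossval_r": results["crossval_r"],
        "representative_direction": results["representative_direction"],
        "n_clusters": results["n_clusters"],
        "order_diagnostics": results["order_diagnostics"],
        "representative_W": results["representative_W"],
        "crossval_matrix": results["crossval"].to_frame(),
        "similarity_profiles": results["similarity_profiles"],
        "purity_table": results["purity_table"],
        "direction_correlations": results["direction_correlations"],
    }
    if results.get("pairwise_tests") is not None:
        out["pairwise_p_values"] = results["pairwise_tests"].to_frame()
    partition = results["partition"]
    out["cluster_assignments"] = pd.DataFrame({
        "subject": partition.subject_labels,
        "cluster": partition.assignments,
    })
    return out
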