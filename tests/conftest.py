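"""Shared fixtures: one small synthetic study reused across the suite.

Session scope keeps the expensive pieces (dataset synthesis, the 9x9
cross-validation) to a single computation.
"""

import numpy as np
import pytest

from synergylab import RunConfig, make_ground_truth, synthesize_dataset
from synergylab import pipeline as pl


@pytest.fixture(scope="session")
def fast_config():
    # envelopes decimated to 50 Hz and few NMF restarts: small enough for CI,
    # large enough that every stage is genuinely exercised
    return RunConfig(envelope_decimate=40, n_restarts=3, max_iter=500,
                     tol=1e-5, seed=1, kmeans_runs=5)


@pytest.fixture(scope="session")
def ground_truth():
    return make_ground_truth(4, seed=1)


@pytest.fixture(scope="session")
def small_dataset(ground_truth):
    return synthesize_dataset(ground_truth, n_subjects=3, reps=3, duration_s=1.0)


@pytest.fixture(scope="session")
def preprocessed(small_dataset, fast_config):
    envelopes, direction_V, subject_V, subject_dir_V = pl.preprocess_stage(
        small_dataset, fast_config)
    return {"envelopes": envelopes, "direction_V": direction_V,
            "subject_V": subject_V, "subject_dir_V": subject_dir_V}


@pytest.fixture(scope="session")
def crossval_result(preprocessed, fast_config):
    cv, rep = pl.crossval_stage(preprocessed["direction_V"], fast_config, R=4)
    return cv, rep


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
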