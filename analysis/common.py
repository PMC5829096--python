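"""Shared study definition for the analysis scripts.

One synthetic two-group study, regenerated deterministically by every
script: a control group and a "study" group with larger between-subject
synergy variability (emulating the heterogeneity of post-stroke
participants). Six subjects per group, 9 targets x 5 repetitions of 1 s
reaches, envelopes decimated to 50 Hz for tractable factorizations.
"""

from pathlib import Path

from synergylab import RunConfig, make_ground_truth, synthesize_dataset

STUDY_SEED = 20180223
RESULTS = Path(__file__).resolve().parent.parent / "results"

CONFIG = RunConfig(envelope_decimate=40, n_restarts=3, max_iter=500,
                   tol=1e-5, seed=STUDY_SEED % (2**31 - 1))

N_SUBJECTS = 6
REPS = 5
DURATION_S = 1.0


def make_study():
    """(ground truth, control dataset, study dataset)."""
    gt = make_ground_truth(4, seed=CONFIG.seed, noise_sd=0.05)
    control = synthesize_dataset(gt, n_subjects=N_SUBJECTS, reps=REPS,
                                 duration_s=DURATION_S, group="control",
                                 subject_prefix="c", subject_jitter_sd=0.10,
                                 seed=CONFIG.seed + 1)
    study = synthesize_dataset(gt, n_subjects=N_SUBJECTS, reps=REPS,
                               duration_s=DURATION_S, group="study",
                               subject_prefix="p", subject_jitter_sd=0.25,
                               seed=CONFIG.seed + 2)
    return gt, control, study


def out_dir(name: str) -> Path:
    path = RESULTS / name
    path.mkdir(parents=True, exist_ok=True)
    return path
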