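"""Compare per-subject synergies with the representative set, within and
between groups.

Each subject's pooled EMG is factorized at R = 4; synergies are matched to
the representative set and scored with the similarity index plus its
10^6-pair permutation percentile (similar when the observed value beats 90 %
of shuffled-weight pairs). Group means are compared with an independent
t-test.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONFIG, make_study, out_dir

from synergylab import pipeline as pl
from synergylab.similarity import shuffle_null
from synergylab.stats import independent_t


def main():
    _, control, study = make_study()
    out = out_dir("04_compare_synergies")

    _, direction_V, _, _ = pl.preprocess_stage(control, CONFIG)
    cv, rep = pl.crossval_stage(direction_V, CONFIG, R=4)
    W_rep = cv.synergies[rep - 1]

    rows = []
    per_group = {}
    for name, ds in [("control", control), ("study", study)]:
        _, _, subject_V, _ = pl.preprocess_stage(ds, CONFIG)
        per_subject_W = pl.subject_synergies_stage(subject_V, CONFIG, R=4)
        per_group[name] = per_subject_W
        for subject, W in per_subject_W.items():
            res = shuffle_null(W_rep.W, W, n_shuffles=CONFIG.n_shuffles,
                               seed=CONFIG.seed)
            rows.append({"group": name, "subject": subject,
                         "similarity": res.mean, "percentile": res.percentile,
                         "similar": res.is_similar(CONFIG.similarity_percentile_rule)})
    table = pd.DataFrame(rows)
    table.to_csv(out / "subject_similarity.csv", index=False)

    c = table[table.group == "control"]
    s = table[table.group == "study"]
    t_sim = independent_t(c["similarity"].to_numpy(), s["similarity"].to_numpy())
    t_pct = independent_t(c["percentile"].to_numpy(), s["percentile"].to_numpy())

    for name, sub in [("control", c), ("study", s)]:
        print(f"{name}: mean similarity {sub['similarity'].mean():.3f} "
              f"({sub['similarity'].std(ddof=1):.3f}), mean percentile "
              f"{sub['percentile'].mean():.2f}; "
              f"{int(sub['similar'].sum())}/{len(sub)} subjects similar to the "
              f"representative set")
    print(f"Between groups: similarity t = {t_sim.statistic:.3f} "
          f"(p = {t_sim.p_value:.3f}); percentile t = {t_pct.statistic:.3f} "
          f"(p = {t_pct.p_value:.3f})")
    print(f"Tables written to {out}")


if __name__ == "__main__":
    main()
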