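"""Validate the representative set: direction similarity profiles, paired
t-test matrices, K-means discrimination of direction, and direction
correlation matrices.

Per subject and direction, synergies are extracted and scored against the
representative set (9-vector profiles; paired t-tests between all 36
direction pairs). The 81 cross-validation activation matrices are reduced
to 44 features each and clustered by K-means (K = 4..9, 10 runs each);
purity measures how well clusters align with movement direction.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONFIG, make_study, out_dir

from synergylab import pipeline as pl
from synergylab.io import write_matrix
from synergylab.stats import pairwise_direction_tests


def main():
    _, control, study = make_study()
    out = out_dir("06_discriminate_directions")

    purity_rows = []
    for name, ds in [("control", control), ("study", study)]:
        _, direction_V, _, subject_dir_V = pl.preprocess_stage(ds, CONFIG)
        cv, rep = pl.crossval_stage(direction_V, CONFIG, R=4)
        W_rep = cv.synergies[rep - 1]

        _, profiles = pl.similarity_stage(subject_dir_V, W_rep, CONFIG, R=4)
        profiles.to_csv(out / f"direction_profiles_{name}.csv")
        tests = pairwise_direction_tests(profiles)
        tests.to_frame().to_csv(out / f"pairwise_p_{name}.csv")
        n_sig = int((tests.p_values[np.triu_indices(9, 1)] < 0.05).sum())

        _, kmeans_results, corr = pl.discrimination_stage(cv, direction_V,
                                                          W_rep, CONFIG)
        write_matrix(corr, out / f"direction_correlations_{name}.csv",
                     row_labels=[f"target_{t}" for t in range(1, 10)],
                     col_labels=[f"target_{t}" for t in range(1, 10)])
        for k, res in kmeans_results.items():
            purity_rows.append({"group": name, "K": k,
                                "mean_purity": round(res.mean_purity, 3),
                                "sd_purity": round(res.sd_purity, 3)})

        print(f"{name}: representative target {rep}; "
              f"{n_sig}/36 direction pairs significant at p < 0.05; "
              f"purity K=4: {kmeans_results[4].mean_purity:.1f} %, "
              f"K=9: {kmeans_results[9].mean_purity:.1f} %")

    table = pd.DataFrame(purity_rows)
    table.to_csv(out / "kmeans_purity.csv", index=False)
    print(f"Tables written to {out}")


if __name__ == "__main__":
    main()
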