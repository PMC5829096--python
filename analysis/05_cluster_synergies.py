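"""Cluster per-subject synergies per group and pair clusters between groups.

Each group's stacked synergy rows (6 subjects x 4 synergies = 24 x 8) are
clustered hierarchically (Ward); the reported number of clusters is the
smallest cut with at most one synergy per subject per cluster. Fewer
clusters mean subjects share synergies; the study group carries larger
between-subject jitter, probing whether shared structure survives it.
Control clusters are then paired with their closest study counterparts and
scored with the permutation-calibrated similarity index.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONFIG, make_study, out_dir

from synergylab import pipeline as pl
from synergylab.clustering import pair_clusters_between_groups


def main():
    _, control, study = make_study()
    out = out_dir("05_cluster_synergies")

    partitions = {}
    for name, ds in [("control", control), ("study", study)]:
        _, _, subject_V, _ = pl.preprocess_stage(ds, CONFIG)
        per_subject_W = pl.subject_synergies_stage(subject_V, CONFIG, R=4)
        partition = pl.clustering_stage(per_subject_W, CONFIG)
        partitions[name] = partition
        pd.DataFrame({"subject": partition.subject_labels,
                      "cluster": partition.assignments}).to_csv(
            out / f"assignments_{name}.csv", index=False)
        print(f"{name}: {partition.n_clusters} clusters for "
              f"{partition.stacked.shape[0]} synergy vectors "
              f"(subjects per cluster: {partition.subjects_per_cluster.tolist()})")

    pairs = pair_clusters_between_groups(
        partitions["control"], partitions["study"],
        metric=CONFIG.similarity_metric, pairing_rule=CONFIG.pairing_rule,
        n_shuffles=CONFIG.n_shuffles, seed=CONFIG.seed)
    pair_table = pd.DataFrame([{
        "control_cluster": p.cluster_a, "study_cluster": p.cluster_b,
        "similarity": p.similarity, "percentile": p.percentile,
        "similar": p.percentile >= CONFIG.similarity_percentile_rule,
    } for p in pairs])
    pair_table.to_csv(out / "cluster_pairs.csv", index=False)
    n_similar = int(pair_table["similar"].sum())
    print(f"{len(pairs)} cross-group cluster pairs; {n_similar} similar under "
          f"the {CONFIG.similarity_percentile_rule:.0f}th-percentile rule")
    print(f"Tables written to {out}")


if __name__ == "__main__":
    main()
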