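# synergylab

Muscle-synergy analysis of multi-direction hand-reaching EMG, built for
motor-control researchers who want the full chain — envelope preprocessing,
synergy extraction, model-order selection, cross-validated representative
sets, permutation-calibrated similarity, clustering, and direction
discrimination — as tested, scriptable Python rather than ad-hoc lab code.

## The model

Surface EMG from `N = 8` shoulder/arm muscles is reduced to a non-negative
envelope matrix `V` (muscles × time) and factorized as

    V ≈ W H,    W ≥ 0 (N × R),  H ≥ 0 (R × M)

by multiplicative-update NMF: each column of `W` is a *muscle synergy* (a
fixed weighting across muscles, normalized to sum to one) and each row of
`H` its time-varying activation. The package asks the questions this model
makes precise:

- **How many synergies?** Per-subject VAF curves over R = 1..7 with the
  85 % / 6-point-increment rule, plus a straight-line MSE diagnostic, where
  `VAF = 100·(1 − ‖V − WH‖²_F / ‖V − V̄‖²_F)`.
- **Is one set of synergies enough for all directions?** A 9×9
  cross-validation: direction `i`'s pooled envelope is refit with direction
  `j`'s synergies held fixed (81 fits); the synergy row with the highest
  mean VAF is the *representative set*.
- **Are two synergy sets the same?** Columns matched by minimal distance,
  scored with the similarity index `½ Σ (Δweight)²` (0 = identical, 1 =
  disjoint one-hot), calibrated against 10⁶ pairs of weight-shuffled
  synergies; similar when the observed value beats 90 % of the null.
- **Do subjects share synergies?** Hierarchical clustering of stacked
  per-subject synergies, cut at the smallest k with at most one synergy
  per subject per cluster.
- **Does activation alone encode direction?** 11 features per synergy from
  each cross-validation activation matrix (44 features at R = 4), K-means
  over K = 4..9, scored by purity on the 9×9 grid.

Because no public recordings accompany this design, the package ships a
first-class synthetic generator that emulates the study — 9 targets on a
3×3 grid, 5 repetitions, MVC and rest trials, raw EMG as amplitude-modulated
band-limited carriers over a known `W·H` — so every stage has a
ground-truth recovery test.

## Worked example

```python
import numpy as np
from synergylab import RunConfig, make_ground_truth, synthesize_dataset
from synergylab import pipeline as pl
from synergylab.similarity import similarity_index

config = RunConfig(envelope_decimate=40, n_restarts=3, max_iter=500,
                   tol=1e-5, seed=1)
gt = make_ground_truth(n_synergies=4, seed=1, noise_sd=0.05)
dataset = synthesize_dataset(gt, n_subjects=5, reps=5, duration_s=1.0)

_, direction_V, subject_V, _ = pl.preprocess_stage(dataset, config)
curve, r_star, _ = pl.order_stage(subject_V, config)
cv, representative = pl.crossval_stage(direction_V, config, R=4)
W_rep = cv.synergies[representative - 1].W
recovery, _ = similarity_index(gt.true_W, W_rep, matched=False)

print("mean VAF by R:", np.round(curve.mean, 1))
print("selected order:", r_star)
print("representative direction:", representative,
      "row mean VAF: %.2f" % cv.row_means[representative - 1])
print("similarity of W_rep to planted synergies: %.4f" % recovery)
```

prints

```
mean VAF by R: [38.5 69.9 91.5 98.5 99.1 99.5 99.6]
selected order: 4
representative direction: 5 row mean VAF: 98.02
similarity of W_rep to planted synergies: 0.0173
```

Read: the VAF curve knees at the planted order (R = 4 is the first order
above 85 % whose next increment is under 6 points); cross-validation picks
target 5 — the centre of the reaching space, the centroid of the
direction-gain design — as the representative set; and that set sits at
similarity 0.017 from the planted synergies (0 = identical, 1 = maximally
different).

The same chain is packaged as numbered drivers under `analysis/`
(`01_simulate.py` … `06_discriminate_directions.py`), each printing what it
found and writing its tables under `results/`, and as a CLI:

```bash
synergylab simulate --out data/ --subjects 5
synergylab run-all --data data/ --out results/run/
```

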