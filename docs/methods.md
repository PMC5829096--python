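# Methods

## The model

Surface EMG from `N = 8` shoulder/arm muscles during hand reaching is
summarized by its non-negative envelope matrix `V` (muscles × time). The
muscle-synergy model factorizes it as

    V ≈ W H,   W ≥ 0 (N × R),  H ≥ 0 (R × M),

where each column of `W` is a *synergy* — a fixed balance of muscle weights —
and each row of `H` its time-varying activation. The hypothesis the pipeline
probes is modular control: a small set of synergies, fixed across movement
directions, whose activations alone are modulated to reach different
targets.

Factorization uses the classical multiplicative updates for the squared
Frobenius loss, which never increase the objective. Two fit modes exist:
free (both factors updated) and fixed-basis (`W` given, only `H` updated),
the engine of the cross-validation. After fitting, `W` columns are rescaled
to sum to one with `H` rescaled inversely; this leaves `W·H` unchanged and
bounds similarity indices. Reconstruction quality is the variance accounted
for,

    VAF = 100 · (1 − ‖V − WH‖²_F / ‖V − V̄‖²_F),

with `V̄` the per-row (per-muscle) mean. VAF can be negative and equals 100
only for exact reconstruction.

## Pipeline stages

1. **Preprocessing.** Per trial: zero-phase 4th-order Butterworth band-pass
   (20–450 Hz), per-channel demeaning, centred 50-sample RMS (25 ms around
   each time point at 2 kHz; window truncated symmetrically at the edges so
   output length equals input length), subtraction of the subject's mean
   resting envelope with clipping at zero (negative "activity" is
   meaningless for the non-negative model), and division by each muscle's
   MVC reference (the maximum RMS envelope over that muscle's MVC trials).
   Envelopes can be decimated by an integer factor (default off) purely for
   speed; the burst structure the factorization uses lives far below the
   envelope's original bandwidth.
2. **Model order.** Per subject, the pooled all-direction envelope is
   factorized at R = 1..7 (best of `n_restarts` random initializations per
   R). The binding rule selects the smallest R with mean VAF > 85 % and a
   gain of less than 6 points from adding another synergy. A second,
   advisory criterion fits least-squares lines to the curve tail from each
   start point and reports the first start whose fit MSE (on the 0–1 VAF
   scale) drops below 0.02; it is reported as a concordance diagnostic, not
   used for the decision, because its outcome depends strongly on curve
   curvature far from the knee.
3. **Representative set.** Per direction `i`, the group-pooled envelope
   `V_i` gets a free factorization `W_i`; every `(j, i)` pair is refit with
   `W_j` fixed, giving 81 activation matrices `H_ij` and a 9×9 VAF grid.
   The row (synergy source) with the highest mean VAF is the representative
   set — the direction whose synergies generalize best. Ties break toward
   the lower row SD, then the lower index.
4. **Similarity.** Two synergy sets are matched by the column permutation
   minimizing total distance (exhaustive over R! orderings), then scored per
   matched pair with `d(a,b) = ½ Σ_m (a_m − b_m)²`, averaged over pairs:
   0 = identical, and exactly 1 for disjoint one-hot weight vectors — the
   natural maximum for columns that sum to one. The printed form of this
   index is typographically ambiguous about an outer square root; the
   half-sum-of-squares reading is the only one whose maximum is exactly 1,
   and the alternative (`‖a−b‖/2`, maximum √2/2) remains available as
   `similarity_metric="euclidean_over_2"`. Chance calibration shuffles each
   synergy's 8 weights (8! = 40320 possible orderings) 1000 times per set
   and scores all 10⁶ cross pairs of the two random ensembles; the
   percentile is the share of null pairs strictly *worse* than the observed
   mean, and sets are declared similar at the 90th-percentile rule. Ties
   with the observed value are counted; a uniform synergy, which shuffling
   cannot change, is flagged degenerate. The null is computed on the
   set-level mean (per-synergy values are also reported); whether the
   original procedure averaged per-synergy percentiles instead is not
   decidable from its description.
5. **Clustering.** Each subject's R synergies are stacked as rows
   (subjects × R rows of 8 weights) and clustered hierarchically (Euclidean
   distance; Ward linkage by default, with single/complete/average
   available — the linkage was not specified by the original procedure and
   Ward is the common choice in this literature). The dendrogram is cut at
   increasing k until no cluster holds two synergies of one subject; that
   minimal k is the group's cluster count. Between groups, cluster
   centroids (mean synergy, renormalized) are paired greedily by global
   minimum similarity — equivalent to "keep the closer pair and re-match
   the loser", which is how the ambiguous conflict rule is read here; the
   opposite reading is available as `pairing_rule="keep_less_similar"`.
6. **Direction discrimination.** Each of the 81 `H_ij` is reduced to 11
   features per synergy: six equally spaced samples of the synergy's row,
   time and amplitude of the first and second peaks wider than
   `min_peak_width` (missing peaks substituted by the trace mean at time
   0.5), and the duration-normalized area. Times are expressed as fractions
   of trace duration because the 81 cells have different lengths; raw
   sample indices would confound direction with duration. Features are
   standardized per dimension (constant dimensions dropped) — amplitudes
   and time fractions are incommensurate — then clustered with K-means
   (random centroids, Lloyd iterations, 10 runs per K, K = 4..9). Labels
   are laid out on the 9×9 grid (rows = data direction) and scored by
   purity: the percentage of cells carrying their row's modal label (row
   ties break toward the smallest label; a single-label grid scores 100,
   a known pathology detectable from the label count). Direction
   correlation matrices are unweighted Pearson correlations between the
   per-direction feature vectors obtained by refitting each `V_i` with the
   representative set.
7. **Statistics.** Within-group direction effects use paired t-tests over
   all 36 direction pairs of the per-subject similarity profiles
   (unadjusted p by default, Bonferroni on request); between-group
   comparisons use independent t-tests (Student by default, Welch
   optional).

## The synthetic study

No recordings accompany the original design, so the generator emulates it:
8 muscles, 9 targets on a 3×3 grid, 5 repetitions per target, per-muscle
MVC trials and a rest trial per subject.

- **Ground truth.** `W` columns are drawn from a sparse gamma prior
  (shape 0.45) and column-normalized, rejection-sampled until every column
  pair is at least 0.05 apart in the similarity metric. Activations are
  narrow Gaussian bursts (widths 0.05–0.08 of the trial, peaks spread over
  0.2–0.8) so activation rows are weakly correlated; per-synergy burst
  amplitudes are scaled by the inverse column 2-norm so every synergy
  carries a comparable share of envelope energy. Both choices serve the
  generator's identifiability contract: with wide overlapping bursts or
  unbalanced energies, a 3-synergy fit of 4-synergy data already explains
  most of the variance and no order criterion could be expected to recover
  the truth.
- **Direction structure** is a linear gain surface over the grid,
  `gain(t, r) = 1 + a_r·x_t + b_r·y_t` (clipped at 0.05), with per-synergy
  slope directions spread around the circle. The central target always has
  gain 1 for every synergy — it is the centroid of the design — which is
  why cross-validation should select it as representative: corner targets
  under-express some synergies and estimate them poorly.
- **Raw signals** are band-limited (20–450 Hz) unit-RMS Gaussian carriers
  amplitude-modulated by `baseline + W_s H` (fraction-of-MVC), scaled to
  volts by per-muscle MVC amplitudes drawn per subject, so the band-pass +
  RMS chain is genuinely exercised. Per-subject variation is log-normal
  jitter on `W` entries (σ = 0.1 by default, renormalized). Envelope noise
  is slow (≈10 Hz) *multiplicative* jitter of relative scale `noise_sd`
  (default 0.05): surface-EMG amplitude noise is signal-dependent, and a
  relative scale keeps weakly weighted muscles proportionally clean.
- **What it does not emulate:** motor-unit physiology, kinematics, ECG or
  motion artifacts, electrode placement error, fatigue, or the genuinely
  idiosyncratic (non-jitter) synergy reorganization seen after stroke.
  Passing recovery tests therefore shows the pipeline is correct and
  well-conditioned under its own model assumptions — not that those
  assumptions hold for any particular recording.

## Numerical choices

- NMF: initialization i.i.d. uniform(0.1, 1.1) (avoids zero-locking),
  ε = 1e-12 in update denominators, stop when the error decrease falls
  below `tol`·‖V‖² (default 1e-6) or 1000 iterations, best of 20 restarts
  by default. The original runs' tolerances and restart counts are unknown;
  these are documented defaults, not claims about them. All-zero muscle
  rows are floored at ε with a warning; an all-zero matrix is an error.
- `min_peak_width` is defined at the 2 kHz envelope rate (500 samples =
  0.25 s) and scaled by the decimation factor so its physical duration is
  rate-independent.
- Analysis scripts and the test suite run at reduced scale — 5–6 subjects
  per group, 1 s trials, envelopes decimated to 50 Hz, 2–3 NMF restarts —
  chosen as the smallest study at which every recovery property is
  exercised with margin. Cohort-scale quantities from real recordings
  (group VAF levels, cluster counts near 17, similarity means near 0.3)
  are not reproducible from synthetic data at this scale and are treated as
  qualitative context only.

## Known limitations

- The exhaustive R! matching is intended for R ≤ 8 and is instant only for
  the R ≤ 4–6 range used here.
- Greedy cluster pairing is not guaranteed to minimize total distance for
  adversarial centroid geometries (it matches the brute-force optimum
  whenever clusters have clear cross-group twins, the regime it exists
  for).
- The MVC reference is a maximum of a short-window RMS estimate and
  overshoots the true plateau by a noise-dependent factor; this cancels in
  any per-muscle ratio but biases absolute fraction-of-MVC units downward.
- K-means purity is computed against the grid's row structure; it rewards
  any labelling aligned with data direction, including degenerate ones
  (single cluster), which callers must screen by label count.
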