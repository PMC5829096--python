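"""Model-order selection and the 9x9 cross-validated representative set.

Two order criteria are computed from the per-subject VAF curve over R = 1..7:
the binding rule — the smallest R whose mean VAF exceeds 85 % with less than
a 6-point gain from adding another synergy — and an advisory straight-line
criterion: least-squares lines are fitted to the curve tail starting at each
point (all points, 2nd..7th, ... 5th..7th) and the first start whose fit MSE
drops below a threshold (default 0.02, on the 0-1 VAF scale) marks the knee.

The representative set is found by cross-validation over directions: each
direction's pooled envelope V_i gets its own free factorization W_i, then
every V_i is refit with every W_j held fixed, yielding the 81-cell VAF grid.
The W_j row with the highest mean VAF generalizes best across directions and
is the representative set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .nmf import FactorizationError, SynergySet, fit_fixed_basis, nmf


class SelectionError(ValueError):
    pass


@dataclass
class VafCurve:
    r_values: List[int]
    mean: np.ndarray
    sd: np.ndarray
    per_subject: pd.DataFrame          # subjects x R
    mse: np.ndarray = None             # filled by mse_linear_fit

    def __post_init__(self) -> None:
        r = np.asarray(self.r_values)
        if len(r) > 1 and not (np.diff(r) == 1).all():
            raise SelectionError("r_range must be contiguous")
        if not np.isfinite(self.mean).all():
            raise SelectionError("VAF means must be finite")


@dataclass
class CrossValMatrix:
    """9x9 grid: cell (j, i) = VAF of refitting direction i's data with
    direction j's synergies (rows = W_j, columns = V_i)."""

    values: np.ndarray
    synergies: List[SynergySet] = field(default_factory=list)
    activations: Dict[Tuple[int, int], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (9, 9):
            raise SelectionError(f"cross-validation matrix must be 9x9, got {self.values.shape}")

    @property
    def row_means(self) -> np.ndarray:
        return self.values.mean(axis=1)

    @property
    def row_sds(self) -> np.ndarray:
        return self.values.std(axis=1, ddof=1)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values,
                             index=[f"W{j}" for j in range(1, 10)],
                             columns=[f"V{i}" for i in range(1, 10)])
        frame["row_mean"] = self.row_means
        frame["row_sd"] = self.row_sds
        return frame


def vaf_curve(per_subject_V: Dict[str, np.ndarray], r_values: Sequence[int], *,
              n_restarts: int = 20, max_iter: int = 1000, tol: float = 1e-6,
              seed: int = 0) -> VafCurve:
    """Free NMF per subject per R on the subject's pooled envelope."""
    r_values = list(r_values)
    table = {}
    for subject, V in per_subject_V.items():
        V = V.values if hasattr(V, "values") and not isinstance(V, np.ndarray) else np.asarray(V)
        row = []
        for R in r_values:
            try:
                res = nmf(V, R, n_restarts=n_restarts, max_iter=max_iter,
                          tol=tol, seed=seed, source=f"subject:{subject}")
            except FactorizationError as exc:
                raise SelectionError(f"subject {subject!r}, R={R}: {exc}") from exc
            row.append(res.vaf_pct)
        table[subject] = row
    frame = pd.DataFrame.from_dict(table, orient="index", columns=[f"R{r}" for r in r_values])
    return VafCurve(r_values=r_values, mean=frame.mean(axis=0).to_numpy(),
                    sd=frame.std(axis=0, ddof=1).fillna(0.0).to_numpy(), per_subject=frame)


def mse_linear_fit(curve: VafCurve) -> np.ndarray:
    """Per-start-point MSE of straight-line fits to the VAF curve tail.

    For start k the line is fitted through points k..r_max; the last two
    start points are excluded (a two-point line is exact by construction).
    MSE is computed on the 0-1 VAF scale to match the conventional
    threshold magnitudes.
    """
    r = np.asarray(curve.r_values, dtype=float)
    v = np.asarray(curve.mean, dtype=float) / 100.0
    n = len(r)
    if n < 3:
        raise SelectionError("need at least 3 curve points for the linear-fit criterion")
    mses = []
    for k in range(n - 2):
        coeffs = np.polyfit(r[k:], v[k:], 1)
        resid = v[k:] - np.polyval(coeffs, r[k:])
        mses.append(float(np.mean(resid ** 2)))
    curve.mse = np.asarray(mses)
    return curve.mse


def select_order(curve: VafCurve, vaf_threshold: float = 85.0,
                 increment: float = 6.0, mse_threshold: float = 0.02
                 ) -> Tuple[int, dict]:
    """Binding VAF rule plus the advisory MSE concordance diagnostic.

    Returns (R*, diagnostics) where R* is the smallest R with
    mean VAF > ``vaf_threshold`` and a gain of less than ``increment`` VAF
    points from R+1; the diagnostics carry the MSE-knee estimate.
    """
    mean = np.asarray(curve.mean)
    r_values = list(curve.r_values)
    chosen = None
    for i, R in enumerate(r_values[:-1]):
        if mean[i] > vaf_threshold and (mean[i + 1] - mean[i]) < increment:
            chosen = R
            break
    if chosen is None:
        raise SelectionError(
            f"no R in {r_values} satisfies VAF > {vaf_threshold} with increment < "
            f"{increment}; curve means = {np.round(mean, 2).tolist()}"
        )
    mses = curve.mse if curve.mse is not None else mse_linear_fit(curve)
    mse_knee = None
    for k, m in enumerate(mses):
        if m < mse_threshold:
            mse_knee = r_values[k]
            break
    return chosen, {
        "mse": mses.tolist(),
        "mse_knee_r": mse_knee,
        "concordant": mse_knee == chosen,
        "curve_mean": mean.tolist(),
    }


def crossval_matrix(direction_V: Sequence, R: int, *, n_restarts: int = 20,
                    max_iter: int = 1000, tol: float = 1e-6, seed: int = 0,
                    keep_activations: bool = True) -> CrossValMatrix:
    """Free NMF per direction, then fixed-basis refits for all 81 (j, i) pairs."""
    if len(direction_V) != 9:
        raise SelectionError(f"expected 9 direction matrices, got {len(direction_V)}")
    mats = [np.asarray(V.values if hasattr(V, "values") and not isinstance(V, np.ndarray) else V)
            for V in direction_V]
    synergies: List[SynergySet] = []
    for i, V in enumerate(mats, start=1):
        try:
            res = nmf(V, R, n_restarts=n_restarts, max_iter=max_iter, tol=tol,
                      seed=seed, source=f"direction:{i}")
        except FactorizationError as exc:
            raise SelectionError(f"free fit failed for direction {i}: {exc}") from exc
        synergies.append(res.synergies)

    values = np.empty((9, 9))
    activations: Dict[Tuple[int, int], np.ndarray] = {}
    for j in range(9):          # synergy source W_j
        for i in range(9):      # data direction V_i
            try:
                res = fit_fixed_basis(mats[i], synergies[j], n_restarts=n_restarts,
                                      max_iter=max_iter, tol=tol, seed=seed)
            except FactorizationError as exc:
                raise SelectionError(f"fixed-basis fit failed at (W{j+1}, V{i+1}): {exc}") from exc
            values[j, i] = res.vaf_pct
            if keep_activations:
                activations[(i + 1, j + 1)] = res.activations.H
    return CrossValMatrix(values=values, synergies=synergies, activations=activations)


def select_representative(cv: CrossValMatrix) -> int:
    """Direction index (1-based) whose synergy row has the highest mean VAF.

    Ties (within 1e-9) break toward the lower row SD, then the lower index.
    """
    means = cv.row_means
    sds = cv.row_sds
    order = sorted(range(9), key=lambda j: (-means[j], sds[j], j))
    best = order[0]
    return best + 1
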