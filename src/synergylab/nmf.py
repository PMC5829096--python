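"""Non-negative matrix factorization of EMG envelopes and the VAF metric.

The envelope matrix V (8 muscles x M samples) is modelled as a linear
combination of R muscle synergies,

    V  ~  W H,    W >= 0 (8 x R),  H >= 0 (R x M),

where each column of W holds the fixed muscle-weight balance of one synergy
and each row of H its time-varying activation. Factors are found by the
classical multiplicative updates that monotonically decrease the squared
Frobenius reconstruction error. Two fit modes are provided: the free fit
(both factors updated) and the fixed-basis fit in which W is supplied and
only H is updated — the workhorse of the 9x9 cross-validation.

Reconstruction quality is summarized by the Variance Accounted For,

    VAF = 100 * (1 - ||V - WH||_F^2 / ||V - Vbar||_F^2),

with Vbar holding each row's mean; VAF can be negative for fits worse than
the row-mean predictor and equals 100 only for exact reconstruction.

After every fit, W columns are rescaled to sum to one (H inversely), a pure
renormalization that leaves W·H unchanged and makes similarity indices
between synergy sets bounded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

_EPS = 1e-12


class FactorizationError(ValueError):
    """Raised for inputs the factorization cannot meaningfully process."""


@dataclass
class SynergySet:
    """A non-negative 8 x R synergy matrix, columns normalized to sum 1."""

    W: np.ndarray
    muscle_names: Optional[List[str]] = None
    source: str = "pooled"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2:
            raise FactorizationError("W must be 2-D (muscles x synergies)")
        if (self.W < 0).any():
            raise FactorizationError("W must be non-negative")
        sums = self.W.sum(axis=0)
        if (sums <= 0).any():
            raise FactorizationError("W has an all-zero synergy column")
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise FactorizationError("W columns must sum to 1 (call normalize_factors)")

    @property
    def n_synergies(self) -> int:
        return self.W.shape[1]


@dataclass
class ActivationSet:
    """Non-negative R x M activation coefficients paired with a SynergySet."""

    H: np.ndarray
    synergies: SynergySet

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        if self.H.ndim != 2 or self.H.shape[0] != self.synergies.n_synergies:
            raise FactorizationError(
                f"H row count {self.H.shape} must equal the paired R={self.synergies.n_synergies}"
            )
        if (self.H < 0).any():
            raise FactorizationError("H must be non-negative")


@dataclass
class FactorizationResult:
    synergies: SynergySet
    activations: ActivationSet
    vaf_pct: float
    iterations: int
    converged: bool
    seed: int
    objective_history: np.ndarray = field(repr=False, default=None)

    def reconstruction(self) -> np.ndarray:
        return self.synergies.W @ self.activations.H


def normalize_factors(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rescale so W columns sum to 1, H rescaled inversely; W·H unchanged."""
    scale = W.sum(axis=0)
    if (scale <= 0).any():
        raise FactorizationError("cannot normalize an all-zero synergy column")
    return W / scale, H * scale[:, None]


def vaf(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Variance Accounted For (percent) of the reconstruction W·H of V."""
    V = np.asarray(V, dtype=float)
    resid = V - W @ H
    centered = V - V.mean(axis=1, keepdims=True)
    denom = float(np.sum(centered * centered))
    if denom <= 0.0:
        raise FactorizationError("VAF undefined: every row of V is constant")
    return 100.0 * (1.0 - float(np.sum(resid * resid)) / denom)


def _prepare_v(V: np.ndarray) -> np.ndarray:
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise FactorizationError("V must be 2-D (muscles x samples)")
    if (V < 0).any():
        raise FactorizationError("V must be non-negative")
    if not V.any():
        raise FactorizationError("V is all zero; nothing to factorize")
    zero_rows = ~V.any(axis=1)
    if zero_rows.any():
        warnings.warn(
            f"{int(zero_rows.sum())} all-zero muscle row(s) floored at {_EPS:g} for stability",
            RuntimeWarning, stacklevel=3,
        )
        V = V.copy()
        V[zero_rows] = _EPS
    return V


def _mu_iterate(V, W, H, *, update_w: bool, max_iter: int, tol: float):
    """Multiplicative updates; returns (W, H, errors, iterations, converged)."""
    norm_v = float(np.sum(V * V))
    errors = []
    prev = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if update_w:
            W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        H *= (W.T @ V) / ((W.T @ W) @ H + _EPS)
        resid = V - W @ H
        err = float(np.sum(resid * resid))
        errors.append(err)
        if prev - err <= tol * max(norm_v, _EPS):
            converged = True
            break
        prev = err
    return W, H, np.asarray(errors), it, converged


def _single_fit(V, R, rng, *, max_iter, tol):
    n, m = V.shape
    W = rng.uniform(0.1, 1.1, size=(n, R))
    H = rng.uniform(0.1, 1.1, size=(R, m))
    return _mu_iterate(V, W, H, update_w=True, max_iter=max_iter, tol=tol)


def nmf(V: np.ndarray, R: int, *, n_restarts: int = 20, max_iter: int = 1000,
        tol: float = 1e-6, seed: int = 0, muscle_names: Optional[List[str]] = None,
        source: str = "pooled") -> FactorizationResult:
    """Free NMF: best of ``n_restarts`` random multiplicative-update fits.

    Initial factors are i.i.d. uniform(0.1, 1.1) to avoid zero-locking; each
    restart draws from an independent stream derived from ``seed``, and the
    restart with the lowest final squared error is kept. Deterministic for a
    given seed.
    """
    V = _prepare_v(V)
    n, m = V.shape
    if not 1 <= R <= n:
        raise FactorizationError(f"R must lie in [1, {n}], got {R}")
    if m <= R:
        raise FactorizationError(f"need more samples than synergies (M={m}, R={R})")
    best = None
    seeds = np.random.SeedSequence(seed).spawn(n_restarts)
    for restart, sub_seq in enumerate(seeds):
        rng = np.random.default_rng(sub_seq)
        W, H, errors, its, conv = _single_fit(V, R, rng, max_iter=max_iter, tol=tol)
        if best is None or errors[-1] < best[2][-1]:
            best = (W, H, errors, its, conv, restart)
    W, H, errors, its, conv, restart = best
    W, H = normalize_factors(W, H)
    syn = SynergySet(W=W, muscle_names=muscle_names, source=source)
    act = ActivationSet(H=H, synergies=syn)
    return FactorizationResult(
        synergies=syn, activations=act, vaf_pct=vaf(V, W, H),
        iterations=its, converged=conv, seed=restart, objective_history=errors,
    )


def fit_fixed_basis(V: np.ndarray, W_fixed: SynergySet | np.ndarray, *,
                    n_restarts: int = 20, max_iter: int = 1000, tol: float = 1e-6,
                    seed: int = 0) -> FactorizationResult:
    """Fixed-basis fit: W is given, only the activation coefficients H are
    updated to convergence (same tolerances as :func:`nmf`)."""
    if isinstance(W_fixed, SynergySet):
        syn = W_fixed
    else:
        syn = SynergySet(W=np.asarray(W_fixed, dtype=float))
    V = _prepare_v(V)
    if V.shape[0] != syn.W.shape[0]:
        raise FactorizationError("V and W_fixed disagree on the number of muscles")
    m = V.shape[1]
    best = None
    seeds = np.random.SeedSequence(seed).spawn(n_restarts)
    for restart, sub_seq in enumerate(seeds):
        rng = np.random.default_rng(sub_seq)
        H0 = rng.uniform(0.1, 1.1, size=(syn.n_synergies, m))
        W, H, errors, its, conv = _mu_iterate(
            V, syn.W.copy(), H0, update_w=False, max_iter=max_iter, tol=tol
        )
        if best is None or errors[-1] < best[1][-1]:
            best = (H, errors, its, conv, restart)
    H, errors, its, conv, restart = best
    act = ActivationSet(H=H, synergies=syn)
    return FactorizationResult(
        synergies=syn, activations=act, vaf_pct=vaf(V, syn.W, H),
        iterations=its, converged=conv, seed=restart, objective_history=errors,
    )
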