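"""Homeostatic gain controllers for the matching-pursuit competition.

During dictionary learning a few atoms can start winning the arg max far more
often than others, monopolize the Hebbian updates, and trap the dictionary in
an inhomogeneous state.  Homeostasis counteracts this by slowly adapting the
per-atom gain functions ``z_i`` used in the selection step so that, at
convergence, all atoms are selected with comparable probability
(the maximum-entropy target ``p0 = N0 / N``).

Five controllers are implemented:

``NONE``
    No gain adaptation (atom normalization alone, in the learning loop).
``OLS``
    SparseNet-style variance equalization: track the per-atom coefficient
    variance ``V_i`` by moving average and scale the gain by
    ``(V_i / σ_g²)**α``.
``EMP``
    Equalitarian MP: binary gate, silencing any atom whose activation
    probability exceeds ``p0·(1 + α_h)``.
``HAP``
    Activation-probability heuristic: ReLU slope ``γ_i = log p_i / log p0``
    (gain 1 at target, >1 for under-active atoms, →0 as ``p_i → 1``).
``HEH``
    Histogram-equalization homeostasis: each atom's gain function is its own
    coefficient CDF, tracked nonparametrically on a shared grid, so the
    competition compares quantiles and is equalized by construction.

All controllers expose the same scoring contract used by the coder: the
score is non-decreasing in the correlation value and zero for ``c ≤ 0``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coding import SparseCode, codes_to_dense

__all__ = [
    "Variant",
    "GainState",
    "init_gains",
    "update_gains",
    "update_none",
    "update_ols",
    "update_emp",
    "update_hap",
    "update_heh",
    "activation_threshold_report",
]


class Variant(str, enum.Enum):
    NONE = "none"
    OLS = "ols"
    EMP = "emp"
    HAP = "hap"
    HEH = "heh"


def _as_variant(variant) -> Variant:
    if isinstance(variant, Variant):
        return variant
    return Variant(str(variant).lower())


@dataclass
class GainState:
    """Per-atom homeostasis state and the gain functions it induces.

    For the multiplicative variants the gain function is the ReLU
    ``z_i(c) = γ_i · c · δ(c > 0)``; for HEH it is the tracked cumulative
    distribution ``z_i(c) = P_i(c)`` evaluated by right-continuous step
    lookup on a shared coefficient grid (0 for ``c ≤ 0``).
    """

    variant: Variant
    N: int
    n0: int
    p0: float
    eta_h: float = 0.01
    alpha_h: float = 0.02
    sigma_g2: float | None = None
    alpha_ols: float = 0.02
    p_floor: float = 1e-6
    gamma: np.ndarray = field(default=None)  # type: ignore[assignment]
    p: np.ndarray = field(default=None)  # type: ignore[assignment]
    V: np.ndarray = field(default=None)  # type: ignore[assignment]
    grid: np.ndarray = field(default=None)  # type: ignore[assignment]
    table: np.ndarray = field(default=None)  # type: ignore[assignment]

    # -- scoring contract -------------------------------------------------
    def scores(self, C: np.ndarray) -> np.ndarray:
        """Competition scores for an array of correlation values (…, N)."""
        C = np.asarray(C, dtype=float)
        if self.variant is Variant.HEH:
            idx = np.searchsorted(self.grid, C, side="right") - 1
            idx = np.clip(idx, 0, self.grid.size - 1)
            atom_ids = np.broadcast_to(np.arange(self.N), C.shape)
            out = self.table[atom_ids, idx]
            return np.where(C > 0, out, 0.0)
        return np.where(C > 0, self.gamma * C, 0.0)

    def score(self, i: int, c: float) -> float:
        """Score of a single (atom, correlation) pair."""
        row = np.zeros(self.N)
        row[i] = c
        return float(self.scores(row[None, :])[0, i])

    def activation_probabilities(self) -> np.ndarray:
        """Best available per-atom activation-probability estimate."""
        if self.variant is Variant.HEH:
            return 1.0 - self.table[:, 0]
        return self.p.copy()

    def copy(self) -> "GainState":
        out = GainState(
            variant=self.variant,
            N=self.N,
            n0=self.n0,
            p0=self.p0,
            eta_h=self.eta_h,
            alpha_h=self.alpha_h,
            sigma_g2=self.sigma_g2,
            alpha_ols=self.alpha_ols,
            p_floor=self.p_floor,
        )
        for name in ("gamma", "p", "V", "grid", "table"):
            v = getattr(self, name)
            setattr(out, name, None if v is None else v.copy())
        return out


#: number of bins of the shared HEH coefficient grid
HEH_GRID_BINS = 512
#: initial ceiling of the HEH grid, extended adaptively (see update_heh)
HEH_INITIAL_CMAX = 1.0
#: grid ceiling is kept at this multiple of the largest coefficient seen
HEH_CMAX_MARGIN = 1.5


def init_gains(
    variant,
    N: int,
    n0: int,
    eta_h: float = 0.01,
    alpha_h: float = 0.02,
    sigma_g2: float | None = None,
    alpha_ols: float = 0.02,
    p_floor: float = 1e-6,
    n_bins: int = HEH_GRID_BINS,
    c_max: float = HEH_INITIAL_CMAX,
) -> GainState:
    """Neutral initial state: identical gain functions for every atom.

    Multiplicative variants start at ``γ = 1`` (and ``p = p0``, ``V = σ_g²``)
    so the first batches are coded exactly as under NONE.  HEH rows start as
    the uniform-prior cumulative function with mass ``1 − N0/N`` at zero,
    rising linearly to 1 across the positive grid.
    """
    variant = _as_variant(variant)
    if not (1 <= n0 < N):
        raise ValueError("need 1 <= N0 < N")
    p0 = n0 / N
    state = GainState(
        variant=variant,
        N=N,
        n0=n0,
        p0=p0,
        eta_h=eta_h,
        alpha_h=alpha_h,
        sigma_g2=sigma_g2,
        alpha_ols=alpha_ols,
        p_floor=p_floor,
    )
    state.gamma = np.ones(N)
    state.p = np.full(N, p0)
    state.V = np.full(N, sigma_g2 if sigma_g2 is not None else 1.0)
    if variant is Variant.HEH:
        state.grid = np.linspace(0.0, c_max, n_bins + 1)
        row = (1.0 - p0) + p0 * state.grid / c_max
        state.table = np.tile(row, (N, 1))
    return state


def _dense(codes, N: int) -> np.ndarray:
    if isinstance(codes, np.ndarray):
        return codes
    return codes_to_dense(list(codes), N)


def _update_p(state: GainState, A: np.ndarray) -> None:
    freq = np.mean(A > 0, axis=0)
    state.p = (1.0 - state.eta_h) * state.p + state.eta_h * freq


def update_none(state: GainState, codes) -> GainState:
    """No-op controller: atom normalization alone regulates the competition."""
    _dense(codes, state.N)
    return state


def update_ols(state: GainState, codes) -> GainState:
    """Variance-equalizing gain update (SparseNet heuristic).

    ``V_i ← (1−η_h)·V_i + η_h·(1/K)Σ_k a²_{i,k}`` then
    ``γ_i ← γ_i·(V_i/σ_g²)**α``.  When ``σ_g²`` was left unset it is
    estimated as the atom-mean coefficient variance of the first batch seen.
    """
    A = _dense(codes, state.N)
    batch_var = np.mean(A**2, axis=0)
    state.V = (1.0 - state.eta_h) * state.V + state.eta_h * batch_var
    if state.sigma_g2 is None:
        state.sigma_g2 = float(np.mean(batch_var))
        state.V = np.full(state.N, state.sigma_g2)
    if state.sigma_g2 <= 0:
        raise ValueError("sigma_g2 must be positive")
    _update_p(state, A)
    state.gamma = state.gamma * (state.V / state.sigma_g2) ** state.alpha_ols
    return state


def update_emp(state: GainState, codes) -> GainState:
    """Binary gate: silence atoms more active than ``p0·(1+α_h)``."""
    A = _dense(codes, state.N)
    _update_p(state, A)
    state.gamma = (state.p < state.p0 * (1.0 + state.alpha_h)).astype(float)
    return state


def update_hap(state: GainState, codes) -> GainState:
    """ReLU-slope heuristic ``γ_i = log(p_i)/log(p0)``.

    The gain is 1 when the activation probability sits at the target ``p0``,
    boosts under-active atoms (>1) and vanishes as ``p_i → 1``; ``p_i`` is
    clamped to ``[p_floor, 1]`` before the log.
    """
    A = _dense(codes, state.N)
    _update_p(state, A)
    p = np.clip(state.p, state.p_floor, 1.0)
    state.gamma = np.log(p) / np.log(state.p0) + 0.0  # +0.0 avoids -0.0 at p=1
    return state


def _extend_grid(state: GainState, new_cmax: float) -> None:
    old_grid, old_table = state.grid, state.table
    state.grid = np.linspace(0.0, new_cmax, old_grid.size)
    # Linear-interpolation rebin; beyond the old ceiling rows keep their
    # terminal value (1 after any update, by construction).
    state.table = np.vstack(
        [np.interp(state.grid, old_grid, row) for row in old_table]
    )


def update_heh(state: GainState, codes) -> GainState:
    """Relax every atom's CDF row toward the batch coefficient indicators.

    Per sample ``k`` (in batch order) and atom ``i`` — including inactive
    atoms, whose coefficient is 0 — the row is relaxed toward the indicator
    step ``δ(a_{k,i} ≤ ·)`` at rate ``η_h``.  The K per-sample relaxations
    are applied in closed form (geometric weights), which is exactly
    equivalent and O(K·N + N·G).
    """
    A = _dense(codes, state.N)
    K = A.shape[0]
    if K == 0:
        return state
    amax = float(A.max(initial=0.0))
    if amax > state.grid[-1]:
        _extend_grid(state, HEH_CMAX_MARGIN * amax)
    eta = state.eta_h
    # weights of the K successive relaxations: last sample weighs most
    w = eta * (1.0 - eta) ** np.arange(K - 1, -1, -1)
    idx = np.searchsorted(state.grid, A, side="left")  # first grid point ≥ a
    G1 = state.grid.size
    W = np.zeros((state.N, G1))
    atom_ids = np.broadcast_to(np.arange(state.N), A.shape)
    np.add.at(
        W,
        (atom_ids.ravel(), idx.ravel()),
        np.broadcast_to(w[:, None], A.shape).ravel(),
    )
    state.table = (1.0 - eta) ** K * state.table + np.cumsum(W, axis=1)
    return state


_UPDATERS = {
    Variant.NONE: update_none,
    Variant.OLS: update_ols,
    Variant.EMP: update_emp,
    Variant.HAP: update_hap,
    Variant.HEH: update_heh,
}


def update_gains(state: GainState, codes) -> GainState:
    """Dispatch the per-variant update on a batch of codes."""
    return _UPDATERS[state.variant](state, codes)


def activation_threshold_report(state: GainState) -> pd.DataFrame:
    """Deterministic per-atom dump of (atom, p_i, γ_i) for diagnostics."""
    p = state.activation_probabilities()
    gamma = (
        np.ones(state.N) if state.variant is Variant.HEH else state.gamma.copy()
    )
    return pd.DataFrame({"atom": np.arange(state.N), "p": p, "gamma": gamma})
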