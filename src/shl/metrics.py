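"""Quantitative yardsticks for sparse coding and dictionary recovery.

The coding cost is the ℓ0 two-term objective

    F = ⟨ ½‖y_k − Φᵀa_k‖² + λ‖a_k‖₀ ⟩_k          (λ = log2 N by default)

optionally extended with μ·W, where W is the summed earth-mover's
(1-Wasserstein) distance between each atom's coefficient CDF and the
population-average CDF — zero exactly when all atoms share one coefficient
distribution, i.e. when the code is equalized.  With λ = log2 N the sparsity
term counts the bits needed to address the active atoms, which makes F an
upper bound on the information cost of the representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coding import Dictionary, SparseCode, codes_to_dense

__all__ = [
    "CostConfig",
    "CostRecord",
    "cost_F",
    "wasserstein_term",
    "activation_probabilities",
    "entropy",
    "recovery_score",
]


@dataclass
class CostConfig:
    """λ (bits per active coefficient; None → log2 N) and μ (weight of W)."""

    lambda_: float | None = None
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_ is not None and self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")

    def resolve_lambda(self, N: int) -> float:
        return float(np.log2(N)) if self.lambda_ is None else self.lambda_


@dataclass
class CostRecord:
    residual_term: float
    sparsity_term: float
    wasserstein: float
    total: float


def cost_F(
    batch, codes: list[SparseCode], dictionary: Dictionary, costcfg: CostConfig | None = None
) -> CostRecord:
    """Batch-mean ℓ0 coding cost, optionally with the equalization term."""
    costcfg = costcfg or CostConfig()
    Y = np.asarray(getattr(batch, "data", batch), dtype=float)
    A = codes_to_dense(codes, dictionary.N)
    if len(codes) != Y.shape[0]:
        raise ValueError("codes must align with batch")
    lam = costcfg.resolve_lambda(dictionary.N)
    resid = Y - A @ dictionary.atoms
    residual_term = 0.5 * float(np.mean(np.sum(resid**2, axis=1)))
    sparsity_term = lam * float(np.mean(np.count_nonzero(A, axis=1)))
    w = wasserstein_term(A) if costcfg.mu > 0 else 0.0
    total = residual_term + sparsity_term + costcfg.mu * w
    return CostRecord(residual_term, sparsity_term, w, total)


def _empirical_cdfs(A: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Per-atom CDFs P_i(g) = fraction of samples with a_{k,i} ≤ g."""
    K, N = A.shape
    idx = np.searchsorted(grid, A, side="left")
    counts = np.zeros((N, grid.size))
    atom_ids = np.broadcast_to(np.arange(N), A.shape)
    np.add.at(counts, (atom_ids.ravel(), np.minimum(idx, grid.size - 1).ravel()), 1.0)
    return np.cumsum(counts, axis=1) / K


def wasserstein_term(codes, N: int | None = None, grid: np.ndarray | None = None) -> float:
    """Σ_i ∫_{a≥0} |P_i(a) − P0(a)| da with P0 the atom-average CDF.

    ``codes`` is a dense (K, N) coefficient matrix or a list of sparse codes
    (then ``N`` is required).  CDFs are built over the nonnegative
    coefficient axis on ``grid`` (default: 512 quantile-spaced points over
    the observed positive values) and the integral is trapezoidal.
    """
    if isinstance(codes, np.ndarray):
        A = codes
    else:
        if N is None:
            raise ValueError("N required when codes is a list")
        A = codes_to_dense(list(codes), N)
    if grid is None:
        pos = A[A > 0]
        if pos.size == 0:
            return 0.0
        qs = np.quantile(pos, np.linspace(0.0, 1.0, 511))
        grid = np.unique(np.concatenate([[0.0], qs]))
    P = _empirical_cdfs(A, np.asarray(grid, dtype=float))
    P0 = P.mean(axis=0)
    return float(np.sum(np.trapezoid(np.abs(P - P0), grid, axis=1)))


def activation_probabilities(codes, N: int) -> np.ndarray:
    """Empirical fraction of samples in which each atom carries a_{i} > 0."""
    A = codes if isinstance(codes, np.ndarray) else codes_to_dense(list(codes), N)
    if A.shape[0] == 0:
        return np.zeros(N)
    return np.mean(A != 0, axis=0)


def entropy(p: np.ndarray) -> float:
    """Shannon entropy (bits) of the normalized selection distribution.

    ``p`` need not sum to one (activation probabilities do not); it is
    normalized first, and 0·log 0 := 0.
    """
    p = np.asarray(p, dtype=float)
    total = p.sum()
    if total <= 0:
        return 0.0
    q = p / total
    nz = q > 0
    return float(-np.sum(q[nz] * np.log2(q[nz])))


def recovery_score(learned: Dictionary, truth: Dictionary) -> float:
    """Mean over true atoms of the best absolute match among learned atoms.

    Both dictionaries have unit-norm rows, so the score lies in [0, 1], is
    invariant to atom permutation and sign, and equals 1 iff every true atom
    is exactly represented (up to sign) in the learned set.
    """
    C = np.abs(truth.atoms @ learned.atoms.T)
    return float(np.mean(C.max(axis=1)))
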