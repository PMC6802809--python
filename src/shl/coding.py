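"""Greedy sparse coding: generalized Matching Pursuit with gain modulation.

A patch ``y`` is approximated as ``Φᵀa`` with at most ``N0`` active atoms.
Matching Pursuit (MP) greedily selects, at each step, the atom whose current
correlation with the residual wins a competition.  The generalization here is
that the competition is scored through per-atom gain functions ``z_i`` (see
:mod:`shl.homeostasis`): the winner is ``argmax_i z_i(c_i)`` where ``c_i`` is
the running correlation, while the *coefficient* accumulated is always the
raw correlation value.  With all-neutral gains this reduces to one-sided MP;
a flag restores the classical symmetric ``|c|`` selection.

Residual bookkeeping is done in correlation space against the cached Gram
matrix (``c ← c − c_{i*}·G[i*]``), which is exact by linearity and avoids
touching the residual vector inside the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Dictionary",
    "SparseCode",
    "build_gram",
    "mp_encode",
    "omp_encode",
    "reconstruct",
    "encode_batch",
    "codes_to_dense",
    "mp_iteration_cap",
]


def mp_iteration_cap(n0: int) -> int:
    # Re-selection of an atom does not grow the distinct support, so the
    # greedy loop may need more than N0 steps; cap it to keep termination.
    return 4 * n0 + 16


@dataclass
class Dictionary:
    """N unit-norm atoms of length M, with the cached Gram matrix.

    ``atoms`` rows are the Φ_i; ``gram[i, j] = ⟨Φ_i, Φ_j⟩`` is symmetric with
    unit diagonal.  Build instances through :func:`build_gram`, which
    normalizes rows and computes the Gram matrix.
    """

    atoms: np.ndarray
    gram: np.ndarray
    patch_size: int | None = None

    @property
    def N(self) -> int:
        return self.atoms.shape[0]

    @property
    def M(self) -> int:
        return self.atoms.shape[1]


@dataclass
class SparseCode:
    """Sparse coefficient vector: parallel (indices, values) plus metadata."""

    indices: np.ndarray
    values: np.ndarray
    N: int
    n0: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.indices.size != self.values.size:
            raise ValueError("indices and values must be parallel")
        if self.indices.size and (
            self.indices.min() < 0 or self.indices.max() >= self.N
        ):
            raise ValueError("atom index out of range")

    @property
    def nnz(self) -> int:
        return int(np.count_nonzero(self.values))

    def dense(self) -> np.ndarray:
        out = np.zeros(self.N)
        out[self.indices] = self.values
        return out


def build_gram(atoms: np.ndarray, patch_size: int | None = None) -> Dictionary:
    """Normalize atom rows to unit norm and cache their Gram matrix."""
    atoms = np.array(atoms, dtype=float)
    norms = np.linalg.norm(atoms, axis=1)
    bad = np.where(norms == 0)[0]
    if bad.size:
        raise ValueError(f"zero-norm atom row(s): {bad.tolist()}")
    atoms /= norms[:, None]
    return Dictionary(atoms=atoms, gram=atoms @ atoms.T, patch_size=patch_size)


class _NeutralGains:
    """Identity ReLU gains: score(i, c) = max(c, 0)."""

    def scores(self, C: np.ndarray) -> np.ndarray:
        return np.maximum(C, 0.0)

    def score(self, i: int, c: float) -> float:
        return max(float(c), 0.0)


class _SymmetricGains:
    """Classical MP selection on the absolute correlation."""

    def scores(self, C: np.ndarray) -> np.ndarray:
        return np.abs(C)

    def score(self, i: int, c: float) -> float:
        return abs(float(c))


NEUTRAL_GAINS = _NeutralGains()


def _resolve_gains(gains, symmetric: bool):
    if symmetric:
        return _SymmetricGains()
    return NEUTRAL_GAINS if gains is None else gains


def mp_encode(
    y: np.ndarray,
    dictionary: Dictionary,
    gains=None,
    n0: int = 10,
    symmetric: bool = False,
) -> SparseCode:
    """Encode one sample with gain-modulated Matching Pursuit.

    The loop runs while the distinct support is smaller than ``n0``; ties in
    the arg max break to the lowest atom index, and the loop stops early when
    every competition score is ≤ 0 (one-sided gains can exhaust positive
    matches).  With symmetric selection the stop applies at score 0.
    """
    Y = np.asarray(y, dtype=float)[None, :]
    record: list[list[tuple[int, float]]] = [[]]
    A = _mp_encode_dense(Y, dictionary, gains, n0, symmetric, record=record)
    nz = np.nonzero(A[0])[0]
    code = SparseCode(indices=nz, values=A[0, nz], N=dictionary.N, n0=n0)
    # per greedy step: selected atom and the correlation value accumulated
    code.selection_sequence = [i for i, _ in record[0]]
    code.selection_values = [v for _, v in record[0]]
    return code


def _mp_encode_dense(
    Y: np.ndarray,
    dictionary: Dictionary,
    gains,
    n0: int,
    symmetric: bool,
    record: list[list[int]] | None = None,
) -> np.ndarray:
    """Vectorized batch MP; returns dense (K, N) coefficients."""
    g = _resolve_gains(gains, symmetric)
    C = Y @ dictionary.atoms.T
    if not np.all(np.isfinite(C)):
        raise ValueError("non-finite correlations in MP input")
    K, N = C.shape
    A = np.zeros((K, N))
    alive = np.ones(K, dtype=bool)
    for _ in range(mp_iteration_cap(n0)):
        idx = np.where(alive)[0]
        if idx.size == 0:
            break
        S = g.scores(C[idx])
        best = np.argmax(S, axis=1)  # first max → lowest-index tie-break
        pos = S[np.arange(idx.size), best] > 0
        stopped = idx[~pos]
        alive[stopped] = False
        idx, best = idx[pos], best[pos]
        if idx.size == 0:
            break
        v = C[idx, best]
        if record is not None:
            for k, i, val in zip(idx, best, v):
                record[k].append((int(i), float(val)))
        A[idx, best] += v
        C[idx] -= v[:, None] * dictionary.gram[best]
        alive[idx] = np.count_nonzero(A[idx], axis=1) < n0
    return A


def omp_encode(
    y: np.ndarray, dictionary: Dictionary, gains=None, n0: int = 10
) -> SparseCode:
    """Orthogonal MP: gain-modulated selection, least-squares coefficient refit.

    After each selection the coefficients on the active support are refit by
    least squares, so the residual is orthogonal to the span of the selected
    atoms.  A rank-deficient support matrix drops the newest atom and stops.
    """
    y = np.asarray(y, dtype=float)
    g = _resolve_gains(gains, symmetric=False)
    atoms = dictionary.atoms
    support: list[int] = []
    coef = np.zeros(0)
    r = y.copy()
    while len(support) < n0:
        c = atoms @ r
        s = g.scores(c[None, :])[0]
        s[support] = 0.0  # an already-active atom has zero residual correlation
        i = int(np.argmax(s))
        if s[i] <= 0:
            break
        support.append(i)
        Phi = atoms[support].T  # (M, |support|)
        sol, _, rank, _ = np.linalg.lstsq(Phi, y, rcond=None)
        if rank < len(support):
            support.pop()
            break
        coef = sol
        r = y - Phi @ coef
    return SparseCode(
        indices=np.array(support, dtype=int),
        values=np.asarray(coef)[: len(support)],
        N=dictionary.N,
        n0=n0,
    )


def reconstruct(code: SparseCode, dictionary: Dictionary) -> np.ndarray:
    """Noiseless synthesis Φᵀa for one sparse code."""
    if code.indices.size == 0:
        return np.zeros(dictionary.M)
    return dictionary.atoms[code.indices].T @ code.values


def encode_batch(
    batch,
    dictionary: Dictionary,
    gains=None,
    n0: int = 10,
    coder: str = "mp",
    symmetric: bool = False,
) -> list[SparseCode]:
    """Encode every sample of a batch independently; order preserving.

    ``batch`` may be a :class:`~shl.images.PatchBatch` or a (K, M) array.
    """
    Y = np.asarray(getattr(batch, "data", batch), dtype=float)
    if Y.ndim != 2 or Y.shape[1] != dictionary.M:
        raise ValueError("batch must be (K, M) with M matching the dictionary")
    if coder == "mp":
        A = _mp_encode_dense(Y, dictionary, gains, n0, symmetric)
        codes = []
        for k in range(A.shape[0]):
            nz = np.nonzero(A[k])[0]
            codes.append(
                SparseCode(indices=nz, values=A[k, nz], N=dictionary.N, n0=n0)
            )
        return codes
    if coder == "omp":
        codes = []
        for k, y in enumerate(Y):
            try:
                codes.append(omp_encode(y, dictionary, gains, n0))
            except Exception as exc:
                raise RuntimeError(f"encoding failed for sample {k}") from exc
        return codes
    raise ValueError(f"unknown coder {coder!r}")


def codes_to_dense(codes: list[SparseCode], N: int) -> np.ndarray:
    """Stack sparse codes as a dense (K, N) coefficient matrix."""
    A = np.zeros((len(codes), N))
    for k, code in enumerate(codes):
        A[k, code.indices] = code.values
    return A
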