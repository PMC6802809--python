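"""Sparse Hebbian Learning: the outer alternation of coding and learning.

Each epoch draws a batch of masked patches, codes it with the current
dictionary and gains, applies the Hebbian dictionary update

    Φ_i ← Φ_i + η · Σ_k a_{k,i} (y_k − Φᵀa_k),     then ‖Φ_i‖ = 1,

and lets the homeostasis controller adapt the gains from the batch codes.
The update is the negative gradient of the reconstruction term of the coding
cost with respect to Φ, restricted to active coefficients — a linear Hebbian
rule (inactive coefficients learn nothing).  Residuals are computed once per
batch against the epoch-start dictionary, the per-sample updates summed, and
normalization applied once, which keeps the rule per-sample in substance but
batch-applied for stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .coding import Dictionary, SparseCode, build_gram, codes_to_dense, encode_batch
from .homeostasis import GainState, Variant, init_gains, update_gains
from .images import ImageSet, PatchBatch, circular_mask, extract_patches
from .metrics import CostConfig, activation_probabilities, cost_F, entropy, wasserstein_term

__all__ = [
    "LearnConfig",
    "LearnTrace",
    "init_dictionary",
    "hebbian_update",
    "schedule_eta",
    "fit",
]


@dataclass
class LearnConfig:
    """Settings of one Sparse Hebbian Learning run.

    The defaults reproduce the full-scale configuration (N=676 atoms on
    21×21 patches, N0=21, K=256, 4096 epochs); experiments and tests run
    scaled-down instances.
    """

    N: int = 676
    n0: int = 21
    patch_size: int = 21
    K: int = 256
    epochs: int = 4096
    eta: float = 0.05
    eta_homeo: float = 0.01
    variant: Variant | str = Variant.NONE
    coder: str = "mp"
    scheduler: str = "inverse-time"
    tau: float | None = None  # inverse-time constant; None → epochs / 4
    seed: int = 0
    pool_size: int = 4096
    heldout_K: int | None = None  # None → K
    checkpoint_every: int = 64
    alpha_h: float = 0.02
    sigma_g2: float | None = None
    alpha_ols: float = 0.02
    p_floor: float = 1e-6

    def __post_init__(self) -> None:
        if not (1 <= self.n0 < self.N):
            raise ValueError("need 1 <= N0 < N")
        for name in ("K", "epochs", "eta", "eta_homeo", "patch_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class LearnTrace:
    """Per-epoch record of the held-out cost and activation statistics."""

    epoch: list[int] = field(default_factory=list)
    cost_F: list[float] = field(default_factory=list)
    wasserstein_W: list[float] = field(default_factory=list)
    entropy_bits: list[float] = field(default_factory=list)
    eta_t: list[float] = field(default_factory=list)
    activation_probability: list[np.ndarray] = field(default_factory=list)

    def append(self, epoch, cost, w, ent, eta_t, p) -> None:
        self.epoch.append(int(epoch))
        self.cost_F.append(float(cost))
        self.wasserstein_W.append(float(w))
        self.entropy_bits.append(float(ent))
        self.eta_t.append(float(eta_t))
        self.activation_probability.append(np.asarray(p))

    def __len__(self) -> int:
        return len(self.epoch)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": self.epoch,
                "cost_F": self.cost_F,
                "wasserstein_W": self.wasserstein_W,
                "entropy_bits": self.entropy_bits,
                "eta_t": self.eta_t,
            }
        )


def init_dictionary(
    N: int, M: int, seed: int = 0, mask: np.ndarray | None = None
) -> Dictionary:
    """Random unit-norm atoms on the (masked) M-sphere, deterministic per seed.

    When ``M`` is a perfect square the circular patch mask is applied by
    default (pass ``mask=np.ones(M, bool)`` to disable); atoms are iid
    standard normal on the support, then unit-normalized.
    """
    if N < 1 or M < 1:
        raise ValueError("N and M must be >= 1")
    if mask is None:
        s = int(round(np.sqrt(M)))
        mask = circular_mask(s) if s * s == M else np.ones(M, dtype=bool)
    rng = np.random.default_rng(seed)
    atoms = rng.standard_normal((N, M))
    atoms[:, ~mask] = 0.0
    s = int(round(np.sqrt(M)))
    return build_gram(atoms, patch_size=s if s * s == M else None)


def hebbian_update(
    dictionary: Dictionary, batch, codes: list[SparseCode], eta: float
) -> Dictionary:
    """One batch of the Hebbian rule, followed by row normalization.

    Residuals are taken against the pre-update dictionary for every sample,
    the coefficient-weighted residual outer products summed, then rows are
    renormalized and the Gram matrix rebuilt.  All-zero codes leave the
    dictionary unchanged.
    """
    Y = np.asarray(getattr(batch, "data", batch), dtype=float)
    if len(codes) != Y.shape[0]:
        raise ValueError("codes must align with batch")
    A = codes_to_dense(codes, dictionary.N)
    with np.errstate(invalid="ignore", over="ignore"):  # checked just below
        R = Y - A @ dictionary.atoms
        delta = A.T @ R
    if not np.all(np.isfinite(delta)):
        bad = np.where(~np.isfinite(delta).all(axis=1))[0]
        raise FloatingPointError(f"non-finite Hebbian update for atom(s) {bad.tolist()}")
    atoms = dictionary.atoms.copy()
    changed = np.any(delta != 0.0, axis=1)  # untouched rows stay bit-identical
    atoms[changed] += eta * delta[changed]
    norms = np.linalg.norm(atoms[changed], axis=1)
    if np.any(norms == 0):
        raise FloatingPointError("atom norm collapsed to zero during update")
    atoms[changed] /= norms[:, None]
    return Dictionary(
        atoms=atoms, gram=atoms @ atoms.T, patch_size=dictionary.patch_size
    )


def schedule_eta(t: int, config: LearnConfig) -> float:
    """Learning rate at epoch ``t``: constant, or inverse-time η·τ/(τ+t)."""
    if config.scheduler == "constant":
        return config.eta
    if config.scheduler == "inverse-time":
        tau = config.tau if config.tau is not None else max(config.epochs / 4.0, 1.0)
        return config.eta * tau / (tau + t)
    raise ValueError(f"unknown scheduler {config.scheduler!r}")


def _patch_pool(source, config: LearnConfig) -> np.ndarray:
    if isinstance(source, ImageSet):
        pool = extract_patches(
            source,
            patch_size=config.patch_size,
            K=config.pool_size,
            seed=config.seed + 1_000_003,
        )
        return pool.data
    if isinstance(source, PatchBatch):
        return source.data
    data = np.asarray(source, dtype=float)
    if data.ndim != 2:
        raise TypeError("source must be ImageSet, PatchBatch or (K, M) array")
    return data


def fit(
    source,
    config: LearnConfig,
    run_dir: str | Path | None = None,
) -> tuple[Dictionary, GainState, LearnTrace]:
    """Run Sparse Hebbian Learning for ``config.epochs`` epochs.

    ``source`` is an :class:`ImageSet` (patches are pooled once, then batches
    are drawn from the pool), a :class:`PatchBatch`, or a raw (K, M) array.
    The held-out evaluation batch is drawn up front and kept fixed; held-out
    codes are computed with *neutral* gains so the recorded cost compares
    dictionaries rather than coders.  Fully reproducible per seed.  When
    ``run_dir`` is given, the config, trace CSV and periodic HDF5 snapshots
    are written there.
    """
    config = replace(config, variant=Variant(config.variant))
    pool = _patch_pool(source, config)
    M = pool.shape[1]
    rng = np.random.default_rng(config.seed)
    heldout_K = config.heldout_K or config.K
    heldout = pool[rng.integers(0, pool.shape[0], heldout_K)]
    dictionary = init_dictionary(config.N, M, seed=config.seed)
    gains = init_gains(
        config.variant,
        config.N,
        config.n0,
        eta_h=config.eta_homeo,
        alpha_h=config.alpha_h,
        sigma_g2=config.sigma_g2,
        alpha_ols=config.alpha_ols,
        p_floor=config.p_floor,
    )
    trace = LearnTrace()
    costcfg = CostConfig()
    run_path = Path(run_dir) if run_dir is not None else None
    if run_path is not None:
        run_path.mkdir(parents=True, exist_ok=True)
        _write_config(run_path / "config.yaml", config)
    try:
        for t in range(config.epochs):
            batch = pool[rng.integers(0, pool.shape[0], config.K)]
            codes = encode_batch(batch, dictionary, gains, config.n0, coder=config.coder)
            eta_t = schedule_eta(t, config)
            dictionary = hebbian_update(dictionary, batch, codes, eta_t)
            gains = update_gains(gains, codes)
            held_codes = encode_batch(heldout, dictionary, None, config.n0)
            rec = cost_F(heldout, held_codes, dictionary, costcfg)
            A_h = codes_to_dense(held_codes, config.N)
            p = activation_probabilities(A_h, config.N)
            trace.append(t, rec.total, wasserstein_term(A_h), entropy(p), eta_t, p)
            if run_path is not None and (
                (t + 1) % config.checkpoint_every == 0 or t + 1 == config.epochs
            ):
                _snapshot(run_path, t, dictionary, gains)
    finally:
        if run_path is not None:
            trace.to_dataframe().to_csv(run_path / "trace.csv", index=False)
    return dictionary, gains, trace


def _write_config(path: Path, config: LearnConfig) -> None:
    import yaml

    d = {k: (v.value if isinstance(v, Variant) else v) for k, v in vars(config).items()}
    path.write_text(yaml.safe_dump(d, sort_keys=True))


def _snapshot(run_path: Path, epoch: int, dictionary: Dictionary, gains: GainState) -> None:
    from .io import save_dictionary, save_gain_state

    snap = run_path / "snapshots"
    snap.mkdir(exist_ok=True)
    save_dictionary(snap / f"dictionary_{epoch + 1:05d}.h5", dictionary)
    save_gain_state(snap / f"gains_{epoch + 1:05d}.h5", gains)
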