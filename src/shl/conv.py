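"""Single-layer convolutional sparse coding with homeostatic gain control.

The patch dictionary is replaced by a small bank of translation-invariant
kernels: an image is coded as a list of events (kernel, row, col, value),
selected greedily by convolutional matching pursuit.  Correlations are
computed in valid mode (no padding) and updated incrementally after each
event through precomputed kernel cross-correlations, which is exact and
keeps the coder translation-equivariant away from borders.

Homeostasis acts per kernel: under HAP the per-kernel share of the event
budget is tracked by moving average and the selection gain set to
``log(p_k)/log(1/n_kernels)``, so under-used kernels win ties until the
activation counts converge; under NONE only kernel normalization operates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import correlate2d

from .homeostasis import GainState, Variant, init_gains
from .images import ImageSet

__all__ = ["KernelBank", "EventCode", "ConvConfig", "conv_mp_encode", "conv_fit"]


@dataclass
class KernelBank:
    """n_k square kernels, each of unit Frobenius norm."""

    kernels: np.ndarray  # (n_k, s, s)

    def __post_init__(self) -> None:
        if self.kernels.ndim != 3 or self.kernels.shape[1] != self.kernels.shape[2]:
            raise ValueError("kernels must be (n_k, s, s)")

    @property
    def n_k(self) -> int:
        return self.kernels.shape[0]

    @property
    def size(self) -> int:
        return self.kernels.shape[1]

    @classmethod
    def random(cls, n_k: int, size: int, seed: int = 0) -> "KernelBank":
        rng = np.random.default_rng(seed)
        k = rng.standard_normal((n_k, size, size))
        return cls(_normalize(k))


def _normalize(kernels: np.ndarray) -> np.ndarray:
    norms = np.sqrt(np.sum(kernels**2, axis=(1, 2), keepdims=True))
    if np.any(norms == 0):
        raise ValueError("zero-norm kernel")
    return kernels / norms


@dataclass
class EventCode:
    """Sparse event list for one image; at most the budget of events."""

    kernel: np.ndarray
    row: np.ndarray
    col: np.ndarray
    value: np.ndarray

    def __len__(self) -> int:
        return self.kernel.size

    def render(self, shape: tuple[int, int], bank: KernelBank) -> np.ndarray:
        """Paste value-scaled kernels at event positions (the reconstruction)."""
        out = np.zeros(shape)
        s = bank.size
        for k, r, c, v in zip(self.kernel, self.row, self.col, self.value):
            out[r : r + s, c : c + s] += v * bank.kernels[k]
        return out


@dataclass
class ConvConfig:
    """Settings of the convolutional learning demo."""

    n_k: int = 20
    kernel_size: int = 9
    n0_events: int = 30
    eta: float = 0.02
    eta_homeo: float = 0.05
    variant: Variant | str = Variant.HAP
    epochs: int = 200
    seed: int = 0
    p_floor: float = 1e-6


def _cross_tables(bank: KernelBank) -> np.ndarray:
    """XC[j, k, dr+s-1, dc+s-1] = Σ_u K_j(u) K_k(u + d)."""
    n_k, s = bank.n_k, bank.size
    xc = np.empty((n_k, n_k, 2 * s - 1, 2 * s - 1))
    for j in range(n_k):
        for k in range(n_k):
            # correlate2d(a, b)[d] = Σ_u a(u) b(u - d) with 'full' offset s-1,
            # so flipping the axes gives Σ_u K_j(u) K_k(u + d).
            xc[j, k] = correlate2d(bank.kernels[j], bank.kernels[k], mode="full")[
                ::-1, ::-1
            ]
    return xc


def conv_mp_encode(
    image: np.ndarray,
    bank: KernelBank,
    gains: GainState | None = None,
    n0_events: int = 30,
) -> EventCode:
    """Greedy convolutional MP: up to ``n0_events`` positive-score events.

    Each step selects the (kernel, position) pair maximizing the gain-scored
    valid-mode correlation with the residual (ties break to the lowest
    kernel, then row-major position), records the raw correlation as the
    event value, and subtracts the scaled kernel from the residual.
    """
    image = np.asarray(image, dtype=float)
    s = bank.size
    if image.shape[0] < s or image.shape[1] < s:
        raise ValueError("image smaller than kernel")
    gamma = np.ones(bank.n_k) if gains is None else gains.gamma
    C = np.stack(
        [correlate2d(image, k, mode="valid") for k in bank.kernels]
    )  # (n_k, H', W')
    xc = _cross_tables(bank)
    Hv, Wv = C.shape[1:]
    ks, rs, cs, vs = [], [], [], []
    for _ in range(n0_events):
        S = np.where(C > 0, gamma[:, None, None] * C, 0.0)
        flat = int(np.argmax(S))
        k, r, c = np.unravel_index(flat, S.shape)
        if S[k, r, c] <= 0:
            break
        v = C[k, r, c]
        ks.append(int(k))
        rs.append(int(r))
        cs.append(int(c))
        vs.append(float(v))
        # incremental correlation update within the affected window
        r0, r1 = max(0, r - (s - 1)), min(Hv, r + s)
        c0, c1 = max(0, c - (s - 1)), min(Wv, c + s)
        dr0, dc0 = r0 - r + (s - 1), c0 - c + (s - 1)
        C[:, r0:r1, c0:c1] -= (
            v * xc[:, k, dr0 : dr0 + (r1 - r0), dc0 : dc0 + (c1 - c0)]
        )
    return EventCode(
        kernel=np.array(ks, dtype=int),
        row=np.array(rs, dtype=int),
        col=np.array(cs, dtype=int),
        value=np.array(vs),
    )


def conv_fit(
    imageset: ImageSet, config: ConvConfig
) -> tuple[KernelBank, GainState, np.ndarray]:
    """Convolutional SHL: one image per epoch, HAP (or no) homeostasis.

    Kernel updates accumulate value-weighted patches of the final residual at
    event positions, then renormalize.  HAP tracks each kernel's share of the
    emitted events against the uniform target 1/n_k.  Returns the learned
    bank, the gain state, and the (epochs, n_k) history of the tracked
    per-kernel activation probabilities.
    """
    variant = Variant(config.variant)
    if variant not in (Variant.NONE, Variant.HAP):
        raise ValueError("convolutional learning supports NONE and HAP only")
    rng = np.random.default_rng(config.seed)
    bank = KernelBank.random(config.n_k, config.kernel_size, seed=config.seed)
    # per-kernel homeostasis over event shares: target p0 = 1/n_k
    gains = init_gains(
        Variant.HAP, N=config.n_k, n0=1, eta_h=config.eta_homeo, p_floor=config.p_floor
    )
    gains.variant = variant
    history = np.empty((config.epochs, config.n_k))
    for t in range(config.epochs):
        image = imageset.images[int(rng.integers(len(imageset.images)))]
        events = conv_mp_encode(image, bank, gains, config.n0_events)
        if len(events):
            residual = image - events.render(image.shape, bank)
            delta = np.zeros_like(bank.kernels)
            s = bank.size
            for k, r, c, v in zip(events.kernel, events.row, events.col, events.value):
                delta[k] += v * residual[r : r + s, c : c + s]
            bank = KernelBank(_normalize(bank.kernels + config.eta * delta))
            share = np.bincount(events.kernel, minlength=config.n_k) / len(events)
        else:
            share = np.zeros(config.n_k)
        gains.p = (1 - config.eta_homeo) * gains.p + config.eta_homeo * share
        if variant is Variant.HAP:
            p = np.clip(gains.p, config.p_floor, 1.0)
            gains.gamma = np.log(p) / np.log(gains.p0)
        history[t] = gains.p
    return bank, gains, history
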