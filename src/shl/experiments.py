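"""Desk-scale comparison experiments between homeostasis strategies.

The default benchmark learns N=144 atoms on 13×13 patches (N0=10, K=128,
256 epochs) from the synthetic natural-scene generator — small enough to run
in minutes on one CPU while preserving the qualitative structure of the
full-scale runs (N=676, 21×21, 4096 epochs), which ship as
:func:`full_scale_config` and are flagged long-running.

All comparisons pair seeds across variants: run ``r`` of every variant uses
the same data pool, the same dictionary initialization and the same batch
sequence, so differences are attributable to the homeostasis rule alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .homeostasis import Variant
from .images import ImageSet, SyntheticParams, synthesize_images
from .learning import LearnConfig, fit, init_dictionary
from .metrics import recovery_score
from .conv import ConvConfig, conv_fit

__all__ = [
    "ExperimentSpec",
    "desk_scale_config",
    "full_scale_config",
    "benchmark_images",
    "run_compare",
    "run_sweep",
    "run_recovery",
    "run_conv_demo",
    "dump_gain_functions",
]

DEFAULT_VARIANTS = ("none", "ols", "emp", "hap", "heh")


@dataclass
class ExperimentSpec:
    """What to run: variants, paired runs per cell, sweep axes, output dir."""

    experiment: str = "compare_variants"
    variants: tuple[str, ...] = DEFAULT_VARIANTS
    runs: int = 10
    sweep_axes: tuple[str, ...] = ("eta", "eta_homeo")
    octaves: float = 4.0
    points_per_axis: int = 5
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


def desk_scale_config(**overrides) -> LearnConfig:
    """The default desk-scale benchmark configuration."""
    base = dict(
        N=144, n0=10, patch_size=13, K=128, epochs=256, eta=0.05, eta_homeo=0.01,
        pool_size=4096,
    )
    base.update(overrides)
    return LearnConfig(**base)


def full_scale_config(**overrides) -> LearnConfig:
    """Full-scale configuration (N=676, 21×21, 4096 epochs). Long-running."""
    base = dict(N=676, n0=21, patch_size=21, K=256, epochs=4096)
    base.update(overrides)
    return LearnConfig(**base)


def benchmark_images(seed: int = 0, **overrides) -> ImageSet:
    """The shared synthetic natural-scene benchmark."""
    params = SyntheticParams(seed=seed, **overrides)
    return synthesize_images(params)


def run_compare(
    spec: ExperimentSpec, config: LearnConfig | None = None
) -> pd.DataFrame:
    """Fit every variant × run with paired seeds; summarize final cost/entropy.

    Per run, all variants share the seed (hence pool, init and batches).
    Emits one trace CSV per cell plus a summary CSV when ``out_dir`` is set.
    A failed run is recorded with NaNs rather than aborting the table.
    """
    config = config or desk_scale_config()
    images = benchmark_images(seed=spec.seed)
    out = Path(spec.out_dir) if spec.out_dir else None
    rows = []
    for r in range(spec.runs):
        seed = spec.seed + r
        for variant in spec.variants:
            cfg = replace(config, variant=Variant(variant), seed=seed)
            try:
                _, _, trace = fit(images, cfg)
                df = trace.to_dataframe()
                rows.append(
                    dict(
                        variant=variant,
                        run=r,
                        seed=seed,
                        final_cost=df.cost_F.iloc[-1],
                        final_entropy=df.entropy_bits.iloc[-1],
                        final_W=df.wasserstein_W.iloc[-1],
                    )
                )
                if out is not None:
                    out.mkdir(parents=True, exist_ok=True)
                    df.to_csv(out / f"trace_{variant}_run{r}.csv", index=False)
            except Exception as exc:  # record, do not abort the comparison
                rows.append(
                    dict(
                        variant=variant, run=r, seed=seed,
                        final_cost=np.nan, final_entropy=np.nan, final_W=np.nan,
                        error=str(exc),
                    )
                )
    summary = pd.DataFrame(rows)
    if out is not None:
        summary.to_csv(out / "summary.csv", index=False)
    return summary


def run_sweep(
    spec: ExperimentSpec, config: LearnConfig | None = None
) -> pd.DataFrame:
    """Grid of final costs over (η, η_h), log-spaced ±octaves/2 around defaults."""
    config = config or desk_scale_config()
    images = benchmark_images(seed=spec.seed)
    half = spec.octaves / 2.0
    factors = 2.0 ** np.linspace(-half, half, spec.points_per_axis)
    etas = config.eta * factors if "eta" in spec.sweep_axes else [config.eta]
    etahs = (
        config.eta_homeo * factors if "eta_homeo" in spec.sweep_axes else [config.eta_homeo]
    )
    rows = []
    for variant in spec.variants:
        for eta in etas:
            for etah in etahs:
                cfg = replace(
                    config, variant=Variant(variant), eta=float(eta),
                    eta_homeo=float(etah), seed=spec.seed,
                )
                _, _, trace = fit(images, cfg)
                rows.append(
                    dict(
                        variant=variant, eta=float(eta), eta_homeo=float(etah),
                        final_cost=trace.cost_F[-1],
                    )
                )
    df = pd.DataFrame(rows)
    if spec.out_dir:
        out = Path(spec.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "sweep.csv", index=False)
    return df


def make_sparse_patches(
    truth, n0: int, K: int, rng: np.random.Generator
) -> np.ndarray:
    """K patches synthesized as N0-sparse positive combinations of true atoms."""
    N, M = truth.atoms.shape
    Y = np.zeros((K, M))
    for k in range(K):
        idx = rng.choice(N, size=n0, replace=False)
        coef = rng.uniform(0.5, 1.5, size=n0)
        Y[k] = coef @ truth.atoms[idx]
    return Y


def run_recovery(
    seed: int = 0,
    variants: tuple[str, ...] = ("hap", "none"),
    N: int = 36,
    M: int = 81,
    n0: int = 3,
    K: int = 128,
    epochs: int = 500,
    pool_size: int = 4096,
    eta: float = 0.1,
) -> dict[str, float]:
    """Ground-truth dictionary recovery with paired seeds across variants.

    Patches are exact ``n0``-sparse positive combinations of N random
    unit-norm atoms; the score is the mean best |correlation| between true
    and learned atoms (1 = perfect recovery).
    """
    rng = np.random.default_rng(seed)
    truth = init_dictionary(N, M, seed=rng.integers(2**31))
    pool = make_sparse_patches(truth, n0, pool_size, rng)
    scores: dict[str, float] = {}
    for variant in variants:
        cfg = LearnConfig(
            N=N, n0=n0, patch_size=int(round(np.sqrt(M))), K=K, epochs=epochs,
            eta=eta, eta_homeo=0.05, variant=Variant(variant), seed=seed,
        )
        learned, _, _ = fit(pool, cfg)
        scores[variant] = recovery_score(learned, truth)
    return scores


def run_conv_demo(
    seed: int = 0,
    variants: tuple[str, ...] = ("hap", "none"),
    config: ConvConfig | None = None,
    image_params: SyntheticParams | None = None,
) -> dict[str, dict]:
    """Paired convolutional runs; reports per-kernel activation spread."""
    config = config or ConvConfig(n_k=8, kernel_size=5, n0_events=24, epochs=200)
    params = image_params or SyntheticParams(
        n_images=8, image_size=32, spectral_exponent=0.5, n_edges=6,
        edge_contrast=3.0, noise_std=0.02, seed=seed,
    )
    images = synthesize_images(params)
    out = {}
    for variant in variants:
        cfg = replace(config, variant=Variant(variant), seed=seed)
        bank, gains, history = conv_fit(images, cfg)
        out[variant] = dict(
            bank=bank,
            p=gains.p.copy(),
            p_std=float(np.std(gains.p)),
            history=history,
        )
    return out


def dump_gain_functions(run_dir: str | Path, out_csv: str | Path | None = None) -> pd.DataFrame:
    """Per-atom gain-function table from the final checkpoint of a run.

    For HEH the cumulative rows over the coefficient grid are dumped (one
    column per atom); for the ReLU variants the (atom, p, gamma) report.
    """
    from .io import load_gain_state
    from .homeostasis import activation_threshold_report

    run_dir = Path(run_dir)
    snaps = sorted((run_dir / "snapshots").glob("gains_*.h5"))
    if not snaps:
        raise FileNotFoundError(f"no gain snapshots under {run_dir}")
    state = load_gain_state(snaps[-1])
    if state.variant is Variant.HEH:
        df = pd.DataFrame(
            state.table.T, columns=[f"z_{i}" for i in range(state.N)]
        )
        df.insert(0, "coefficient", state.grid)
    else:
        df = activation_threshold_report(state)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
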