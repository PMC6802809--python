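# Methods

## Model

A grayscale patch `y ∈ R^M` (default 21×21 → M = 441, circularly masked) is
modelled as a sparse linear combination of `N` unit-norm atoms,

    y = Φᵀ a + ε,        ‖a‖₀ ≤ N0,   ε ~ N(0, σ²I),

with `Φ ∈ R^{N×M}` the dictionary.  The coding objective is the ℓ0 two-term
cost

    F = ⟨ ½‖y_k − Φᵀa_k‖² + λ‖a_k‖₀ ⟩_k,       λ = log2 N,

so each active coefficient is charged the bits needed to address it.  An
optional third term `μ·W(a)` penalizes inhomogeneity, where `W` is the summed
1-Wasserstein (earth-mover's) distance between each atom's coefficient CDF
`P_i` and the population average `P0 = (1/N)Σ_i P_i`:

    W(a) = Σ_i ∫_{a≥0} |P_i(a) − P0(a)| da.

`W = 0` exactly when all atoms share one coefficient distribution, i.e. when
the code is equalized.  Because `μ` has no canonical value, the recorded cost
curves use `μ = 0` and `W` is reported alongside as its own trace column.

## Coding

Generalized Matching Pursuit: initialize correlations `c_i = ⟨y, Φ_i⟩`, then
repeatedly select `i* = argmax_i z_i(c_i)`, accumulate the *raw* correlation
`a_{i*} += c_{i*}`, and update all correlations through the cached Gram row,
`c ← c − c_{i*}·G[i*]` (exact by linearity).  The gain functions `z_i` only
affect the selection, never the stored coefficient or the learning step.
Choices the greedy loop needs that the objective does not fix:

- ties in the arg max break to the lowest atom index (determinism);
- scores are one-sided (`z_i(c) = 0` for `c ≤ 0`); the classical symmetric
  `|c|` selection is available behind a flag;
- the loop stops early when every score is ≤ 0 — one-sided selection can
  exhaust positive matches before filling `N0`, and padding with
  non-matching atoms would only raise the cost;
- an atom may be re-selected (its coefficient accumulates); `‖a‖₀` counts
  distinct atoms, and the loop is capped at `4·N0 + 16` iterations so that
  pathological re-selection chains terminate.

An OMP comparator refits the active coefficients by least squares after each
selection (residual orthogonal to the selected span); selection still goes
through the gains.

## Homeostasis

All controllers regulate the *selection* gains toward the maximum-entropy
target `p0 = N0/N` of per-atom activation probability:

| variant | state | gain |
|---|---|---|
| NONE | — | `z_i(c) = c·δ(c>0)` |
| OLS  | variance EMA `V_i` | `γ_i ← γ_i(V_i/σ_g²)^α` |
| EMP  | activation EMA `p_i` | `γ_i = δ(p_i < p0(1+α_h))` |
| HAP  | activation EMA `p_i` | `γ_i = log p_i / log p0` |
| HEH  | per-atom CDF rows `z_i` | `z_i(c) = P_i(c)` (quantile) |

EMAs for OLS/EMP/HAP run once per batch at rate `η_h`
(`p_i ← (1−η_h)p_i + η_h·freq_batch`); HEH relaxes its CDF rows once per
*sample* (`z_i ← (1−η_h)z_i + η_h·δ(a_{k,i} ≤ ·)`, including the zero
coefficients of inactive atoms), applied in closed form over a batch with
geometric weights — exactly equivalent to the K successive relaxations
(the coefficient grid, when it must grow, is extended once per batch before
the relaxations rather than per sample; the rebinning is linear either way).
Note the consequence: at equal `η_h`, HEH adapts roughly K times faster per
batch than the scalar controllers.  This asymmetry is inherent to the
update definitions, not a calibration choice.

Numerical choices:

- HEH rows live on a shared uniform grid of 512 bins over `[0, c_max]`,
  with `c_max` tracked at 1.5× the largest coefficient seen; on extension
  rows are rebinned by linear interpolation.  Scoring is a right-continuous
  step lookup (0 for `c ≤ 0`).  Rows initialize to the uniform-prior CDF
  with mass `1 − N0/N` at zero rising linearly to 1.
- HAP clamps `p_i` to `[10⁻⁶, 1]` before the log, keeping the boost of a
  never-active atom finite (`log 10⁻⁶ / log p0`).
- OLS follows the printed update `γ_i ← γ_i(V_i/σ_g²)^α` literally, with
  `α = 0.02` and `σ_g²` estimated from the first batch when unset.  Be
  aware that with gains that enter only the selection score this is
  positive feedback (in the ancestral variance-equalization scheme the gain
  rescales the atom inside the reconstruction, which flips the feedback
  sign); the property suite documents that on a stationary skewed stream
  OLS does not shrink the activation spread, while EMP/HAP/HEH do.
- defaults (overridable): `η_h = 0.01`, `α_h = 0.02` (EMP slack),
  `α = 0.02` (OLS exponent).

## Learning loop

Per epoch: draw a K-batch of patches → code with current gains → Hebbian
update `Φ_i ← Φ_i + η Σ_k a_{k,i}(y_k − Φᵀa_k)` with residuals against the
epoch-start dictionary, summed, then one row renormalization → homeostasis
update → trace record.  The learning rate defaults to the inverse-time
schedule `η·τ/(τ+t)` with `τ = T/4` (a concrete stand-in for generic
stochastic-approximation scheduling; constant is available).  Batches are
drawn with replacement from a pool of patches extracted once at fit time
(default 4096) — statistically equivalent to per-epoch extraction and fully
reproducible per seed.

The held-out cost curve codes a fixed held-out batch with *neutral* gains on
each epoch's dictionary, so the curve compares dictionaries rather than
coders; the trace also records the Wasserstein spread and the entropy of the
held-out activation probabilities.

## Synthetic images

The generator emulates two statistics of natural outdoor scenes that drive
edge learning: a `1/f^β` amplitude spectrum (filtered Gaussian field,
default β = 1, verified by radial-spectrum fits to ±0.15 in log-log slope)
and oriented structure (straight ridge segments with Gaussian cross-section,
random position/orientation, default 24 per 128² image at contrast 2, plus
iid pixel noise of σ = 0.05); images are standardized.  What it does *not*
emulate: occlusion, curvature, phase alignment across scales, luminance
nonstationarity, and photometric noise statistics of real sensors.  Passing
tests therefore show that the algorithms behave as designed on data with
natural second-order and edge statistics, not that the learned dictionaries
match cortical receptive fields quantitatively.

## Problem sizes

Experiments run at desk scale by default — N = 144 atoms on 13×13 patches,
N0 = 10, K = 128, T = 256 epochs, with the full-scale configuration
(N = 676, 21×21, N0 = 21, K = 256, T = 4096) shipped as
`full_scale_config()` and flagged long-running.  The recovery experiment
uses a ground-truth dictionary of N = 36 atoms in M = 81 dimensions with
N0 = 3-sparse positive combinations, 500 epochs.  The convolutional demo
uses 8 kernels of 5×5 on 32×32 synthetic edge images with a 24-event budget,
200 epochs, 3 paired seeds.  At desk scale the ordering HEH ≤ (OLS, EMP,
HAP) ≤ NONE on final cost is noisy for the scalar controllers — their
benefit grows with N and T (longer runs at N = 324, T = 1024 separate
HEH < HAP < NONE cleanly); HEH's advantage is robust already at desk scale.

## Known limitations

- One-sided coding cannot represent negative coefficients on first
  selection; symmetric selection exists but is untested against the
  homeostasis variants.
- HEH stores an N×512 table and pays one searchsorted per (sample, atom)
  per MP step; it is the most expensive controller by ~4×.
- The convolutional layer supports NONE and HAP only, tracks homeostasis
  per kernel (not per position), and has no overlap inhibition beyond
  residual subtraction.
- `W` is a grid-trapezoidal estimate; with fewer than ~100 positive
  coefficients per atom it is noisy.
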