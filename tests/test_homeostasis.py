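"""Closed-form and distributional checks of the five gain controllers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shl.coding import SparseCode
from shl.homeostasis import (
    GainState,
    Variant,
    activation_threshold_report,
    init_gains,
    update_emp,
    update_gains,
    update_hap,
    update_heh,
    update_none,
    update_ols,
)


def dense_codes(A):
    """Wrap a dense coefficient matrix for the updaters."""
    return np.asarray(A, dtype=float)


class TestInit:
    def test_multiplicative_variants_start_neutral(self):
        for v in ("none", "ols", "emp", "hap"):
            st_ = init_gains(v, 16, 4)
            np.testing.assert_array_equal(st_.gamma, 1.0)
            assert st_.score(3, 0.5) == pytest.approx(0.5)

    def test_heh_mass_at_zero_is_one_minus_sparsity_fraction(self):
        st_ = init_gains("heh", 676, 21)
        np.testing.assert_allclose(st_.table[:, 0], 1 - 21 / 676, atol=1e-12)
        # ≈ 0.968–0.969 for the full-scale configuration
        assert st_.table[0, 0] == pytest.approx(0.9689, abs=5e-4)

    def test_all_atoms_identical_at_init(self):
        for v in ("hap", "heh"):
            st_ = init_gains(v, 12, 3)
            c = 0.37
            scores = [st_.score(i, c) for i in range(12)]
            assert len(set(np.round(scores, 15))) == 1

    def test_rejects_n0_not_below_n(self):
        with pytest.raises(ValueError):
            init_gains("hap", 8, 8)


class TestScore:
    def test_hap_gain_scales_positive_correlations(self):
        st_ = init_gains("hap", 4, 1)
        st_.gamma = np.array([1.0, 2.0, 1.0, 1.0])
        assert st_.score(1, 0.3) == pytest.approx(0.6)

    @pytest.mark.parametrize("variant", ["none", "ols", "emp", "hap", "heh"])
    def test_negative_correlations_score_zero(self, variant):
        st_ = init_gains(variant, 6, 2)
        assert st_.score(2, -0.5) == 0.0
        assert st_.score(2, 0.0) == 0.0

    def test_heh_score_tracks_empirical_cdf(self, rng):
        # feed a known mixture stream; the tracked quantile at the median of
        # the positive part must approach the true mixture CDF value
        p_active = 0.3
        n_samples = 10_000
        st_ = init_gains("heh", 2, 1, eta_h=1e-3)
        active = rng.random((n_samples, 2)) < p_active
        vals = rng.exponential(1.0, (n_samples, 2)) * active
        for start in range(0, n_samples, 100):
            update_heh(st_, dense_codes(vals[start : start + 100]))
        med = float(np.median(vals[vals[:, 0] > 0, 0]))
        true_cdf = (1 - p_active) + p_active * (1 - np.exp(-med))
        assert st_.score(0, med) == pytest.approx(true_cdf, abs=0.02)

    def test_score_monotone_in_correlation(self, rng):
        # gain-interface contract for every variant, incl. a trained HEH state
        for variant in ("none", "ols", "emp", "hap", "heh"):
            st_ = init_gains(variant, 6, 2)
            if variant == "heh":
                update_heh(st_, dense_codes(np.abs(rng.standard_normal((200, 6)))))
            else:
                st_.gamma = rng.uniform(0.0, 2.0, 6)
            cs = np.linspace(-1.0, 2.0, 41)
            for i in range(6):
                vals = [st_.score(i, c) for c in cs]
                assert np.all(np.diff(vals) >= -1e-12)


class TestUpdateRules:
    def test_none_is_identity(self, rng):
        st_ = init_gains("none", 8, 2)
        before = st_.copy()
        update_none(st_, dense_codes(rng.standard_normal((16, 8))))
        np.testing.assert_array_equal(st_.gamma, before.gamma)
        np.testing.assert_array_equal(st_.gamma, 1.0)

    def test_ols_fixed_point_at_target_variance(self):
        st_ = init_gains("ols", 4, 1, sigma_g2=1.0, eta_h=1.0, alpha_ols=0.5)
        A = np.ones((4, 4))  # batch variance exactly 1 for every atom
        for _ in range(3):
            update_ols(st_, dense_codes(A))
            np.testing.assert_allclose(st_.gamma, 1.0, atol=1e-12)

    def test_ols_closed_form_doubling(self):
        st_ = init_gains("ols", 3, 1, sigma_g2=1.0, eta_h=1.0, alpha_ols=0.5)
        A = np.full((5, 3), 2.0)  # batch mean square = 4 = 4·σ_g²
        update_ols(st_, dense_codes(A))
        np.testing.assert_allclose(st_.gamma, 2.0, atol=1e-12)

    def test_ols_moving_average_matches_loop_oracle(self, rng):
        st_ = init_gains("ols", 6, 2, sigma_g2=0.5, eta_h=0.3)
        V_ref = st_.V.copy()
        for _ in range(4):
            A = rng.standard_normal((10, 6))
            update_ols(st_, dense_codes(A))
            V_ref = 0.7 * V_ref + 0.3 * np.mean(A**2, axis=0)
        np.testing.assert_allclose(st_.V, V_ref, atol=1e-12)

    def test_ols_rejects_nonpositive_target(self, rng):
        st_ = init_gains("ols", 4, 1, sigma_g2=-1.0)
        with pytest.raises(ValueError):
            update_ols(st_, dense_codes(rng.standard_normal((4, 4))))

    def test_emp_gate_silences_overactive_atoms(self):
        st_ = init_gains("emp", 4, 1, alpha_h=0.02)
        threshold = st_.p0 * 1.02
        st_.p = np.array([threshold * 1.01, 0.0, st_.p0, threshold * 0.99])
        st_.eta_h = 0.0  # freeze p to probe the gate alone
        update_emp(st_, dense_codes(np.zeros((2, 4))))
        np.testing.assert_array_equal(st_.gamma, [0.0, 1.0, 1.0, 1.0])

    def test_emp_probability_arithmetic(self):
        st_ = init_gains("emp", 2, 1, eta_h=0.5)
        st_.p = np.array([0.2, 0.2])
        update_emp(st_, dense_codes(np.zeros((4, 2))))  # batch frequency 0
        np.testing.assert_allclose(st_.p, 0.1)

    def test_hap_closed_forms(self):
        st_ = init_gains("hap", 100, 5, eta_h=0.0)
        p0 = st_.p0
        st_.p = np.array([p0, p0**2, 1.0] + [p0] * 97)
        update_hap(st_, dense_codes(np.zeros((1, 100))))
        assert st_.gamma[0] == pytest.approx(1.0)
        assert st_.gamma[1] == pytest.approx(2.0)
        assert st_.gamma[2] == pytest.approx(0.0, abs=1e-12)

    def test_hap_gain_decreasing_in_p(self):
        st_ = init_gains("hap", 4, 1)
        ps = np.linspace(st_.p_floor * 10, 1.0, 50)
        gains = np.log(ps) / np.log(st_.p0)
        assert np.all(np.diff(gains) < 0)
        assert np.interp(st_.p0, ps, gains) == pytest.approx(1.0, abs=1e-2)

    def test_hap_floor_prevents_infinite_gain(self):
        st_ = init_gains("hap", 4, 1, eta_h=1.0, p_floor=1e-6)
        update_hap(st_, dense_codes(np.zeros((8, 4))))  # nothing ever active
        assert np.all(np.isfinite(st_.gamma))
        np.testing.assert_allclose(
            st_.gamma, np.log(1e-6) / np.log(st_.p0), atol=1e-12
        )


class TestHEHUpdate:
    def test_full_replacement_step(self):
        st_ = init_gains("heh", 3, 1, eta_h=1.0)
        A = np.zeros((1, 3))
        A[0, 1] = 0.5
        update_heh(st_, dense_codes(A))
        row = st_.table[1]
        expected = (st_.grid >= 0.5).astype(float)
        np.testing.assert_allclose(row, expected, atol=1e-12)

    def test_all_zero_codes_converge_to_step_at_zero(self):
        st_ = init_gains("heh", 3, 1, eta_h=0.5)
        for _ in range(60):
            update_heh(st_, dense_codes(np.zeros((4, 3))))
        np.testing.assert_allclose(st_.table[:, 0], 1.0, atol=1e-8)

    def test_batch_update_equals_per_sample_relaxation(self, rng):
        st_a = init_gains("heh", 5, 2, eta_h=0.1, c_max=10.0)
        st_b = st_a.copy()
        A = np.abs(rng.standard_normal((7, 5))) * 3
        update_heh(st_a, dense_codes(A))
        for k in range(7):
            ind = (A[k][:, None] <= st_b.grid[None, :]).astype(float)
            st_b.table = 0.9 * st_b.table + 0.1 * ind
        np.testing.assert_allclose(st_a.table, st_b.table, atol=1e-12)

    def test_grid_extends_for_large_coefficients(self):
        st_ = init_gains("heh", 2, 1, eta_h=0.5)
        A = np.full((1, 2), 5.0)
        update_heh(st_, dense_codes(A))
        assert st_.grid[-1] == pytest.approx(7.5)
        assert st_.score(0, 6.0) > st_.score(0, 1.0)

    def test_cdf_convergence_to_mixture(self, rng):
        # sup-norm distance to the true (mass at 0 + exponential) CDF after
        # 10^4 samples at eta_h = 1e-3
        p_active = 0.2
        st_ = init_gains("heh", 4, 1, eta_h=1e-3)
        active = rng.random((10_000, 4)) < p_active
        vals = rng.exponential(1.0, (10_000, 4)) * active
        for s in range(0, 10_000, 100):
            update_heh(st_, dense_codes(vals[s : s + 100]))
        true_cdf = (1 - p_active) + p_active * (1 - np.exp(-st_.grid))
        sup = np.max(np.abs(st_.table - true_cdf[None, :]))
        assert sup <= 0.03

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_rows_monotone_and_terminal_after_random_streams(self, seed):
        rng = np.random.default_rng(seed)
        st_ = init_gains("heh", 3, 1, eta_h=float(rng.uniform(0.01, 0.9)))
        for _ in range(5):
            A = np.abs(rng.standard_normal((rng.integers(1, 9), 3))) * rng.uniform(0, 4)
            update_heh(st_, dense_codes(A))
        assert np.all(np.diff(st_.table, axis=1) >= -1e-12)
        np.testing.assert_allclose(st_.table[:, -1], 1.0, atol=1e-9)
        assert np.all(st_.table >= -1e-12) and np.all(st_.table <= 1 + 1e-12)


def simulate_selection_stream(variant, rounds=400, seed=0, n=16, n0=2):
    """Drive a controller with a skewed stationary score stream.

    Atoms have heterogeneous correlation scales, so without homeostasis a few
    atoms dominate the top-n0 selection; returns the spread (std) of
    selection frequencies over the final quarter of the stream.
    """
    rng = np.random.default_rng(seed)
    scales = np.geomspace(0.5, 2.0, n)
    state = init_gains(variant, n, n0, eta_h=0.05)
    counts = np.zeros(n)
    tail = rounds // 4
    for t in range(rounds):
        C = scales * rng.exponential(1.0, n)
        scores = state.scores(C[None, :])[0]
        chosen = np.argsort(-scores)[:n0]
        A = np.zeros((1, n))
        A[0, chosen] = C[chosen]
        update_gains(state, A)
        if t >= rounds - tail:
            counts[chosen] += 1
    return float(np.std(counts / tail))


class TestEqualizationTrend:
    def test_adaptive_variants_reduce_activation_spread(self):
        spread = {v: simulate_selection_stream(v) for v in ("none", "emp", "hap", "heh")}
        assert spread["heh"] <= spread["hap"] <= spread["none"]
        assert spread["emp"] <= spread["none"]
        assert min(spread, key=spread.get) == "heh"

    def test_ols_spread_does_not_shrink(self):
        # The variance-based rule multiplies gains by (V/σ_g²)^α, which under
        # selection-only gains is positive feedback: the spread stays at or
        # above the unregulated level on the same stream.
        assert simulate_selection_stream("ols") >= simulate_selection_stream("none") - 1e-9


class TestReport:
    def test_fresh_hap_state_rows(self):
        st_ = init_gains("hap", 5, 1)
        df = activation_threshold_report(st_)
        assert len(df) == 5
        np.testing.assert_allclose(df["p"], st_.p0)
        np.testing.assert_allclose(df["gamma"], 1.0)

    def test_emp_gamma_column_binary_after_silencing(self, rng):
        st_ = init_gains("emp", 6, 1, eta_h=1.0)
        A = np.zeros((10, 6))
        A[:, 0] = 1.0  # atom 0 active always → above threshold → silenced
        update_emp(st_, dense_codes(A))
        df = activation_threshold_report(st_)
        assert set(df["gamma"]).issubset({0.0, 1.0})
        assert df["gamma"][0] == 0.0
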