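"""LIV, kernel-pooled autocorrelation and OCDS estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynoct import (
    ACFProfile,
    Kernel,
    TimeSeriesStack,
    compute_acf,
    compute_liv,
    compute_ocds,
    fit_exponential_decay,
    simulate_uniform,
)
from dynoct.phantom import CompartmentDynamics

from _oracles import liv_literal, ols_slope_literal, pooled_acf_literal

DT = 204.8


def make_stack(data, dt_ms=DT):
    return TimeSeriesStack(data=np.asarray(data, dtype=float), dt_ms=dt_ms)


class TestLIV:
    def test_constant_series_zero(self):
        stack = make_stack(np.full((2, 8, 3, 3), 27.5))
        assert np.all(compute_liv(stack).values == 0.0)

    def test_alternating_two_db_gives_unit_variance(self):
        series = np.tile([0.0, 2.0], 16)
        stack = make_stack(np.broadcast_to(series[None, :, None, None], (1, 32, 2, 2)))
        vol = compute_liv(stack)
        np.testing.assert_allclose(vol.values, 1.0)
        np.testing.assert_allclose(vol.mean_intensity_db, 1.0)

    def test_matches_literal_transcription(self, random_stack):
        vol = compute_liv(random_stack)
        for y in range(random_stack.n_locations):
            for z in range(random_stack.data.shape[2]):
                for x in range(random_stack.data.shape[3]):
                    expected = liv_literal(list(random_stack.data[y, :, z, x]))
                    assert vol.values[y, z, x] == pytest.approx(expected, rel=1e-12, abs=1e-12)

    @given(offset=st.floats(-80, 80), scale=st.floats(0.1, 10))
    @settings(max_examples=25, deadline=None)
    def test_offset_invariant_and_quadratic_scaling(self, offset, scale):
        rng = np.random.default_rng(5)
        base = rng.standard_normal((1, 16, 3, 3))
        ref = compute_liv(make_stack(base)).values
        shifted = compute_liv(make_stack(base + offset)).values
        scaled = compute_liv(make_stack(base * scale)).values
        np.testing.assert_allclose(shifted, ref, rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(scaled, ref * scale**2, rtol=1e-9)

    def test_rejects_short_or_nonfinite_input(self):
        with pytest.raises(ValueError, match="repeats"):
            compute_liv(make_stack(np.zeros((1, 1, 2, 2))))
        bad = np.zeros((1, 4, 2, 2))
        bad[0, 1, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            compute_liv(make_stack(bad))


class TestACF:
    def test_lag_zero_is_unity(self, random_stack):
        acf = compute_acf(random_stack, Kernel(k=2, l=2))
        np.testing.assert_array_equal(acf.rho[:, 0], 1.0)

    @given(
        n_rep=st.integers(4, 24),
        nz=st.integers(2, 7),
        nx=st.integers(4, 9),
        k=st.integers(1, 3),
        l=st.integers(1, 4),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=40, deadline=None)
    def test_fft_and_direct_paths_agree(self, n_rep, nz, nx, k, l, seed):
        rng = np.random.default_rng(seed)
        stack = make_stack(20 + rng.standard_normal((1, n_rep, nz, nx)))
        kern = Kernel(k=min(k, nz), l=min(l, nx))
        a = compute_acf(stack, kern, method="fft", i_max=min(6, n_rep - 1))
        b = compute_acf(stack, kern, method="direct", i_max=min(6, n_rep - 1))
        np.testing.assert_allclose(a.rho, b.rho, rtol=1e-9, atol=1e-11)

    @pytest.mark.parametrize("method", ["direct", "fft"])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_triple_loop_transcription(self, method, seed):
        """Kernel covering a whole 2 x 4 x 32 patch equals the literal pooled estimator."""
        rng = np.random.default_rng(seed)
        patch = 25 + 2.0 * rng.standard_normal((2, 4, 32))  # (k, l, time)
        stack = make_stack(patch.transpose(2, 0, 1)[None])  # (1, t, z, x)
        acf = compute_acf(stack, Kernel(k=2, l=4), i_max=6, method=method)
        expected = pooled_acf_literal(patch.tolist(), 6)
        np.testing.assert_allclose(acf.rho[0, :, 0, 1], expected, rtol=1e-9, atol=1e-12)

    def test_affine_rescaling_invariance(self, random_stack):
        ref = compute_acf(random_stack, Kernel(k=2, l=2)).rho
        scaled = TimeSeriesStack(data=3.5 * random_stack.data - 40.0, dt_ms=DT)
        got = compute_acf(scaled, Kernel(k=2, l=2)).rho
        np.testing.assert_allclose(got, ref, rtol=1e-9, atol=1e-9)

    def test_constant_background_degenerates_to_zero(self):
        stack = make_stack(np.full((1, 16, 4, 6), 30.0))
        acf = compute_acf(stack)
        assert np.all(acf.rho[:, 0] == 1.0)
        assert np.all(acf.rho[:, 1:] == 0.0)
        assert acf.degenerate.all()
        assert np.all(compute_ocds(acf).values == 0.0)

    def test_kernel_larger_than_image_rejected(self):
        stack = make_stack(np.zeros((1, 8, 2, 3)))
        with pytest.raises(ValueError, match="larger than image"):
            compute_acf(stack, Kernel(k=4, l=2))

    def test_white_noise_correlation_near_zero(self):
        comp = CompartmentDynamics(mean_db=20, sigma2_db2=0, tau_c_ms=1, noise_db2=4)
        stack = simulate_uniform(comp, (1, 20, 40), n_repeats=128, seed=3)
        acf = compute_acf(stack)
        # independent voxels on a kernel-strided subgrid
        sub = acf.rho[0][:, 0:20:2, 1:40:4]
        for i in range(1, acf.n_lags):
            v = sub[i].ravel()
            assert abs(v.mean()) < 4 * v.std(ddof=1) / np.sqrt(v.size)


def linear_rho_profile(slope, i_max=6, shape=(1, 3, 4)):
    tau = np.arange(i_max + 1) * DT
    rho = 1.0 - slope * tau
    full = np.broadcast_to(rho[None, :, None, None],
                           (shape[0], i_max + 1, shape[1], shape[2])).copy()
    return ACFProfile(rho=full, tau_ms=tau, dt_ms=DT)


class TestOCDS:
    def test_linear_decay_recovers_slope_exactly(self):
        """ρ = 1 − mτ gives OCDS = m; m set at the viability cutoff magnitude."""
        vol = compute_ocds(linear_rho_profile(2e-4))
        np.testing.assert_allclose(vol.values, 2e-4, rtol=1e-12)
        assert vol.metric == "ocdsl"

    def test_flat_correlation_gives_zero(self):
        np.testing.assert_allclose(compute_ocds(linear_rho_profile(0.0)).values,
                                   0.0, atol=1e-15)

    def test_exponential_decay_matches_ols_oracle(self):
        tau = np.arange(7) * DT
        rho = np.exp(-tau / 1000.0)
        prof = ACFProfile(
            rho=np.broadcast_to(rho[None, :, None, None], (1, 7, 2, 2)).copy(),
            tau_ms=tau, dt_ms=DT)
        expected = -ols_slope_literal(list(tau[1:]), list(rho[1:]))
        np.testing.assert_allclose(compute_ocds(prof).values, expected, rtol=1e-12)

    def test_rising_correlation_goes_negative_unclipped(self):
        vol = compute_ocds(linear_rho_profile(-1e-4))
        np.testing.assert_allclose(vol.values, -1e-4, rtol=1e-12)

    def test_window_needs_two_delay_points(self):
        with pytest.raises(ValueError, match="need >= 2"):
            compute_ocds(linear_rho_profile(1e-4), fit_lo_ms=200.0, fit_hi_ms=210.0)

    def test_ocds_monotone_on_slow_side_of_response(self):
        """Slower decorrelation means smaller OCDS, for τ_c past the window response peak."""
        means = []
        for tau_c in (1000.0, 2000.0, 4000.0):
            comp = CompartmentDynamics(mean_db=30, sigma2_db2=5, tau_c_ms=tau_c, noise_db2=0.2)
            stack = simulate_uniform(comp, (2, 40, 40), seed=int(tau_c))
            means.append(compute_ocds(compute_acf(stack)).values.mean())
        assert means[0] > means[1] > means[2]

    def test_noise_floor_lowers_ocds(self):
        """More white noise shrinks the correlated fraction r and hence OCDS."""
        means = []
        for noise in (0.0, 5.0):
            comp = CompartmentDynamics(mean_db=30, sigma2_db2=5, tau_c_ms=800.0, noise_db2=noise)
            stack = simulate_uniform(comp, (2, 40, 40), seed=99)
            means.append(compute_ocds(compute_acf(stack)).values.mean())
        assert means[0] > means[1] > 0


class TestParameterRecovery:
    @pytest.mark.parametrize("tau_c", [300.0, 1000.0, 3000.0])
    def test_decorrelation_time_recovered_within_25_percent(self, tau_c):
        comp = CompartmentDynamics(mean_db=30, sigma2_db2=5, tau_c_ms=tau_c, noise_db2=0.1)
        stack = simulate_uniform(comp, (2, 60, 60), seed=100 + int(tau_c))
        tau_est, amp = fit_exponential_decay(compute_acf(stack))
        med = np.nanmedian(tau_est)
        assert abs(med - tau_c) / tau_c < 0.25
        assert 0 < np.nanmedian(amp) <= 1.2
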