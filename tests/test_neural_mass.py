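"""Unit and property tests of the three-population neural mass model."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from ssrdcm.errors import InstabilityError, ParameterError, StructuralError
from ssrdcm import neural_mass as nm
from ssrdcm.params import default_noise, default_params


class TestAlphaKernel:
    def test_vanishes_at_origin(self):
        assert nm.alpha_kernel_response(8.0, 250.0, 0.0) == 0.0
        assert nm.alpha_kernel_response(1.0, 5.0, 0.0) == 0.0

    def test_peak_at_inverse_rate(self):
        for H, k in ((8.0, 250.0), (32.0, 62.5), (1.0, 1.0)):
            assert nm.alpha_kernel_response(H, k, 1.0 / k) == \
                pytest.approx(H / np.e, rel=1e-12)
            # single interior maximum: values on either side are smaller
            t = np.linspace(1e-6, 10 / k, 500)
            h = nm.alpha_kernel_response(H, k, t)
            assert h.max() <= H / np.e + 1e-12

    def test_integral_closed_form(self):
        H, k = 8.0, 250.0
        val, _ = quad(lambda t: nm.alpha_kernel_response(H, k, t), 0, 50 / k)
        assert val == pytest.approx(H / k, rel=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            nm.alpha_kernel_response(-1.0, 250.0, 0.1)
        with pytest.raises(ParameterError):
            nm.alpha_kernel_response(8.0, 0.0, 0.1)
        with pytest.raises(ParameterError):
            nm.alpha_kernel_response(8.0, 250.0, -0.1)


class TestSigmoid:
    def test_centred_at_rest(self):
        assert nm.sigmoid_firing(0.0, 2.0, 1.0) == pytest.approx(0.0, abs=1e-15)

    def test_saturation_and_monotonicity(self):
        v = np.linspace(-8, 8, 2001)
        s = nm.sigmoid_firing(v, 2.0, 1.0)
        assert np.all(np.diff(s) > 0)
        # asymptotes of the centred sigmoid are finite in both directions
        upper = 1 - 1 / (1 + np.exp(2.0))
        lower = -1 / (1 + np.exp(2.0))
        assert nm.sigmoid_firing(50.0, 2.0, 1.0) == pytest.approx(upper, abs=1e-9)
        assert nm.sigmoid_firing(-50.0, 2.0, 1.0) == pytest.approx(lower, abs=1e-9)

    def test_slope_matches_finite_difference(self):
        h = 1e-6
        for v in (-2.0, 0.0, 1.0, 3.5):
            fd = (nm.sigmoid_firing(v + h, 2.0, 1.0)
                  - nm.sigmoid_firing(v - h, 2.0, 1.0)) / (2 * h)
            assert nm.sigmoid_slope(v, 2.0, 1.0) == pytest.approx(fd, abs=1e-8)


class TestStateDerivatives:
    def test_origin_is_equilibrium(self, fb_params):
        x0 = np.zeros(fb_params.n_states)
        assert np.abs(nm.state_derivatives(x0, 0.0, fb_params)).max() == 0.0

    def test_dimension_mismatch(self, fb_params):
        with pytest.raises(StructuralError):
            nm.state_derivatives(np.zeros(7), 0.0, fb_params)

    def test_impulse_response_equals_alpha_kernel(self, decoupled_params):
        """Integrating the uncoupled stellate subunit reproduces the kernel.

        An impulse of input firing through the second-order state equations
        must produce exactly H·κ·t·e^{−κt}; integrated with tight adaptive
        tolerances the match is far below 1e-6 of the peak.
        """
        p = decoupled_params
        H, k, C = p.H_e[0], p.kappa_e[0], p.C[0]
        x0 = np.zeros(p.n_states)
        x0[1] = k * H * C        # post-impulse stellate current
        sol = solve_ivp(lambda t, x: nm.state_derivatives(x, 0.0, p),
                        (0, 0.08), x0, rtol=1e-11, atol=1e-14,
                        dense_output=True)
        t = np.linspace(0, 0.08, 200)
        v = sol.sol(t)[0]
        expected = nm.alpha_kernel_response(H, k, t) * C
        assert np.abs(v - expected).max() < 1e-6 * expected.max()

    def test_response_linear_in_H_e_near_origin(self, fb_params):
        p2 = fb_params.copy()
        p2.H_e = p2.H_e * 2
        x = np.zeros(fb_params.n_states)
        u = 1e-6
        d1 = nm.state_derivatives(x, u, fb_params)
        d2 = nm.state_derivatives(x, u, p2)
        # stellate current drive doubles with H_e in the linear regime
        assert d2[1] == pytest.approx(2 * d1[1], rel=1e-9)


class TestFixedPointAndJacobian:
    def test_zero_input_fixed_point_is_origin(self, fb_params):
        x = nm.find_fixed_point(fb_params, u0=0.0)
        assert np.all(x == 0)

    def test_nonzero_input_fixed_point(self, fb_params):
        x = nm.find_fixed_point(fb_params, u0=0.2)
        res = nm.state_derivatives(x, 0.2, fb_params)
        assert np.abs(res).max() < 1e-9
        assert np.abs(x).max() > 0

    def test_jacobian_matches_finite_differences(self, fb_params, rng):
        x = rng.normal(0, 0.3, fb_params.n_states)
        J = nm.jacobian(fb_params, x)
        eps = 1e-6
        scale = np.abs(J).max()
        for i in range(fb_params.n_states):
            e = np.zeros(fb_params.n_states)
            e[i] = eps
            col = (nm.state_derivatives(x + e, 0.0, fb_params)
                   - nm.state_derivatives(x - e, 0.0, fb_params)) / (2 * eps)
            assert np.abs(J[:, i] - col).max() < 1e-6 * scale

    def test_uncoupled_eigenvalues_are_kernel_rates(self, decoupled_params):
        J = nm.jacobian(decoupled_params, np.zeros(decoupled_params.n_states))
        eig = np.sort(np.linalg.eigvals(J).real)
        ke, ki = decoupled_params.kappa_e[0], decoupled_params.kappa_i[0]
        # per source: 3 excitatory subunits (double root -kappa_e) and
        # 2 inhibitory subunits (double root -kappa_i)
        expected = np.sort(np.array([-ke] * 12 + [-ki] * 8))
        # double roots of the kernel are defective, so numerical eigenvalues
        # split at the square root of machine precision
        assert np.allclose(eig, expected, atol=0.05)
        assert np.abs(np.linalg.eigvals(J).imag).max() < 0.05

    def test_default_architectures_are_stable(self):
        for tag in ("FB", "BF", "LL"):
            assert nm.spectral_abscissa(default_params(tag)) < 0

    def test_unstable_parameters_flagged(self):
        p = default_params("FB", overrides={"gamma": (1280, 1280, 64, 64, 16)})
        assert nm.spectral_abscissa(p) > 0


class TestSimulation:
    def test_zero_innovations_stay_at_fixed_point(self, fb_params):
        silent = default_noise(innovation_white=0, innovation_pink=0,
                               channel_white=0, channel_pink=0,
                               shared_white=0, shared_pink=0)
        sim = nm.simulate_timeseries(fb_params, silent, duration=0.5, seed=0,
                                     burn_in=0.5)
        assert np.abs(sim.data).max() == 0.0

    def test_seed_determinism(self, fb_params, noise):
        a = nm.simulate_timeseries(fb_params, noise, duration=1.0, seed=7)
        b = nm.simulate_timeseries(fb_params, noise, duration=1.0, seed=7)
        c = nm.simulate_timeseries(fb_params, noise, duration=1.0, seed=8)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_divergence_guard(self, noise):
        p = default_params("FB", overrides={"gamma": (1280, 1280, 64, 64, 16),
                                            "H_e": 64.0})
        with pytest.raises(InstabilityError):
            nm.simulate_timeseries(p, noise, duration=5.0, seed=1)

    def test_colored_noise_psd(self):
        """Spectral synthesis hits the white + 1/f target density."""
        from scipy import signal
        rng = np.random.default_rng(3)
        dt = 1e-3
        x = nm.colored_noise(2 ** 19, dt, 0.5, 1.0, rng)
        f, P = signal.welch(x, fs=1 / dt, nperseg=4096, noverlap=0)
        sel = (f >= 1) & (f <= 100)
        target = 0.5 + 1.0 / np.maximum(f[sel], 1.0)
        ratio = P[sel] / 2 / target
        n_seg = 2 ** 19 // 4096
        assert np.abs(ratio.mean() - 1) < 3 / np.sqrt(n_seg * sel.sum())
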