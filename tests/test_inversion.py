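"""Tests of CSD vectorization and the variational Laplace scheme."""

import numpy as np
import pytest

from ssrdcm.containers import CrossSpectra
from ssrdcm.errors import InstabilityError
from ssrdcm.forward import default_freqs, predict_csd
from ssrdcm.inversion import (PriorSpec, VLSettings, devectorize_csd,
                              log_evidence, variational_laplace,
                              vectorize_csd)


def make_csd(rng, n_freqs=30, c=2):
    z = rng.standard_normal((n_freqs, c, 4)) \
        + 1j * rng.standard_normal((n_freqs, c, 4))
    values = np.einsum("fck,fdk->fcd", z, z.conj()) / 4
    return CrossSpectra(freqs=np.arange(1.0, n_freqs + 1.0), values=values)


class TestVectorize:
    def test_length_two_channels(self, rng):
        csd = make_csd(rng)
        # 3 real + 1 imaginary number per frequency for 2 channels
        assert vectorize_csd(csd).size == 30 * 4

    def test_round_trip_identity(self, rng):
        csd = make_csd(rng)
        back = devectorize_csd(vectorize_csd(csd), csd.freqs, csd.channels)
        assert np.allclose(back.values, csd.values, atol=1e-12)

    def test_real_diagonal_gives_zero_imaginary_part(self, rng):
        csd = make_csd(rng)
        vec = vectorize_csd(csd)
        diag_real = np.diagonal(csd.values, axis1=1, axis2=2).real
        # diagonal entries appear among the real block, imag block excludes them
        per_f = vec.reshape(30, 4)
        assert np.allclose(per_f[:, 0], diag_real[:, 0])
        assert np.allclose(per_f[:, 2], diag_real[:, 1])


def linear_problem(rng, n=40, p=3, sigma=0.3):
    X = rng.standard_normal((n, p))
    mu0 = rng.normal(0, 1, p)
    C0 = np.diag(rng.uniform(0.5, 2.0, p))
    theta_true = mu0 + np.linalg.cholesky(C0) @ rng.standard_normal(p)
    y = X @ theta_true + sigma * rng.standard_normal(n)
    priors = PriorSpec(names=tuple(f"t{i}" for i in range(p)), mean=mu0,
                       cov=C0, hyper_mean=np.log(1 / sigma ** 2),
                       hyper_var=0.0)
    return X, y, priors, sigma


def conjugate_posterior(X, y, priors, sigma):
    C0inv = np.linalg.inv(priors.cov)
    S = np.linalg.inv(X.T @ X / sigma ** 2 + C0inv)
    m = S @ (X.T @ y / sigma ** 2 + C0inv @ priors.mean)
    n = y.size
    Cy = sigma ** 2 * np.eye(n) + X @ priors.cov @ X.T
    r = y - X @ priors.mean
    _, logdet = np.linalg.slogdet(Cy)
    log_ev = -0.5 * (n * np.log(2 * np.pi) + logdet
                     + r @ np.linalg.solve(Cy, r))
    return m, S, log_ev


class TestVariationalLaplace:
    def test_linear_gaussian_conjugate_oracle(self, rng):
        """Posterior mean/covariance and F match the closed form."""
        X, y, priors, sigma = linear_problem(rng)
        post = variational_laplace(lambda t: X @ t, y, priors)
        m_ref, S_ref, log_ev = conjugate_posterior(X, y, priors, sigma)
        assert np.abs(post.mean - m_ref).max() < 1e-6
        assert np.abs(post.cov - S_ref).max() < 1e-6
        assert post.free_energy == pytest.approx(log_ev, abs=1e-4)

    def test_trace_monotone_and_final(self, rng):
        X, y, priors, _ = linear_problem(rng)
        post = variational_laplace(lambda t: X @ t, y, priors)
        assert all(b >= a for a, b in zip(post.trace, post.trace[1:]))
        assert log_evidence(post) == post.trace[-1]

    def test_batch_forward_agrees_with_scalar(self, rng):
        X, y, priors, _ = linear_problem(rng)
        post_a = variational_laplace(lambda t: X @ t, y, priors)
        post_b = variational_laplace(lambda t: X @ t, y, priors,
                                     forward_batch=lambda ts: ts @ X.T)
        assert np.allclose(post_a.mean, post_b.mean, atol=1e-10)
        assert post_a.free_energy == pytest.approx(post_b.free_energy,
                                                   abs=1e-8)

    def test_complexity_zero_when_data_uninformative(self, rng):
        """A constant forward model leaves the posterior at the prior."""
        priors = PriorSpec(names=("a", "b"), mean=np.zeros(2),
                           cov=np.eye(2), hyper_mean=0.0, hyper_var=0.0)
        y = np.zeros(10)
        post = variational_laplace(lambda t: np.zeros(10), y, priors)
        assert post.complexity == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(post.mean, priors.mean)
        assert np.allclose(post.cov, priors.cov, atol=1e-10)

    def test_complexity_nonnegative(self, rng):
        X, y, priors, _ = linear_problem(rng)
        post = variational_laplace(lambda t: X @ t, y, priors)
        assert post.complexity >= 0

    def test_no_signal_keeps_posterior_near_prior(self, rng):
        """Data generated at the prior mean moves no parameter beyond 2 SD."""
        X, _, priors, _ = linear_problem(rng, sigma=1e-3)
        y = X @ priors.mean + 1e-6 * rng.standard_normal(40)
        priors = PriorSpec(names=priors.names, mean=priors.mean,
                           cov=priors.cov, hyper_mean=np.log(1e6),
                           hyper_var=0.0)
        post = variational_laplace(lambda t: X @ t, y, priors)
        for i, name in enumerate(post.names):
            assert abs(post.mean[i] - priors.mean[i]) < 2 * post.sd(name) + 1e-6

    def test_irrelevant_parameter_does_not_raise_evidence(self, rng):
        """Occam penalty: a free parameter with no data effect cannot help."""
        X, y, priors, sigma = linear_problem(rng)
        post_base = variational_laplace(lambda t: X @ t, y, priors)
        p = len(priors.names)
        priors_big = PriorSpec(names=priors.names + ("junk",),
                               mean=np.append(priors.mean, 0.0),
                               cov=np.diag(np.append(np.diag(priors.cov), 1.0)),
                               hyper_mean=priors.hyper_mean, hyper_var=0.0)
        post_big = variational_laplace(lambda t: X @ t[:p], y, priors_big)
        assert post_big.free_energy <= post_base.free_energy + 0.05

    def test_tolerance_stability(self, rng):
        X, y, priors, _ = linear_problem(rng)
        f_loose = variational_laplace(lambda t: X @ t, y, priors,
                                      VLSettings(tol=1e-2)).free_energy
        f_tight = variational_laplace(lambda t: X @ t, y, priors,
                                      VLSettings(tol=1e-4)).free_energy
        assert abs(f_loose - f_tight) < 0.1

    def test_unstable_forward_regions_are_avoided(self, rng):
        """Instability errors reject the step instead of aborting the fit."""
        X, y, priors, _ = linear_problem(rng)

        def forward(t):
            if np.abs(t - priors.mean).max() > 5.0:
                raise InstabilityError("out of the stable region")
            return X @ t

        post = variational_laplace(forward, y, priors)
        assert np.isfinite(post.free_energy)

    def test_free_noise_precision_is_estimated(self, rng):
        X, y, priors, sigma = linear_problem(rng, n=200, sigma=0.5)
        priors_free = PriorSpec(names=priors.names, mean=priors.mean,
                                cov=priors.cov, hyper_mean=0.0, hyper_var=16.0)
        post = variational_laplace(lambda t: X @ t, y, priors_free)
        est_sigma = np.exp(-post.log_precision / 2)
        assert est_sigma == pytest.approx(sigma, rel=0.2)

    def test_fixed_parameters_stay_fixed(self, rng):
        X, y, priors, _ = linear_problem(rng)
        cov = priors.cov.copy()
        cov[0, 0] = 0.0      # structurally fixed
        priors_fixed = PriorSpec(names=priors.names, mean=priors.mean,
                                 cov=cov, hyper_mean=priors.hyper_mean,
                                 hyper_var=0.0)
        post = variational_laplace(lambda t: X @ t, y, priors_fixed)
        assert post.mean[0] == priors.mean[0]
        assert post.cov[0, 0] == 0.0


class TestDCMFitSmoke:
    def test_recovers_strong_single_effect(self):
        """A large known He reduction at the top dose is found by the fit."""
        from ssrdcm.dcm import fit_recording
        from ssrdcm.params import ConditionEffects, default_params, \
            default_noise

        eff = ConditionEffects()
        eff.b[3, 0, 0] = -0.6    # H_e of A1 at 2.8%
        p0 = default_params("FB")
        nz = default_noise()
        csds = {}
        for dose in (1.4, 1.8, 2.4, 2.8):
            csds[dose] = predict_csd(p0, nz, default_freqs(), effects=eff,
                                     condition=dose)
        post = fit_recording(csds, "FB", settings=VLSettings(max_iter=32))
        assert post["b_H_e_A1_2.8"] < -0.3
        assert abs(post["b_H_e_PAF_2.8"]) < 0.2
        assert all(b >= a for a, b in zip(post.trace, post.trace[1:]))
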