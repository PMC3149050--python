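"""Variational Laplace inversion of generative models of cross-spectra.

The observation model is y = g(ϑ) + ε with Gaussian priors p(ϑ) = N(μ, Σ0)
over log-scaling parameters and i.i.d. Gaussian observation noise of
log-precision λ.  A Gaussian posterior q(ϑ) = N(m, Σ) is found by
maximising the negative free energy

    F = E_q[ln p(y|ϑ, λ)] − KL[q(ϑ) ∥ p(ϑ)] − KL[q(λ) ∥ p(λ)],

a lower bound on the log model evidence ln p(y|m).  Optimisation uses
Gauss–Newton steps with Levenberg–Marquardt damping; a step is accepted only
if it increases F, so the iteration trace is monotone by construction.
Gradients of the forward model are taken by central finite differences on
the log-scaling parameters, and the noise log-precision is updated by a
one-dimensional Newton scheme under its own Gaussian (hyper)prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import CrossSpectra
from .errors import InstabilityError, ParameterError, StructuralError

__all__ = ["vectorize_csd", "devectorize_csd", "PriorSpec", "VLSettings",
           "Posterior", "variational_laplace", "log_evidence"]


def vectorize_csd(csd: CrossSpectra) -> np.ndarray:
    """Stack a Hermitian CSD into a real vector with a fixed ordering.

    Per frequency: real parts of the upper triangle including the diagonal
    (row-major), then imaginary parts of the strict upper triangle.  For C
    channels this gives C² real numbers per frequency; the map is invertible
    (:func:`devectorize_csd`).
    """
    c = csd.n_channels
    iu_r, ju_r = np.triu_indices(c)
    iu_i, ju_i = np.triu_indices(c, k=1)
    re = csd.values[:, iu_r, ju_r].real
    im = csd.values[:, iu_i, ju_i].imag
    return np.concatenate([re, im], axis=1).reshape(-1)


def devectorize_csd(vec: np.ndarray, freqs, channels) -> CrossSpectra:
    """Inverse of :func:`vectorize_csd`."""
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    c = len(channels)
    per_f = c * c
    vec = np.asarray(vec, dtype=float)
    if vec.size != freqs.size * per_f:
        raise StructuralError(
            f"vector length {vec.size} does not match {freqs.size} "
            f"frequencies x {per_f} entries"
        )
    block = vec.reshape(freqs.size, per_f)
    n_re = c * (c + 1) // 2
    iu_r, ju_r = np.triu_indices(c)
    iu_i, ju_i = np.triu_indices(c, k=1)
    values = np.zeros((freqs.size, c, c), dtype=complex)
    values[:, iu_r, ju_r] += block[:, :n_re]
    values[:, iu_i, ju_i] += 1j * block[:, n_re:]
    lower = values.conj().transpose(0, 2, 1).copy()
    diag = np.arange(c)
    lower[:, diag, diag] = 0.0
    return CrossSpectra(freqs=freqs, values=values + lower, channels=channels)


@dataclass
class PriorSpec:
    """Gaussian prior over named log-scaling parameters, plus the noise
    hyperprior.

    Parameters with zero prior variance are structurally fixed and excluded
    from estimation.  ``hyper_mean`` / ``hyper_var`` parameterise the
    Gaussian prior on the observation-noise log-precision λ; ``hyper_var =
    0`` fixes λ at ``hyper_mean`` (known noise).
    """

    names: tuple
    mean: np.ndarray
    cov: np.ndarray
    hyper_mean: float = 8.0
    hyper_var: float = 16.0

    def __post_init__(self):
        self.names = tuple(self.names)
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        m = len(self.names)
        if self.cov.ndim == 1:
            self.cov = np.diag(self.cov)
        if self.mean.shape != (m,) or self.cov.shape != (m, m):
            raise StructuralError("prior mean/cov shapes do not match names")
        if np.abs(self.cov - self.cov.T).max() > 1e-12 * max(1.0, np.abs(self.cov).max()):
            raise ParameterError("prior covariance must be symmetric")
        if np.linalg.eigvalsh(0.5 * (self.cov + self.cov.T)).min() < -1e-10:
            raise ParameterError("prior covariance must be PSD")
        if self.hyper_var < 0:
            raise ParameterError("hyperprior variance must be nonnegative")

    @property
    def free(self) -> np.ndarray:
        return np.diag(self.cov) > 0

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class VLSettings:
    """Optimiser settings for :func:`variational_laplace`."""

    max_iter: int = 128
    tol: float = 1e-2          # nats; convergence when dF < tol ...
    n_converged: int = 3       # ... on this many consecutive accepted steps
    fd_step: float = 1e-3      # central-difference step on the log scale
    init_damping: float = 1e-4
    max_damping: float = 1e8
    hyper_newton_iters: int = 8


@dataclass
class Posterior:
    """Approximate Gaussian posterior with its free-energy bound.

    ``mean``/``cov`` cover the full named parameter vector; structurally
    fixed entries keep their prior value with zero variance.  ``trace``
    records F at every accepted optimisation step (non-decreasing).
    """

    names: tuple
    mean: np.ndarray
    cov: np.ndarray
    free_energy: float
    trace: list
    converged: bool
    log_precision: float
    accuracy: float
    complexity: float
    predictions: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return float(self.mean[self.names.index(name)])

    def sd(self, name: str) -> float:
        i = self.names.index(name)
        return float(np.sqrt(self.cov[i, i]))


def log_evidence(post: Posterior) -> float:
    """Free-energy lower bound on ln p(y|m) in nats (final trace entry)."""
    if not post.converged:
        warnings.warn("posterior did not converge; free energy is best-so-far",
                      RuntimeWarning, stacklevel=2)
    return post.free_energy


def _fd_jacobian(forward, m, free_idx, step, forward_batch=None):
    """Central finite-difference Jacobian of ``forward`` wrt free entries.

    With ``forward_batch`` (mapping a (B, p) stack of parameter vectors to
    (B, n) predictions) all perturbed evaluations run in one vectorized
    call.
    """
    if forward_batch is not None:
        stack = np.repeat(m[None], 2 * free_idx.size, axis=0)
        for k, i in enumerate(free_idx):
            stack[2 * k, i] += step
            stack[2 * k + 1, i] -= step
        preds = forward_batch(stack)
        return ((preds[0::2] - preds[1::2]) / (2 * step)).T
    cols = []
    for i in free_idx:
        mp = m.copy(); mp[i] += step
        mm = m.copy(); mm[i] -= step
        cols.append((forward(mp) - forward(mm)) / (2 * step))
    return np.column_stack(cols)


def _free_energy(r, J, Sigma, dm_prior, Pi, ln_det_prior, lam, q_extra,
                 hyper_mean, hyper_var):
    """Negative free energy and its accuracy/complexity split."""
    n = r.size
    p_f = Sigma.shape[0]
    elam = np.exp(lam)
    q = r @ r + q_extra
    accuracy = -0.5 * n * np.log(2 * np.pi) + 0.5 * n * lam - 0.5 * elam * q
    sign, ln_det_sigma = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return -np.inf, accuracy, np.inf
    kl_theta = 0.5 * (dm_prior @ Pi @ dm_prior + np.trace(Pi @ Sigma)
                      - p_f + ln_det_prior - ln_det_sigma)
    kl_lam = 0.0
    if hyper_var > 0:
        sq = 1.0 / (0.5 * elam * q + 1.0 / hyper_var)
        kl_lam = 0.5 * (sq / hyper_var + (lam - hyper_mean) ** 2 / hyper_var
                        - 1.0 + np.log(hyper_var / sq))
    complexity = kl_theta + kl_lam
    return accuracy - complexity, accuracy, complexity


def _update_lambda(lam, r, J, Pi, hyper_mean, hyper_var, iters):
    """Maximise F over the noise log-precision by damped Newton iteration."""
    if hyper_var == 0:
        Sigma = np.linalg.inv(np.exp(lam) * (J.T @ J) + Pi)
        return lam, Sigma
    JtJ = J.T @ J
    rr = r @ r
    n = r.size
    for _ in range(iters):
        Sigma = np.linalg.inv(np.exp(lam) * JtJ + Pi)
        q = rr + np.einsum("ij,jk,ik->", J, Sigma, J)
        elam = np.exp(lam)
        grad = 0.5 * n - 0.5 * elam * q - (lam - hyper_mean) / hyper_var
        hess = -0.5 * elam * q - 1.0 / hyper_var
        step = grad / hess
        lam = lam - np.clip(step, -4.0, 4.0)
    Sigma = np.linalg.inv(np.exp(lam) * JtJ + Pi)
    return lam, Sigma


def variational_laplace(forward, y, priors: PriorSpec,
                        settings: VLSettings | None = None,
                        forward_batch=None) -> Posterior:
    """Fit ``y ≈ forward(ϑ) + ε`` by Gauss–Newton free-energy ascent.

    ``forward`` maps a full parameter vector (ordered as ``priors.names``)
    to a prediction vector; it may raise :class:`InstabilityError` for
    parameter values without a stable steady state, in which case the
    proposed step is rejected and damping increased.  ``forward_batch``
    optionally evaluates a stack of parameter vectors at once (used for
    finite-difference Jacobians).  The scheme is deterministic: no
    stochastic steps are involved.

    Candidate steps are first screened with the current Jacobian (cheap);
    promising candidates are then re-evaluated with their own Jacobian, and
    accepted only if the exact F increases — so the recorded trace is
    monotone.  ``converged`` is True when F changes fall below ``tol`` on
    consecutive accepted steps or no improving step exists within the
    damping budget; only an exhausted iteration budget leaves it False.
    """
    if settings is None:
        settings = VLSettings()
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ParameterError("data vector contains non-finite values")

    free = priors.free
    free_idx = np.flatnonzero(free)
    p_f = free_idx.size
    if p_f == 0:
        raise ParameterError("no free parameters (all prior variances zero)")
    prior_cov_f = priors.cov[np.ix_(free_idx, free_idx)]
    Pi = np.linalg.inv(prior_cov_f)
    _, ln_det_prior = np.linalg.slogdet(prior_cov_f)
    mu_f = priors.mean[free_idx]

    def evaluate(m_vec, lam_start):
        g_v = forward(m_vec)
        r_v = y - g_v
        J_v = _fd_jacobian(forward, m_vec, free_idx, settings.fd_step,
                           forward_batch)
        lam_v, Sigma_v = _update_lambda(lam_start, r_v, J_v, Pi,
                                        priors.hyper_mean, priors.hyper_var,
                                        settings.hyper_newton_iters)
        q_extra = np.einsum("ij,jk,ik->", J_v, Sigma_v, J_v)
        F_v, acc_v, comp_v = _free_energy(
            r_v, J_v, Sigma_v, m_vec[free_idx] - mu_f, Pi, ln_det_prior,
            lam_v, q_extra, priors.hyper_mean, priors.hyper_var)
        return F_v, acc_v, comp_v, g_v, r_v, J_v, lam_v, Sigma_v

    m = priors.mean.copy()
    F, acc, comp, g, r, J, lam, Sigma = evaluate(m, priors.hyper_mean)
    if g.shape != y.shape:
        raise StructuralError("forward prediction and data lengths differ")
    trace = [F]
    nu = settings.init_damping
    converged = False
    n_small = 0

    for _ in range(settings.max_iter):
        elam = np.exp(lam)
        H = elam * (J.T @ J) + Pi
        grad = elam * (J.T @ r) - Pi @ (m[free_idx] - mu_f)
        accepted = False
        while nu <= settings.max_damping:
            H_d = H + nu * np.diag(np.diag(H))
            try:
                dm = np.linalg.solve(H_d, grad)
            except np.linalg.LinAlgError:
                nu *= 10
                continue
            m_new = m.copy()
            m_new[free_idx] += dm
            # cheap screen with the current Jacobian
            try:
                g_scr = forward(m_new)
                r_scr = y - g_scr
                lam_scr, Sigma_scr = _update_lambda(
                    lam, r_scr, J, Pi, priors.hyper_mean, priors.hyper_var,
                    settings.hyper_newton_iters)
                q_extra = np.einsum("ij,jk,ik->", J, Sigma_scr, J)
                F_scr, _, _ = _free_energy(
                    r_scr, J, Sigma_scr, m_new[free_idx] - mu_f, Pi,
                    ln_det_prior, lam_scr, q_extra,
                    priors.hyper_mean, priors.hyper_var)
            except (InstabilityError, FloatingPointError):
                F_scr = -np.inf
            if not (np.isfinite(F_scr) and F_scr > F):
                nu *= 10
                continue
            # full evaluation at the candidate
            try:
                F_new, acc_new, comp_new, g_new, r_new, J_new, lam_new, \
                    Sigma_new = evaluate(m_new, lam)
            except (InstabilityError, FloatingPointError):
                F_new = -np.inf
            if np.isfinite(F_new) and F_new > F:
                dF = F_new - F
                m, g, r, J = m_new, g_new, r_new, J_new
                lam, Sigma = lam_new, Sigma_new
                F, acc, comp = F_new, acc_new, comp_new
                trace.append(F)
                nu = max(nu / 4, 1e-8)
                accepted = True
                n_small = n_small + 1 if dF < settings.tol else 0
                break
            nu *= 10
        if not accepted:
            # no improving step within the damping budget: local optimum
            converged = True
            break
        if n_small >= settings.n_converged:
            converged = True
            break

    cov_full = np.zeros((len(priors.names), len(priors.names)))
    cov_full[np.ix_(free_idx, free_idx)] = Sigma
    return Posterior(
        names=priors.names, mean=m, cov=cov_full, free_energy=F,
        trace=trace, converged=converged, log_precision=float(lam),
        accuracy=float(acc), complexity=float(comp), predictions=g,
    )
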