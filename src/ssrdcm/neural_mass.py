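"""Three-population alpha-kernel neural mass model of coupled cortical sources.

Each source holds five second-order synaptic subunits (state pairs v, g):

==========  =======================  ==========================  ========
index       subunit                  drive                       kernel
==========  =======================  ==========================  ========
0, 1        stellate                 γ2·S(V_p), extrinsic fwd/   exc.
                                     lat., endogenous input u
2, 3        pyramidal (excitatory)   γ1·S(V_s), extrinsic bwd/   exc.
                                     lat.
4, 5        pyramidal (inhibitory)   γ4·S(V_i)                   inh.
6, 7        interneuron (excit.)     γ3·S(V_p), extrinsic bwd/   exc.
                                     lat.
8, 9        interneuron (self-inh.)  γ5·S(V_i)                   inh.
==========  =======================  ==========================  ========

Population potentials are V_s = v[0], V_p = v[2] − v[4], V_i = v[6] − v[8].
Every subunit obeys the alpha-kernel second-order form

    dv/dt = g,      dg/dt = κ·H·(input firing) − 2κ·g − κ²·v,

so that an impulse of presynaptic firing produces the postsynaptic response
h(t) = H·κ·t·exp(−κt).  Firing is a centred sigmoid of the potential, which
makes the origin an exact equilibrium of the input-free system.

Intrinsic (within-source) and extrinsic (between-source) couplings carry
distinct conduction delays; the simulator applies them as integer-step lags
of the fixed-step integrator, which matches the e^{−iωτ} factors used by the
frequency-domain linearization exactly in the linear regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FixedPointError, InstabilityError, ParameterError, StructuralError
from .params import NeuralMassParams, NoiseParams

__all__ = [
    "alpha_kernel_response", "sigmoid_firing", "sigmoid_slope",
    "potentials", "state_derivatives", "find_fixed_point",
    "jacobian", "jacobian_blocks", "spectral_abscissa",
    "leadfield_matrix", "input_matrix", "colored_noise",
    "simulate_timeseries", "SimulationResult",
]

# State indices within one source block.
V_S, G_S, V_PE, G_PE, V_PI, G_PI, V_IE, G_IE, V_II, G_II = range(10)


def alpha_kernel_response(H, kappa, t):
    """Postsynaptic membrane response h(t) = H·κ·t·exp(−κt) for t ≥ 0 (mV).

    ``H`` is the maximum response amplitude (mV, attained at t = 1/κ where
    h = H/e) and ``kappa`` the synaptic rate constant (1/s).
    """
    H = np.asarray(H, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    if np.any(H <= 0) or np.any(kappa <= 0):
        raise ParameterError("alpha kernel requires H > 0 and kappa > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("alpha kernel is defined for t >= 0")
    return H * kappa * t * np.exp(-kappa * t)


def sigmoid_firing(v, rho1, rho2):
    """Centred sigmoid mapping membrane potential (mV) to normalised firing.

    S(v) = 1/(1+exp(−ρ1(v−ρ2))) − 1/(1+exp(ρ1·ρ2)), so S(0) = 0 and the
    resting state produces zero net output.  Strictly increasing in v and
    saturating in both directions.
    """
    if rho1 <= 0:
        raise ParameterError("sigmoid slope rho1 must be positive")
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp(-rho1 * (v - rho2))) - \
        1.0 / (1.0 + np.exp(rho1 * rho2))


def sigmoid_slope(v, rho1, rho2):
    """Derivative dS/dv of :func:`sigmoid_firing`."""
    if rho1 <= 0:
        raise ParameterError("sigmoid slope rho1 must be positive")
    v = np.asarray(v, dtype=float)
    s = 1.0 / (1.0 + np.exp(-rho1 * (v - rho2)))
    return rho1 * s * (1.0 - s)


def _as_blocks(x, n_sources):
    x = np.asarray(x, dtype=float)
    if x.shape != (n_sources * NeuralMassParams.STATES_PER_SOURCE,):
        raise StructuralError(
            f"state vector must have length {n_sources * 10}, got {x.shape}"
        )
    return x.reshape(n_sources, 10)


def potentials(x, n_sources):
    """Population potentials (n_sources, 3): columns V_s, V_p, V_i."""
    b = _as_blocks(x, n_sources)
    return np.column_stack([
        b[:, V_S],
        b[:, V_PE] - b[:, V_PI],
        b[:, V_IE] - b[:, V_II],
    ])


def state_derivatives(x, u, params: NeuralMassParams,
                      x_intrinsic=None, x_extrinsic=None):
    """Time derivative dx/dt of the full state vector.

    ``u`` is the endogenous/exogenous firing-rate input per source (scalar
    broadcasts).  ``x_intrinsic`` / ``x_extrinsic`` optionally supply the
    delayed states that intrinsic and extrinsic couplings read; both default
    to ``x`` (the undelayed dynamics).
    """
    n = params.n_sources
    b = _as_blocks(x, n)
    pot_i = potentials(x if x_intrinsic is None else x_intrinsic, n)
    pot_e = potentials(x if x_extrinsic is None else x_extrinsic, n)
    u = np.broadcast_to(np.asarray(u, dtype=float), (n,))
    if not np.all(np.isfinite(b)):
        raise ParameterError("state vector contains non-finite entries")

    Sv = sigmoid_firing(pot_i, params.rho1, params.rho2)       # (n, 3)
    Sp = sigmoid_firing(pot_e[:, 1], params.rho1, params.rho2)  # (n,)

    g = params.gamma
    afl = params.A_forward + params.A_lateral
    abl = params.A_backward + params.A_lateral
    ext_fwd = afl @ Sp
    ext_bwd = abl @ Sp

    I_s = g[:, 1] * Sv[:, 1] + ext_fwd + params.C * u
    I_pe = g[:, 0] * Sv[:, 0] + ext_bwd
    I_pi = g[:, 3] * Sv[:, 2]
    I_ie = g[:, 2] * Sv[:, 1] + ext_bwd
    I_ii = g[:, 4] * Sv[:, 2]

    ke, ki = params.kappa_e, params.kappa_i
    He, Hi = params.H_e, params.H_i
    d = np.empty_like(b)
    d[:, V_S] = b[:, G_S]
    d[:, G_S] = ke * He * I_s - 2 * ke * b[:, G_S] - ke ** 2 * b[:, V_S]
    d[:, V_PE] = b[:, G_PE]
    d[:, G_PE] = ke * He * I_pe - 2 * ke * b[:, G_PE] - ke ** 2 * b[:, V_PE]
    d[:, V_PI] = b[:, G_PI]
    d[:, G_PI] = ki * Hi * I_pi - 2 * ki * b[:, G_PI] - ki ** 2 * b[:, V_PI]
    d[:, V_IE] = b[:, G_IE]
    d[:, G_IE] = ke * He * I_ie - 2 * ke * b[:, G_IE] - ke ** 2 * b[:, V_IE]
    d[:, V_II] = b[:, G_II]
    d[:, G_II] = ki * Hi * I_ii - 2 * ki * b[:, G_II] - ki ** 2 * b[:, V_II]
    return d.reshape(-1)


def jacobian_blocks(params: NeuralMassParams, x_star):
    """Jacobian split by delay class: (local, intrinsic, extrinsic).

    ``local`` holds the per-subunit kernel dynamics (no coupling), applied
    instantaneously; ``intrinsic`` the within-source sigmoid couplings
    (conduction delay ``params.delay_intrinsic``); ``extrinsic`` the
    between-source couplings (delay ``params.delay_extrinsic``).  The full
    (delay-free) Jacobian is their sum.
    """
    n = params.n_sources
    ns = params.n_states
    pot = potentials(x_star, n)
    sp = sigmoid_slope(pot, params.rho1, params.rho2)       # (n, 3)
    sp_p = sp[:, 1]                                          # pyramidal
    ke, ki = params.kappa_e, params.kappa_i
    He, Hi = params.H_e, params.H_i

    J0 = np.zeros((ns, ns))
    Ji = np.zeros((ns, ns))
    Je = np.zeros((ns, ns))
    for s in range(n):
        o = 10 * s
        for v_idx, g_idx, kap in ((V_S, G_S, ke[s]), (V_PE, G_PE, ke[s]),
                                  (V_PI, G_PI, ki[s]), (V_IE, G_IE, ke[s]),
                                  (V_II, G_II, ki[s])):
            J0[o + v_idx, o + g_idx] = 1.0
            J0[o + g_idx, o + v_idx] = -kap ** 2
            J0[o + g_idx, o + g_idx] = -2 * kap

        ge, gi = ke[s] * He[s], ki[s] * Hi[s]
        g1, g2, g3, g4, g5 = params.gamma[s]
        # stellate <- pyramidal potential (gamma_2)
        Ji[o + G_S, o + V_PE] += ge * g2 * sp[s, 1]
        Ji[o + G_S, o + V_PI] -= ge * g2 * sp[s, 1]
        # pyramidal <- stellate (gamma_1)
        Ji[o + G_PE, o + V_S] += ge * g1 * sp[s, 0]
        # pyramidal <- interneuron (gamma_4, inhibitory kernel)
        Ji[o + G_PI, o + V_IE] += gi * g4 * sp[s, 2]
        Ji[o + G_PI, o + V_II] -= gi * g4 * sp[s, 2]
        # interneuron <- pyramidal (gamma_3)
        Ji[o + G_IE, o + V_PE] += ge * g3 * sp[s, 1]
        Ji[o + G_IE, o + V_PI] -= ge * g3 * sp[s, 1]
        # interneuron self-inhibition (gamma_5)
        Ji[o + G_II, o + V_IE] += gi * g5 * sp[s, 2]
        Ji[o + G_II, o + V_II] -= gi * g5 * sp[s, 2]

    afl = params.A_forward + params.A_lateral
    abl = params.A_backward + params.A_lateral
    for i in range(n):
        oi = 10 * i
        ge_i = ke[i] * He[i]
        for j in range(n):
            if i == j:
                continue
            oj = 10 * j
            w_f = ge_i * afl[i, j] * sp_p[j]
            w_b = ge_i * abl[i, j] * sp_p[j]
            # forward/lateral afferents terminate on stellate cells
            Je[oi + G_S, oj + V_PE] += w_f
            Je[oi + G_S, oj + V_PI] -= w_f
            # backward/lateral afferents terminate on pyramidal cells and
            # interneurons (extra-granular layers)
            Je[oi + G_PE, oj + V_PE] += w_b
            Je[oi + G_PE, oj + V_PI] -= w_b
            Je[oi + G_IE, oj + V_PE] += w_b
            Je[oi + G_IE, oj + V_PI] -= w_b
    return J0, Ji, Je


def jacobian(params: NeuralMassParams, x_star):
    """Full (delay-free) Jacobian ∂f/∂x at ``x_star``."""
    J0, Ji, Je = jacobian_blocks(params, x_star)
    return J0 + Ji + Je


def spectral_abscissa(params: NeuralMassParams, x_star=None) -> float:
    """Largest real part over eigenvalues of the Jacobian at the fixed point."""
    if x_star is None:
        x_star = np.zeros(params.n_states)
    return float(np.linalg.eigvals(jacobian(params, x_star)).real.max())


def find_fixed_point(params: NeuralMassParams, u0=0.0,
                     tol: float = 1e-9, max_iter: int = 100):
    """Newton search for an equilibrium state of the (undelayed) dynamics.

    With the centred sigmoid and u0 = 0 the origin is exact; for nonzero
    constant input the equilibrium is found by damped Newton iteration.
    Raises :class:`FixedPointError` carrying the last residual on failure.
    """
    n = params.n_states
    x = np.zeros(n)
    f = state_derivatives(x, u0, params)
    if np.abs(f).max() < tol:
        return x
    for _ in range(max_iter):
        J = jacobian(params, x)
        try:
            step = np.linalg.solve(J, f)
        except np.linalg.LinAlgError as exc:
            raise FixedPointError("singular Jacobian in fixed-point search",
                                  residual=float(np.abs(f).max())) from exc
        alpha = 1.0
        res0 = np.abs(f).max()
        while alpha > 1e-6:
            x_new = x - alpha * step
            f_new = state_derivatives(x_new, u0, params)
            if np.abs(f_new).max() < res0:
                break
            alpha *= 0.5
        x, f = x_new, f_new
        if np.abs(f).max() < tol:
            return x
    raise FixedPointError(
        f"fixed point not found in {max_iter} iterations",
        residual=float(np.abs(f).max()),
    )


def leadfield_matrix(params: NeuralMassParams) -> np.ndarray:
    """Observation matrix L (n_channels × n_states): channel i reads source i.

    The measured LFP is dominated by the pyramidal membrane potential; the
    stellate and interneuron populations jointly contribute the remaining
    ~20% of the response.
    """
    n = params.n_sources
    lp, ls, li = params.leadfield
    L = np.zeros((n, params.n_states))
    for s in range(n):
        o = 10 * s
        L[s, o + V_PE] = lp
        L[s, o + V_PI] = -lp
        L[s, o + V_S] = ls
        L[s, o + V_IE] = li
        L[s, o + V_II] = -li
    return L


def input_matrix(params: NeuralMassParams) -> np.ndarray:
    """Input matrix B (n_states × n_sources): innovations drive stellate cells."""
    n = params.n_sources
    B = np.zeros((params.n_states, n))
    for s in range(n):
        B[10 * s + G_S, s] = params.kappa_e[s] * params.H_e[s] * params.C[s]
    return B


def colored_noise(n_samples: int, dt: float, white: float, pink: float,
                  rng: np.random.Generator, freq_floor: float = 1.0
                  ) -> np.ndarray:
    """Gaussian noise with two-sided PSD  white + pink/max(f, freq_floor).

    Synthesised by spectrally shaping a white series in the frequency
    domain, so a long-run periodogram converges to the target density.
    """
    w = rng.standard_normal(n_samples) / np.sqrt(dt)   # two-sided PSD = 1
    if white == 0.0 and pink == 0.0:
        return np.zeros(n_samples)
    W = np.fft.rfft(w)
    f = np.fft.rfftfreq(n_samples, dt)
    psd = white + pink / np.maximum(f, freq_floor)
    W *= np.sqrt(psd)
    return np.fft.irfft(W, n_samples)


@dataclass
class SimulationResult:
    """Multichannel LFP series produced by :func:`simulate_timeseries`."""

    t: np.ndarray          # (N,) seconds, post burn-in
    data: np.ndarray       # (N, n_channels) observed LFP (mV)
    channels: tuple
    dt: float
    seed: int | None

    @property
    def fs(self) -> float:
        return 1.0 / self.dt


def simulate_timeseries(params: NeuralMassParams, noise: NoiseParams,
                        dt: float = 5e-4, duration: float = 10.0,
                        seed: int | None = None, burn_in: float = 2.0,
                        freq_floor: float = 1.0, u_mean: float = 0.0,
                        guard: float = 200.0,
                        channels: tuple | None = None) -> SimulationResult:
    """Integrate the stochastic model and observe it through the lead field.

    Fixed-step semi-implicit Euler–Maruyama at ``dt`` (default 0.5 ms),
    driven by
    white + 1/f innovations entering the stellate populations and observed
    as L·x(t) plus channel noise.  Conduction delays are applied as
    integer-step lags of the integrator.  Deterministic given ``seed``;
    raises :class:`InstabilityError` if any membrane potential exceeds
    ``guard`` mV.
    """
    n = params.n_sources
    if noise.n_sources != n:
        raise StructuralError("noise parameters do not match source count")
    if noise.n_channels != n:
        raise StructuralError(
            "one observation channel per source is required "
            f"(got {noise.n_channels} channels for {n} sources)"
        )
    n_keep = int(round(duration / dt))
    n_burn = int(round(burn_in / dt))
    n_total = n_keep + n_burn
    di = int(round(params.delay_intrinsic / dt))
    de = int(round(params.delay_extrinsic / dt))
    hist_len = max(di, de) + 1

    rng = np.random.default_rng(seed)
    u = np.empty((n_total, n))
    for s in range(n):
        u[:, s] = colored_noise(n_total, dt, noise.innovation_white[s],
                                noise.innovation_pink[s], rng, freq_floor)
    n_chan = noise.n_channels
    obs_noise = np.empty((n_total, n_chan))
    for c in range(n_chan):
        obs_noise[:, c] = colored_noise(n_total, dt, noise.channel_white[c],
                                        noise.channel_pink[c], rng, freq_floor)
    shared = colored_noise(n_total, dt, noise.shared_white,
                           noise.shared_pink, rng, freq_floor)
    obs_noise += shared[:, None]

    x_star = find_fixed_point(params, u0=u_mean)
    xb = x_star.reshape(n, 10)
    # subunit layout (n, 5): stellate, pyr-exc, pyr-inh, int-exc, int-inh
    V = xb[:, 0::2].copy()
    G = xb[:, 1::2].copy()

    ke, ki = params.kappa_e, params.kappa_i
    He, Hi = params.H_e, params.H_i
    kap = np.column_stack([ke, ke, ki, ke, ki])          # (n, 5)
    KH = kap * np.column_stack([He, He, Hi, He, Hi])
    two_kap = 2.0 * kap
    kap2 = kap ** 2
    g1, g2, g3, g4, g5 = (params.gamma[:, k] for k in range(5))
    afl = params.A_forward + params.A_lateral
    abl = params.A_backward + params.A_lateral
    C = params.C
    rho1, rho2 = params.rho1, params.rho2
    s_ref = 1.0 / (1.0 + np.exp(rho1 * rho2))

    pot0 = np.column_stack([V[:, 0], V[:, 1] - V[:, 2], V[:, 3] - V[:, 4]])
    hist = np.tile(pot0, (hist_len, 1, 1))               # (hist_len, n, 3)
    y = np.empty((n_total, n_chan))
    lp, ls, li = params.leadfield
    I = np.empty((n, 5))
    guard_check = max(1, int(round(0.05 / dt)))          # test every 50 ms

    for k in range(n_total):
        pot = np.column_stack([V[:, 0], V[:, 1] - V[:, 2], V[:, 3] - V[:, 4]])
        hist[k % hist_len] = pot
        pot_i = hist[(k - di) % hist_len]
        pot_e_p = hist[(k - de) % hist_len][:, 1]

        Sv = 1.0 / (1.0 + np.exp(-rho1 * (pot_i - rho2))) - s_ref
        Sp = 1.0 / (1.0 + np.exp(-rho1 * (pot_e_p - rho2))) - s_ref
        ext_b = abl @ Sp

        I[:, 0] = g2 * Sv[:, 1] + afl @ Sp + C * (u[k] + u_mean)
        I[:, 1] = g1 * Sv[:, 0] + ext_b
        I[:, 2] = g4 * Sv[:, 2]
        I[:, 3] = g3 * Sv[:, 1] + ext_b
        I[:, 4] = g5 * Sv[:, 2]

        y[k] = lp * pot[:, 1] + ls * pot[:, 0] + li * pot[:, 2]

        # semi-implicit Euler-Maruyama: positions first, velocities with the
        # updated positions (better damping fidelity than the explicit form)
        V += dt * G
        G += dt * (KH * I - two_kap * G - kap2 * V)

        if k % guard_check == 0 and np.abs(pot).max() > guard:
            raise InstabilityError(
                f"simulation diverged at t = {k * dt:.3f} s "
                f"(|v| > {guard} mV)"
            )

    y += obs_noise
    if channels is None:
        if n_chan == n and n <= 2:
            channels = ("A1", "PAF")[:n]
        else:
            channels = tuple(f"ch{c}" for c in range(n_chan))
    t = np.arange(n_keep) * dt
    return SimulationResult(t=t, data=y[n_burn:], channels=tuple(channels),
                            dt=dt, seed=seed)
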