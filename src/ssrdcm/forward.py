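"""Model cross-spectral densities from the linearized neural mass model.

The observed spectrum is predicted through the modulation transfer function
of the linearization around the model's stable fixed point,

    G_y(f) = T(f) · diag(G_u(f)) · T(f)^H + G_channel(f),

where T(f) = L (i2πf·I − J(f))⁻¹ B maps per-source innovations to observed
channels, J(f) carries conduction delays as e^{−i2πfτ} factors on the
intrinsic and extrinsic coupling blocks, and the innovation and channel
noise spectra mix white and 1/f components.
"""

from __future__ import annotations

import numpy as np

from . import neural_mass as nm
from .containers import CrossSpectra
from .errors import InstabilityError
from .params import (EFFECT_PARAMS, ConditionEffects, NeuralMassParams,
                     NoiseParams, REGIONS)

__all__ = ["apply_condition_effects", "transfer_function", "predict_csd",
           "default_freqs"]


def default_freqs(fmin: float = 1.0, fmax: float = 30.0,
                  df: float = 1.0) -> np.ndarray:
    """The analysis frequency grid, 1–30 Hz at 1 Hz by default."""
    return np.arange(fmin, fmax + df / 2, df)


def apply_condition_effects(params: NeuralMassParams,
                            effects: ConditionEffects,
                            condition: float) -> NeuralMassParams:
    """Scale the drug-sensitive parameters for one experimental condition.

    Per region: H_e ← H_e·exp(b_He), H_i ← H_i·exp(b_Hi),
    κ_i ← κ_i·exp(b_κi); everything else untouched.  The baseline condition
    has all coefficients fixed at zero and returns the parameters unchanged.
    """
    c = effects.condition_index(condition)   # raises KeyError if unknown
    out = params.copy()
    scale = np.exp(effects.b[c])             # (n_regions, 3)
    out.H_e = out.H_e * scale[:, EFFECT_PARAMS.index("H_e")]
    out.H_i = out.H_i * scale[:, EFFECT_PARAMS.index("H_i")]
    out.kappa_i = out.kappa_i * scale[:, EFFECT_PARAMS.index("kappa_i")]
    return out


def transfer_function(params: NeuralMassParams, freqs,
                      x_star: np.ndarray | None = None) -> np.ndarray:
    """Channel × innovation-source frequency response T(f).

    Returns a complex array (n_freqs, n_channels, n_sources).  Raises
    :class:`InstabilityError` when the delay-free Jacobian has a
    nonnegative spectral abscissa (no stable equilibrium to linearize
    about).
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if x_star is None:
        x_star = nm.find_fixed_point(params, u0=0.0)
    J0, Ji, Je = nm.jacobian_blocks(params, x_star)
    abscissa = float(np.linalg.eigvals(J0 + Ji + Je).real.max())
    if abscissa >= 0:
        raise InstabilityError(
            f"unstable linearization (spectral abscissa {abscissa:.3g})",
            spectral_abscissa=abscissa,
        )
    w = 2 * np.pi * freqs
    ph_i = np.exp(-1j * w * params.delay_intrinsic)[:, None, None]
    ph_e = np.exp(-1j * w * params.delay_extrinsic)[:, None, None]
    ns = params.n_states
    M = (1j * w)[:, None, None] * np.eye(ns)[None] \
        - (J0[None] + Ji[None] * ph_i + Je[None] * ph_e)
    B = nm.input_matrix(params)
    X = np.linalg.solve(M, np.broadcast_to(B, (freqs.size, ns, B.shape[1])))
    L = nm.leadfield_matrix(params)
    return np.einsum("cn,fns->fcs", L, X)


def _one_over_f(freqs: np.ndarray, freq_floor: float) -> np.ndarray:
    return 1.0 / np.maximum(freqs, freq_floor)


def innovation_spectra(noise: NoiseParams, freqs,
                       freq_floor: float = 1.0) -> np.ndarray:
    """Per-source innovation PSD G_u(f) = white + pink/max(f, floor)."""
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    inv_f = _one_over_f(freqs, freq_floor)
    return noise.innovation_white[None, :] + \
        np.outer(inv_f, noise.innovation_pink)


def channel_noise_spectra(noise: NoiseParams, freqs,
                          freq_floor: float = 1.0) -> np.ndarray:
    """Observation-noise CSD (n_freqs, C, C): per-channel plus shared parts."""
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    inv_f = _one_over_f(freqs, freq_floor)
    c = noise.n_channels
    own = noise.channel_white[None, :] + np.outer(inv_f, noise.channel_pink)
    G = np.zeros((freqs.size, c, c))
    G[:, np.arange(c), np.arange(c)] = own
    G += (noise.shared_white + noise.shared_pink * inv_f)[:, None, None] \
        * np.ones((c, c))
    return G


def predict_csd(params: NeuralMassParams, noise: NoiseParams,
                freqs=None, effects: ConditionEffects | None = None,
                condition: float | None = None, freq_floor: float = 1.0,
                channels: tuple | None = None,
                metadata: dict | None = None) -> CrossSpectra:
    """Predicted cross-spectral densities of the observed channels.

    When ``effects`` and ``condition`` are given, the condition-specific
    parameter scaling is applied first and the linearization re-evaluated
    (with zero mean input the fixed point stays at the origin, but the
    Jacobian changes with the scaled synaptic gains).
    """
    if freqs is None:
        freqs = default_freqs()
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if effects is not None:
        if condition is None:
            raise ValueError("condition label required with condition effects")
        params = apply_condition_effects(params, effects, condition)
    T = transfer_function(params, freqs)
    Gu = innovation_spectra(noise, freqs, freq_floor)      # (F, S)
    G = np.einsum("fcs,fs,fds->fcd", T, Gu, T.conj())
    G = G + channel_noise_spectra(noise, freqs, freq_floor)
    G = 0.5 * (G + G.conj().transpose(0, 2, 1))            # exact Hermitian
    if channels is None:
        channels = REGIONS[:params.n_sources] if params.n_sources <= 2 \
            else tuple(f"src{j}" for j in range(params.n_sources))
    md = dict(metadata or {})
    if condition is not None:
        md.setdefault("dose", condition)
    return CrossSpectra(freqs=freqs, values=G, channels=channels, metadata=md)
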