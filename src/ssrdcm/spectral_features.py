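"""Empirical cross-spectral densities from multichannel LFP series.

Recorded (or simulated) series are reduced to quasi-steady-state spectral
summaries in two steps: a vector autoregression of order p (default 8) is
fitted to the down-sampled, mean-removed epoch, and its coefficients are
mapped to cross-spectral densities through

    S(f) = Δ · A(f)⁻¹ E A(f)⁻ᴴ,   A(f) = I − Σ_{n=1..p} A^(n) e^{−i 2π f n Δ},

with Δ the sampling interval and E the innovation covariance.  Band-power
summaries use the conventional delta/theta/alpha/beta bins.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .containers import CrossSpectra, VARModel
from .errors import EstimationError, ParameterError, StructuralError

__all__ = ["preprocess", "fit_var", "var_to_csd", "band_power", "BANDS",
           "series_to_csd"]

#: Conventional EEG frequency bands (Hz); intervals are half-open [lo, hi).
BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 16.0),
    "beta": (16.0, 30.0),
}


def preprocess(series: np.ndarray, fs_in: float, fs_out: float = 125.0,
               epoch_seconds: float = 600.0) -> np.ndarray:
    """Extract, down-sample and demean an analysis epoch.

    The first ``epoch_seconds`` of the recording are kept, anti-alias
    filtered and resampled from ``fs_in`` to ``fs_out`` (polyphase
    resampling; non-integer ratios are handled through their rational
    approximation), and each channel's mean is removed.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.shape[0] == 1 and series.size > series.shape[1]:
        series = series.T
    if series.ndim != 2:
        raise StructuralError("series must be a (samples, channels) matrix")
    n_needed = int(round(epoch_seconds * fs_in))
    if series.shape[0] < n_needed:
        raise EstimationError(
            f"recording shorter than the requested epoch: "
            f"{series.shape[0]} < {n_needed} samples"
        )
    epoch = series[:n_needed]
    ratio = Fraction(fs_out / fs_in).limit_denominator(1000)
    if ratio != 1:
        # mean-padding avoids edge ripple on signals with a DC offset
        epoch = sps.resample_poly(epoch, ratio.numerator, ratio.denominator,
                                  axis=0, padtype="mean")
    return epoch - epoch.mean(axis=0, keepdims=True)


def fit_var(series: np.ndarray, p: int = 8, dt: float = 1.0 / 125.0,
            channels: tuple | None = None) -> VARModel:
    """Least-squares VAR(p) fit of a multichannel series.

    Uses ordinary least squares with an intercept (discarded afterwards;
    the series is expected to be mean-removed already, the intercept only
    guards against residual drift).  The innovation covariance is the
    residual covariance.  Deterministic: no randomness is involved.
    """
    from statsmodels.tsa.api import VAR as _VAR

    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise StructuralError("series must be a (samples, channels) matrix")
    T, k = series.shape
    if T <= p * k + p + 1:
        raise EstimationError(f"series too short (T={T}) for VAR({p}) in {k} channels")
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(k))
    try:
        res = _VAR(series).fit(maxlags=p, ic=None, trend="c")
    except np.linalg.LinAlgError as exc:
        raise EstimationError("rank-deficient regressor matrix in VAR fit") from exc
    coefs = np.asarray(res.coefs)             # (p, k, k)
    # residual covariance without the small-sample dof adjustment
    resid = np.asarray(res.resid)
    E = resid.T @ resid / resid.shape[0]
    return VARModel(coefs=coefs, noise_cov=E, dt=dt, channels=tuple(channels))


def var_to_csd(model: VARModel, freqs) -> CrossSpectra:
    """Cross-spectral densities of a stationary VAR model on a frequency grid.

    Implements S(f) = Δ·A(f)⁻¹ E A(f)⁻ᴴ.  Raises if the model is
    non-stationary or A(f) is numerically singular at a grid frequency.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if not model.is_stationary():
        raise EstimationError("VAR model is not stationary; spectrum undefined")
    k = model.n_channels
    p = model.order
    A = np.tile(np.eye(k, dtype=complex), (freqs.size, 1, 1))
    for nlag in range(1, p + 1):
        phase = np.exp(-1j * 2 * np.pi * freqs * nlag * model.dt)
        A -= phase[:, None, None] * model.coefs[nlag - 1][None]
    values = np.empty_like(A)
    for i, f in enumerate(freqs):
        try:
            Ainv = np.linalg.inv(A[i])
        except np.linalg.LinAlgError as exc:
            raise EstimationError(
                f"VAR spectral factor singular at {f:g} Hz") from exc
        values[i] = model.dt * Ainv @ model.noise_cov @ Ainv.conj().T
    values = 0.5 * (values + values.conj().transpose(0, 2, 1))
    return CrossSpectra(freqs=freqs, values=values, channels=model.channels)


def band_power(csd: CrossSpectra, band, mode: str = "mean") -> np.ndarray:
    """Band summary of |S_ij| per channel pair over grid points in [lo, hi).

    ``band`` is a (lo, hi) pair in Hz or a named band from :data:`BANDS`.
    ``mode="mean"`` averages |S| over the included grid points;
    ``mode="integral"`` integrates (trapezoid over the included grid).
    """
    if isinstance(band, str):
        try:
            band = BANDS[band]
        except KeyError:
            raise ParameterError(f"unknown band name {band!r}") from None
    lo, hi = band
    if not (lo < hi):
        raise ParameterError("band must satisfy lo < hi")
    mask = (csd.freqs >= lo) & (csd.freqs < hi)
    if not mask.any():
        raise ParameterError(f"no grid frequencies in band [{lo}, {hi})")
    mag = np.abs(csd.values[mask])
    if mode == "mean":
        return mag.mean(axis=0)
    if mode == "integral":
        if mask.sum() == 1:
            return mag[0]
        return np.trapezoid(mag, csd.freqs[mask], axis=0)
    raise ParameterError(f"unknown band_power mode {mode!r}")


def series_to_csd(series: np.ndarray, fs_in: float, freqs=None,
                  fs_out: float = 125.0, epoch_seconds: float = 600.0,
                  order: int = 8, channels: tuple | None = None,
                  metadata: dict | None = None,
                  n_segments: int = 1) -> CrossSpectra:
    """Full data-feature path: preprocess → VAR(order) → CSD on ``freqs``.

    With ``n_segments > 1`` the epoch is split into equal sub-epochs, a VAR
    is fitted per segment and the resulting spectra averaged.
    """
    from .forward import default_freqs
    if freqs is None:
        freqs = default_freqs()
    x = preprocess(series, fs_in, fs_out=fs_out, epoch_seconds=epoch_seconds)
    dt = 1.0 / fs_out
    if n_segments <= 1:
        model = fit_var(x, p=order, dt=dt, channels=channels)
        csd = var_to_csd(model, freqs)
    else:
        parts = np.array_split(x, n_segments, axis=0)
        acc = None
        for part in parts:
            model = fit_var(part - part.mean(axis=0, keepdims=True),
                            p=order, dt=dt, channels=channels)
            v = var_to_csd(model, freqs).values
            acc = v if acc is None else acc + v
        csd = CrossSpectra(freqs=np.asarray(freqs, dtype=float),
                           values=acc / n_segments,
                           channels=channels or tuple(f"ch{i}" for i in
                                                      range(x.shape[1])))
    csd.metadata = dict(metadata or {})
    return csd
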