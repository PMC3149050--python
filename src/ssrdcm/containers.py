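"""Data containers shared across the pipeline: cross-spectra and VAR models."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, StructuralError


@dataclass
class CrossSpectra:
    """Hermitian cross-spectral density matrices on a frequency grid.

    ``values[k]`` is the n_chan × n_chan complex CSD matrix at
    ``freqs[k]`` (Hz), in two-sided power-density units (signal²/Hz).
    ``metadata`` carries recording labels (animal, hemisphere, dose,
    stimulus environment, ...).
    """

    freqs: np.ndarray                  # (F,) Hz
    values: np.ndarray                 # (F, C, C) complex
    channels: tuple = ("A1", "PAF")
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 3 or self.values.shape[0] != self.freqs.size:
            raise StructuralError("values must have shape (n_freqs, C, C)")
        if self.values.shape[1] != self.values.shape[2]:
            raise StructuralError("CSD matrices must be square")
        if len(self.channels) != self.values.shape[1]:
            raise StructuralError("channel names do not match matrix size")
        self.channels = tuple(self.channels)

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def validate(self, hermitian_tol: float = 1e-8, psd_tol: float = 1e-10):
        """Check Hermitian symmetry, strictly positive diagonal and PSD-ness."""
        v = self.values
        herm_err = np.abs(v - v.conj().transpose(0, 2, 1)).max()
        if herm_err > hermitian_tol * max(1.0, np.abs(v).max()):
            raise ParameterError(f"CSD not Hermitian (max asymmetry {herm_err:g})")
        diag = np.diagonal(v, axis1=1, axis2=2)
        if np.any(np.abs(diag.imag) > hermitian_tol * np.abs(diag).max()):
            raise ParameterError("CSD diagonal must be real")
        if np.any(diag.real <= 0):
            raise ParameterError("auto-spectra must be strictly positive")
        sym = 0.5 * (v + v.conj().transpose(0, 2, 1))
        eig = np.linalg.eigvalsh(sym)
        scale = max(np.abs(eig).max(), 1e-300)
        if eig.min() < -psd_tol * scale:
            raise ParameterError(
                f"CSD not positive semidefinite (min eigenvalue {eig.min():g})"
            )
        return self

    def auto(self, channel) -> np.ndarray:
        """Real auto-spectrum of one channel (by name or index)."""
        i = channel if isinstance(channel, int) else self.channels.index(channel)
        return self.values[:, i, i].real

    def to_frame(self) -> pd.DataFrame:
        """Flatten to tidy rows (freq, chan_i, chan_j, re, im)."""
        rows = []
        for k, f in enumerate(self.freqs):
            for i, ci in enumerate(self.channels):
                for j, cj in enumerate(self.channels):
                    rows.append((f, ci, cj,
                                 self.values[k, i, j].real,
                                 self.values[k, i, j].imag))
        return pd.DataFrame(rows, columns=["freq", "chan_i", "chan_j", "re", "im"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metadata: dict | None = None
                   ) -> "CrossSpectra":
        channels = tuple(pd.unique(df["chan_i"]))
        freqs = np.sort(pd.unique(df["freq"]))
        c = len(channels)
        values = np.zeros((freqs.size, c, c), dtype=complex)
        fidx = {f: k for k, f in enumerate(freqs)}
        cidx = {name: i for i, name in enumerate(channels)}
        for row in df.itertuples(index=False):
            values[fidx[row.freq], cidx[row.chan_i], cidx[row.chan_j]] = \
                row.re + 1j * row.im
        return cls(freqs=freqs, values=values, channels=channels,
                   metadata=dict(metadata or {}))


@dataclass
class VARModel:
    """Order-p vector autoregression y_t = Σ_n A^(n) y_{t−n} + ε_t.

    ``coefs``: (p, C, C) coefficient matrices; ``noise_cov``: innovation
    covariance E (C, C); ``dt``: sampling interval Δ in seconds.
    """

    coefs: np.ndarray
    noise_cov: np.ndarray
    dt: float
    channels: tuple = ("A1", "PAF")

    def __post_init__(self):
        self.coefs = np.asarray(self.coefs, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if self.coefs.ndim != 3 or self.coefs.shape[1] != self.coefs.shape[2]:
            raise StructuralError("coefs must have shape (p, C, C)")
        c = self.coefs.shape[1]
        if self.noise_cov.shape != (c, c):
            raise StructuralError("noise_cov shape does not match coefficients")
        if self.dt <= 0:
            raise ParameterError("sampling interval must be positive")
        if np.abs(self.noise_cov - self.noise_cov.T).max() > \
                1e-8 * max(1.0, np.abs(self.noise_cov).max()):
            raise ParameterError("innovation covariance must be symmetric")
        if np.linalg.eigvalsh(0.5 * (self.noise_cov + self.noise_cov.T)).min() < \
                -1e-10 * max(1.0, np.abs(self.noise_cov).max()):
            raise ParameterError("innovation covariance must be PSD")

    @property
    def order(self) -> int:
        return self.coefs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coefs.shape[1]

    def companion(self) -> np.ndarray:
        p, c = self.order, self.n_channels
        if p == 0:
            return np.zeros((0, 0))
        comp = np.zeros((p * c, p * c))
        comp[:c, :] = np.concatenate(list(self.coefs), axis=1)
        if p > 1:
            comp[c:, :-c] = np.eye((p - 1) * c)
        return comp

    def is_stationary(self) -> bool:
        if self.order == 0:
            return True
        return bool(np.abs(np.linalg.eigvals(self.companion())).max() < 1.0)
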