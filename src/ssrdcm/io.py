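"""File I/O: time series, cross-spectra, posteriors, configs and manifests.

All on-disk formats are plain text: tab-separated series with a JSON
metadata sidecar, JSON containers for spectra and posteriors (with a CSV
flattening for interoperability), YAML configs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .containers import CrossSpectra
from .errors import StructuralError
from .inversion import Posterior

__all__ = ["write_timeseries", "read_timeseries", "write_csd", "read_csd",
           "write_posterior", "read_posterior", "load_config", "save_config",
           "config_hash"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_timeseries(path, data: np.ndarray, channels, fs: float,
                     metadata: dict | None = None) -> Path:
    """Write a (samples, channels) series as TSV plus a JSON sidecar.

    The sidecar records the sampling rate and any recording metadata
    (seed/spawn key, dose, environment, ...).
    """
    path = Path(path)
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != len(channels):
        raise StructuralError("data shape does not match channel names")
    header = "\t".join(channels)
    np.savetxt(path, data, delimiter="\t", header=header, comments="")
    meta = {"fs": float(fs), "channels": list(channels),
            **(metadata or {})}
    _sidecar(path).write_text(json.dumps(meta, indent=1, default=str))
    return path


def read_timeseries(path):
    """Read a TSV series and its sidecar; returns (data, metadata).

    Errors on a missing sidecar (naming the expected file), NaN values, or
    a header/column-count mismatch.
    """
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise StructuralError(f"missing metadata sidecar: {side}")
    meta = json.loads(side.read_text())
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    if data.shape[1] != len(header):
        raise StructuralError(
            f"header lists {len(header)} channels but data has "
            f"{data.shape[1]} columns")
    if list(header) != list(meta.get("channels", header)):
        raise StructuralError("header channels disagree with sidecar")
    if np.isnan(data).any():
        raise StructuralError(f"NaN values in {path}")
    return data, meta


def write_csd(path, csd: CrossSpectra) -> Path:
    """JSON container: frequency vector, stacked real/imag matrices,
    metadata."""
    path = Path(path)
    payload = {
        "freqs": csd.freqs.tolist(),
        "channels": list(csd.channels),
        "re": csd.values.real.tolist(),
        "im": csd.values.imag.tolist(),
        "metadata": csd.metadata,
    }
    path.write_text(json.dumps(payload, default=str))
    return path


def read_csd(path) -> CrossSpectra:
    payload = json.loads(Path(path).read_text())
    values = np.asarray(payload["re"]) + 1j * np.asarray(payload["im"])
    return CrossSpectra(freqs=np.asarray(payload["freqs"]), values=values,
                        channels=tuple(payload["channels"]),
                        metadata=payload.get("metadata", {}))


def csd_to_csv(path, csd: CrossSpectra) -> Path:
    """Documented CSV flattening (freq, chan_i, chan_j, re, im)."""
    path = Path(path)
    csd.to_frame().to_csv(path, index=False)
    return path


def write_posterior(path, post: Posterior) -> Path:
    path = Path(path)
    payload = {
        "names": list(post.names),
        "mean": post.mean.tolist(),
        "cov": post.cov.tolist(),
        "free_energy": post.free_energy,
        "trace": list(post.trace),
        "converged": bool(post.converged),
        "log_precision": post.log_precision,
        "accuracy": post.accuracy,
        "complexity": post.complexity,
        "metadata": post.metadata,
    }
    path.write_text(json.dumps(payload, default=str))
    return path


def read_posterior(path) -> Posterior:
    payload = json.loads(Path(path).read_text())
    return Posterior(
        names=tuple(payload["names"]),
        mean=np.asarray(payload["mean"]),
        cov=np.asarray(payload["cov"]),
        free_energy=float(payload["free_energy"]),
        trace=list(payload["trace"]),
        converged=bool(payload["converged"]),
        log_precision=float(payload["log_precision"]),
        accuracy=float(payload["accuracy"]),
        complexity=float(payload["complexity"]),
        metadata=payload.get("metadata", {}),
    )


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(path, cfg: dict) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return path


def config_hash(cfg: dict) -> str:
    """Stable hash of a config dict (invariant to key ordering)."""
    blob = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
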