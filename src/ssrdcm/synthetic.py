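"""Synthetic study generator with known ground truth.

Emulates the study design the pipeline targets: seven animals (three
recorded bilaterally, giving ten recording sites), four anaesthetic dose
levels and two stimulus environments (broadband noise vs silence), with
dose-dependent modulation of synaptic parameters — a linear decrease of
EPSP amplitude, a saturating (linear + negative quadratic) increase of IPSP
amplitude and an unchanged inhibitory rate constant — and pink-dominated
innovations producing prominent low-frequency spectral power that declines
with dose.

Every recording can be produced either as a simulated LFP time series
(``mode="timeseries"``) or directly as cross-spectral densities with
finite-sample Wishart noise (``mode="spectra"``).  Per-recording random
streams are derived from the master seed with a counter-based spawn scheme,
so adding animals or conditions does not reshuffle existing recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CrossSpectra
from .errors import InstabilityError, ParameterError
from .forward import apply_condition_effects, default_freqs, predict_csd
from .neural_mass import SimulationResult, simulate_timeseries, spectral_abscissa
from .params import (ConditionEffects, DOSES, NoiseParams, REGIONS,
                     default_noise, default_params)

__all__ = ["StudyConfig", "GroundTruth", "sample_ground_truth",
           "generate_study", "StudyData"]


@dataclass
class StudyConfig:
    """Design and ground-truth parameters of a synthetic study.

    Dose-response curves are parameterised on the shifted dose
    u = dose − baseline (% isoflurane), as log-scaling effects relative to
    the baseline condition:

    * H_e:  b(u) = he_slope·u                       (linear decrease)
    * H_i:  b(u) = hi_linear·u + hi_quad·u²         (saturating increase)
    * κ_i:  b(u) = ki_slope·u                       (flat by default)

    Animal-level variability perturbs each curve coefficient per animal and
    region (Gaussian, the ``*_sd`` fields).  The noise environment scales
    innovation amplitudes by ``noise_env_gain`` relative to silence.
    """

    seed: int
    n_animals: int = 7
    n_dual: int = 3
    doses: tuple = DOSES
    environments: tuple = ("noise", "silence")
    architecture: str = "FB"
    he_slope: float = -0.5
    he_slope_sd: float = 0.1
    hi_linear: float = 1.2
    hi_linear_sd: float = 0.2
    hi_quad: float = -0.55
    hi_quad_sd: float = 0.1
    ki_slope: float = 0.0
    ki_slope_sd: float = 0.0
    noise_env_gain: float = 1.5
    epoch_seconds: float = 600.0
    sim_dt: float = 5e-4
    wishart_dof: int = 64
    param_overrides: dict | None = None
    noise_overrides: dict | None = None
    max_resample: int = 20

    def __post_init__(self):
        if self.seed is None:
            raise ParameterError("a seed is mandatory for a synthetic study")
        if self.n_animals < 3:
            raise ParameterError("need at least 3 animals")
        if self.n_dual > self.n_animals:
            raise ParameterError("more bilateral animals than animals")
        if tuple(sorted(self.doses)) != tuple(self.doses) or \
                len(set(self.doses)) != len(self.doses):
            raise ParameterError("doses must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return self.n_animals + self.n_dual

    def animal_ids(self) -> list:
        return [f"a{i + 1}" for i in range(self.n_animals)]

    def hemispheres(self, animal_index: int) -> tuple:
        return ("L", "R") if animal_index < self.n_dual else ("L",)


@dataclass
class GroundTruth:
    """Everything needed to regenerate a dataset bit-identically."""

    config: StudyConfig
    curves: dict                    # (animal, region) -> coefficient dict
    effects: dict                   # animal -> ConditionEffects
    base_params: object
    base_noise: NoiseParams
    n_resampled: int = 0

    def curve_frame(self) -> pd.DataFrame:
        rows = []
        for (animal, region), c in self.curves.items():
            rows.append({"animal": animal, "region": region, **c})
        return pd.DataFrame(rows)


def _sub_rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-based per-recording stream from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=key))


def _effects_from_curves(config: StudyConfig, curves_by_region: dict
                         ) -> ConditionEffects:
    doses = np.asarray(config.doses)
    u = doses - doses.min()
    b = np.zeros((len(doses), len(REGIONS), 3))
    for r, region in enumerate(REGIONS):
        c = curves_by_region[region]
        b[:, r, 0] = c["he_slope"] * u
        b[:, r, 1] = c["hi_linear"] * u + c["hi_quad"] * u ** 2
        b[:, r, 2] = c["ki_slope"] * u
    return ConditionEffects(doses=tuple(config.doses), regions=REGIONS, b=b)


def sample_ground_truth(config: StudyConfig) -> GroundTruth:
    """Draw per-animal dose-response curves around the population curves.

    Unstable draws (any dose condition whose linearization has a
    nonnegative spectral abscissa) are resampled, with the count recorded.
    """
    base_params = default_params(config.architecture,
                                 overrides=config.param_overrides)
    noise_kwargs = dict(config.noise_overrides or {})
    base_noise = default_noise(base_params.n_sources, **noise_kwargs)

    curves, effects = {}, {}
    n_resampled = 0
    for a_idx, animal in enumerate(config.animal_ids()):
        rng = _sub_rng(config.seed, 0, a_idx)
        for attempt in range(config.max_resample + 1):
            by_region = {}
            for region in REGIONS:
                by_region[region] = {
                    "he_slope": config.he_slope
                    + config.he_slope_sd * rng.standard_normal(),
                    "hi_linear": config.hi_linear
                    + config.hi_linear_sd * rng.standard_normal(),
                    "hi_quad": config.hi_quad
                    + config.hi_quad_sd * rng.standard_normal(),
                    "ki_slope": config.ki_slope
                    + config.ki_slope_sd * rng.standard_normal(),
                }
            eff = _effects_from_curves(config, by_region)
            stable = all(
                spectral_abscissa(
                    apply_condition_effects(base_params, eff, dose)) < 0
                for dose in config.doses
            )
            if stable:
                break
            n_resampled += 1
        else:
            raise InstabilityError(
                f"could not draw stable effects for {animal} in "
                f"{config.max_resample} attempts")
        for region in REGIONS:
            curves[(animal, region)] = by_region[region]
        effects[animal] = eff
    return GroundTruth(config=config, curves=curves, effects=effects,
                       base_params=base_params, base_noise=base_noise,
                       n_resampled=n_resampled)


def _env_noise(base_noise: NoiseParams, environment: str,
               gain: float) -> NoiseParams:
    nz = base_noise.copy()
    if environment == "noise":
        nz.innovation_white = nz.innovation_white * gain
        nz.innovation_pink = nz.innovation_pink * gain
    return nz


def _wishart_csd(csd: CrossSpectra, dof: int,
                 rng: np.random.Generator) -> CrossSpectra:
    """Finite-sample spectral estimate: complex Wishart perturbation.

    Emulates the sampling variability of an empirical CSD estimated from
    ``dof`` effectively independent spectral samples per frequency:
    Ŝ = (1/ν)·Σ_k z_k z_kᴴ with z_k ~ CN(0, S), independent across
    frequencies.
    """
    values = np.empty_like(csd.values)
    c = csd.n_channels
    for k in range(csd.freqs.size):
        S = csd.values[k]
        jitter = 1e-12 * np.trace(S).real / c
        Lc = np.linalg.cholesky(S + jitter * np.eye(c))
        Z = Lc @ ((rng.standard_normal((c, dof))
                   + 1j * rng.standard_normal((c, dof))) / np.sqrt(2))
        values[k] = Z @ Z.conj().T / dof
    return CrossSpectra(freqs=csd.freqs.copy(), values=values,
                        channels=csd.channels, metadata=dict(csd.metadata))


@dataclass
class StudyData:
    """In-memory synthetic dataset: per-recording records plus ground truth."""

    records: list
    manifest: pd.DataFrame
    truth: GroundTruth
    mode: str


def generate_study(config: StudyConfig, mode: str = "spectra",
                   freqs=None) -> StudyData:
    """Generate the full synthetic study.

    ``mode="timeseries"`` simulates each recording's multichannel LFP with
    the stochastic integrator (sampled at 1/sim_dt); ``mode="spectra"``
    predicts each recording's CSD analytically and applies the Wishart
    finite-sample perturbation.  Each record is a dict with keys ``id``,
    ``animal``, ``hemisphere``, ``dose``, ``environment`` and either
    ``series`` (:class:`SimulationResult`) or ``csd``
    (:class:`CrossSpectra`).
    """
    if mode not in ("timeseries", "spectra"):
        raise ParameterError(f"unknown generation mode {mode!r}")
    if freqs is None:
        freqs = default_freqs()
    truth = sample_ground_truth(config)
    records = []
    rows = []
    for a_idx, animal in enumerate(config.animal_ids()):
        for h_idx, hemi in enumerate(config.hemispheres(a_idx)):
            for d_idx, dose in enumerate(config.doses):
                for e_idx, env in enumerate(config.environments):
                    key = (1, a_idx, h_idx, d_idx, e_idx)
                    rec_id = f"{animal}_{hemi}_{dose:g}_{env}"
                    params_d = apply_condition_effects(
                        truth.base_params, truth.effects[animal], dose)
                    noise_d = _env_noise(truth.base_noise, env,
                                         config.noise_env_gain)
                    meta = {"animal": animal, "hemisphere": hemi,
                            "dose": dose, "environment": env}
                    record = {"id": rec_id, "spawn_key": key, **meta}
                    if mode == "timeseries":
                        seed_seq = np.random.SeedSequence(
                            entropy=config.seed, spawn_key=key)
                        record["series"] = simulate_timeseries(
                            params_d, noise_d, dt=config.sim_dt,
                            duration=config.epoch_seconds,
                            seed=seed_seq)
                    else:
                        rng = _sub_rng(config.seed, *key)
                        clean = predict_csd(params_d, noise_d, freqs,
                                            metadata=meta)
                        record["csd"] = _wishart_csd(
                            clean, config.wishart_dof, rng)
                    records.append(record)
                    rows.append({"id": rec_id, **meta,
                                 "spawn_key": str(key), "mode": mode})
    manifest = pd.DataFrame(rows)
    return StudyData(records=records, manifest=manifest, truth=truth,
                     mode=mode)
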