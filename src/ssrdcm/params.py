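"""Parameter containers for the three-population neural mass model.

Each cortical source is a layered macrocolumn with three interacting
populations: excitatory spiny stellate cells (granular layer IV), excitatory
pyramidal cells and inhibitory interneurons (extra-granular layers).
Synaptic responses are alpha kernels h(t) = H·κ·t·exp(−κt), parameterised by
their maximum amplitude H (mV) and rate constant κ (1/s).  Sources are
coupled by forward, backward and lateral connections distinguished by the
populations they terminate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError, StructuralError

#: Canonical region names for the two-source auditory hierarchy.
REGIONS = ("A1", "PAF")

#: Isoflurane dose levels (%), lowest is the baseline condition.
DOSES = (1.4, 1.8, 2.4, 2.8)

#: Condition-sensitive synaptic parameters (log-scaled per condition).
EFFECT_PARAMS = ("H_e", "H_i", "kappa_i")

ARCHITECTURES = ("FB", "BF", "LL")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Extrinsic wiring hypothesis for a two-source hierarchy.

    tag
        ``FB``: forward A1→PAF, backward PAF→A1 (the anatomically expected
        hierarchy); ``BF``: the reverse; ``LL``: reciprocal lateral coupling.

    Connection matrices follow the target-row convention: ``mask[i, j] = 1``
    means a connection from source ``j`` to source ``i``.  Forward
    connections terminate on granular-layer stellate cells, backward
    connections on extra-granular pyramidal cells and interneurons, lateral
    connections on all three populations.
    """

    tag: str
    n_sources: int = 2

    def __post_init__(self):
        if self.tag not in ARCHITECTURES:
            raise StructuralError(f"unknown architecture tag {self.tag!r}")
        if self.n_sources != 2:
            raise StructuralError("only the two-source A1/PAF network is supported")

    @property
    def forward_mask(self) -> np.ndarray:
        m = np.zeros((self.n_sources, self.n_sources))
        if self.tag == "FB":
            m[1, 0] = 1.0  # A1 -> PAF
        elif self.tag == "BF":
            m[0, 1] = 1.0  # PAF -> A1
        return m

    @property
    def backward_mask(self) -> np.ndarray:
        m = np.zeros((self.n_sources, self.n_sources))
        if self.tag == "FB":
            m[0, 1] = 1.0  # PAF -> A1
        elif self.tag == "BF":
            m[1, 0] = 1.0  # A1 -> PAF
        return m

    @property
    def lateral_mask(self) -> np.ndarray:
        m = np.zeros((self.n_sources, self.n_sources))
        if self.tag == "LL":
            m[0, 1] = m[1, 0] = 1.0
        return m


# Default biophysical values.  These are configuration, not physics: they sit
# in the middle of the plausible ranges used for this model family and every
# one of them can be overridden through the config machinery.
DEFAULTS = {
    "H_e": 8.0,        # mV, max EPSP amplitude
    "H_i": 32.0,       # mV, max IPSP amplitude
    "kappa_e": 250.0,  # 1/s  (4 ms excitatory time constant)
    "kappa_i": 62.5,   # 1/s  (16 ms inhibitory time constant)
    "gamma": (128.0, 128.0, 64.0, 64.0, 16.0),
    "rho1": 2.0,
    "rho2": 1.0,
    "forward_strength": 32.0,
    "backward_strength": 16.0,
    "lateral_strength": 16.0,
    "input_gain": 1.0,
    "delay_intrinsic_ms": 2.0,
    "delay_extrinsic_ms": 10.0,
    "leadfield_pyramidal": 0.8,
    "leadfield_stellate": 0.1,
    "leadfield_interneuron": 0.1,
}


@dataclass
class NeuralMassParams:
    """All biophysical parameters of a multi-source three-population model.

    Intrinsic coupling strengths ``gamma[s]`` = (γ1..γ5) per source:
    γ1 stellate→pyramidal, γ2 pyramidal→stellate, γ3 pyramidal→interneuron,
    γ4 interneuron→pyramidal, γ5 recurrent interneuron self-inhibition.

    ``A_forward/ A_backward / A_lateral`` are nonnegative extrinsic coupling
    matrices with zero diagonal; entries outside the architecture's mask must
    be exactly zero.  ``leadfield`` holds the per-population observation
    weights (pyramidal, stellate, interneuron) shared across channels; the
    pyramidal weight dominates, with the other populations jointly
    contributing about 20% of the measured response.
    """

    n_sources: int
    H_e: np.ndarray          # (n,) mV
    H_i: np.ndarray          # (n,) mV
    kappa_e: np.ndarray      # (n,) 1/s
    kappa_i: np.ndarray      # (n,) 1/s
    gamma: np.ndarray        # (n, 5) dimensionless
    rho1: float
    rho2: float
    A_forward: np.ndarray    # (n, n)
    A_backward: np.ndarray   # (n, n)
    A_lateral: np.ndarray    # (n, n)
    C: np.ndarray            # (n,) input gain
    delay_intrinsic: float   # s
    delay_extrinsic: float   # s
    leadfield: np.ndarray    # (3,) weights: pyramidal, stellate, interneuron
    architecture: ArchitectureSpec | None = None

    STATES_PER_SOURCE = 10

    def __post_init__(self):
        n = self.n_sources
        for name in ("H_e", "H_i", "kappa_e", "kappa_i", "C"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if arr.size == 1:
                arr = np.full(n, float(arr[0]))
            if arr.shape != (n,):
                raise StructuralError(f"{name} must have shape ({n},)")
            setattr(self, name, arr)
        g = np.asarray(self.gamma, dtype=float)
        if g.ndim == 1:
            g = np.tile(g, (n, 1))
        if g.shape != (n, 5):
            raise StructuralError(f"gamma must have shape ({n}, 5)")
        self.gamma = g
        for name in ("A_forward", "A_backward", "A_lateral"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != (n, n):
                raise StructuralError(f"{name} must have shape ({n}, {n})")
            setattr(self, name, a)
        self.leadfield = np.asarray(self.leadfield, dtype=float)
        if self.leadfield.shape != (3,):
            raise StructuralError("leadfield must hold 3 population weights")
        self.validate()

    def validate(self):
        for name in ("H_e", "H_i", "kappa_e", "kappa_i"):
            if not np.all(getattr(self, name) > 0):
                raise ParameterError(f"{name} must be strictly positive")
        if self.rho1 <= 0:
            raise ParameterError("sigmoid slope rho1 must be positive")
        masks = None
        if self.architecture is not None:
            masks = {
                "A_forward": self.architecture.forward_mask,
                "A_backward": self.architecture.backward_mask,
                "A_lateral": self.architecture.lateral_mask,
            }
        for name in ("A_forward", "A_backward", "A_lateral"):
            a = getattr(self, name)
            if np.any(a < 0):
                raise ParameterError(f"{name} must be entrywise nonnegative")
            if np.any(np.diag(a) != 0):
                raise ParameterError(f"{name} must have a zero diagonal")
            if masks is not None and np.any(a[masks[name] == 0] != 0):
                raise StructuralError(
                    f"{name} has entries outside the {self.architecture.tag} mask"
                )
        if not np.all(self.leadfield >= 0):
            raise ParameterError("lead-field weights must be nonnegative")
        if self.leadfield[0] <= self.leadfield[1] + self.leadfield[2]:
            raise ParameterError(
                "pyramidal lead-field weight must dominate the other populations"
            )

    @property
    def n_states(self) -> int:
        return self.n_sources * self.STATES_PER_SOURCE

    def copy(self) -> "NeuralMassParams":
        return replace(
            self,
            H_e=self.H_e.copy(),
            H_i=self.H_i.copy(),
            kappa_e=self.kappa_e.copy(),
            kappa_i=self.kappa_i.copy(),
            gamma=self.gamma.copy(),
            A_forward=self.A_forward.copy(),
            A_backward=self.A_backward.copy(),
            A_lateral=self.A_lateral.copy(),
            C=self.C.copy(),
            leadfield=self.leadfield.copy(),
        )


def default_params(architecture: ArchitectureSpec | str = "FB",
                   overrides: dict | None = None) -> NeuralMassParams:
    """Prior-mean parameters for a given extrinsic architecture.

    ``overrides`` may replace any entry of :data:`DEFAULTS` (scalar values
    are broadcast over sources).
    """
    if isinstance(architecture, str):
        architecture = ArchitectureSpec(architecture)
    cfg = dict(DEFAULTS)
    if overrides:
        unknown = set(overrides) - set(cfg)
        if unknown:
            raise ParameterError(f"unknown parameter overrides: {sorted(unknown)}")
        cfg.update(overrides)
    n = architecture.n_sources
    return NeuralMassParams(
        n_sources=n,
        H_e=np.full(n, cfg["H_e"]),
        H_i=np.full(n, cfg["H_i"]),
        kappa_e=np.full(n, cfg["kappa_e"]),
        kappa_i=np.full(n, cfg["kappa_i"]),
        gamma=np.asarray(cfg["gamma"], dtype=float),
        rho1=float(cfg["rho1"]),
        rho2=float(cfg["rho2"]),
        A_forward=cfg["forward_strength"] * architecture.forward_mask,
        A_backward=cfg["backward_strength"] * architecture.backward_mask,
        A_lateral=cfg["lateral_strength"] * architecture.lateral_mask,
        C=np.full(n, cfg["input_gain"]),
        delay_intrinsic=cfg["delay_intrinsic_ms"] * 1e-3,
        delay_extrinsic=cfg["delay_extrinsic_ms"] * 1e-3,
        leadfield=np.array([
            cfg["leadfield_pyramidal"],
            cfg["leadfield_stellate"],
            cfg["leadfield_interneuron"],
        ]),
        architecture=architecture,
    )


@dataclass
class ConditionEffects:
    """Per-condition log-scaling of the drug-sensitive synaptic parameters.

    ``b[c, s, k]`` scales parameter ``EFFECT_PARAMS[k]`` of region ``s`` in
    condition ``c`` as θ ← θ·exp(b).  The baseline condition (lowest dose)
    is structurally fixed at zero.
    """

    doses: tuple = DOSES
    regions: tuple = REGIONS
    b: np.ndarray = None   # (n_doses, n_regions, 3)

    def __post_init__(self):
        shape = (len(self.doses), len(self.regions), len(EFFECT_PARAMS))
        if self.b is None:
            self.b = np.zeros(shape)
        self.b = np.asarray(self.b, dtype=float)
        if self.b.shape != shape:
            raise StructuralError(f"effects array must have shape {shape}")
        self.validate()

    def validate(self):
        if not np.all(np.isfinite(self.b)):
            raise ParameterError("condition effects must be finite")
        if np.any(self.b[self.condition_index(self.baseline)] != 0):
            raise ParameterError("baseline condition effects must be exactly 0")

    @property
    def baseline(self) -> float:
        return min(self.doses)

    def condition_index(self, condition: float) -> int:
        for i, d in enumerate(self.doses):
            if np.isclose(d, condition):
                return i
        raise KeyError(f"unknown condition {condition!r}; doses are {self.doses}")

    def get(self, condition: float, region: str, param: str) -> float:
        return float(
            self.b[
                self.condition_index(condition),
                self.regions.index(region),
                EFFECT_PARAMS.index(param),
            ]
        )


@dataclass
class NoiseParams:
    """Amplitudes of the innovation and observation noise spectra.

    Innovations driving each source and channel (observation) noise both mix
    white and 1/f ("pink") components: G(f) = white + pink/f, with f floored
    at the lowest analysis frequency to avoid the DC singularity.  Channel
    noise additionally has a component shared across channels so that
    measured cross-spectra need not vanish when coupling is weak.
    """

    innovation_white: np.ndarray   # (n_sources,)
    innovation_pink: np.ndarray    # (n_sources,)
    channel_white: np.ndarray      # (n_channels,)
    channel_pink: np.ndarray       # (n_channels,)
    shared_white: float = 0.0
    shared_pink: float = 0.0

    def __post_init__(self):
        for name in ("innovation_white", "innovation_pink",
                     "channel_white", "channel_pink"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name),
                                                         dtype=float)))
        self.validate()

    def validate(self):
        for name in ("innovation_white", "innovation_pink",
                     "channel_white", "channel_pink"):
            if np.any(getattr(self, name) < 0):
                raise ParameterError(f"{name} amplitudes must be nonnegative")
        if self.shared_white < 0 or self.shared_pink < 0:
            raise ParameterError("shared channel-noise amplitudes must be nonnegative")

    @property
    def n_sources(self) -> int:
        return self.innovation_white.size

    @property
    def n_channels(self) -> int:
        return self.channel_white.size

    def copy(self) -> "NoiseParams":
        return NoiseParams(
            innovation_white=self.innovation_white.copy(),
            innovation_pink=self.innovation_pink.copy(),
            channel_white=self.channel_white.copy(),
            channel_pink=self.channel_pink.copy(),
            shared_white=self.shared_white,
            shared_pink=self.shared_pink,
        )


def default_noise(n_sources: int = 2, n_channels: int = 2,
                  innovation_white: float = 0.01, innovation_pink: float = 0.02,
                  channel_white: float = 5e-8, channel_pink: float = 1e-7,
                  shared_white: float = 1e-8, shared_pink: float = 2e-8,
                  ) -> NoiseParams:
    """Default noise spectra: pink-dominated innovations, weak channel noise.

    Amplitudes are sized so that membrane-potential fluctuations stay in the
    quasi-linear regime of the sigmoid (the small-perturbation operating
    point the steady-state treatment assumes); observed LFPs come out at the
    few-tens-of-microvolt scale typical of epidural recordings.
    """
    return NoiseParams(
        innovation_white=np.full(n_sources, innovation_white),
        innovation_pink=np.full(n_sources, innovation_pink),
        channel_white=np.full(n_channels, channel_white),
        channel_pink=np.full(n_channels, channel_pink),
        shared_white=shared_white,
        shared_pink=shared_pink,
    )
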