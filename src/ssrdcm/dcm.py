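"""Steady-state DCM assembly: priors, condition effects and recording fits.

A DCM for one recording predicts the cross-spectral densities of all dose
conditions jointly from a shared set of baseline parameters, per-condition
log-scalings of the drug-sensitive synaptic parameters (H_e, H_i, κ_i per
region; baseline condition fixed at zero), extrinsic coupling gains and
noise amplitudes.  All estimated quantities are log-scaling coefficients ϑ
with θ = θ̄·e^ϑ around the prior mean θ̄, under shrinkage priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import neural_mass as nm
from .containers import CrossSpectra
from .errors import InstabilityError, StructuralError
from .forward import default_freqs
from .inversion import PriorSpec, Posterior, VLSettings, variational_laplace
from .params import (ArchitectureSpec, DOSES, EFFECT_PARAMS, NeuralMassParams,
                     NoiseParams, REGIONS, default_noise, default_params)

__all__ = ["DCMModel", "build_priors", "fit_recording"]

# prior standard deviations of the log-scaling parameters
SD_BASELINE = 1.0 / 8.0    # baseline synaptic gains
SD_EFFECT = 0.5            # condition-specific effects
SD_COUPLING = 0.5          # extrinsic coupling gains
SD_NOISE = 0.5             # innovation / channel noise amplitudes


def build_priors(architecture: ArchitectureSpec, doses: tuple = DOSES,
                 regions: tuple = REGIONS,
                 hyper_mean: float = 8.0, hyper_var: float = 16.0
                 ) -> PriorSpec:
    """Shrinkage priors over the named log-scaling parameters of one DCM."""
    names, sds = [], []
    for param in ("He", "Hi", "ki"):
        for region in regions:
            names.append(f"scale_{param}_{region}")
            sds.append(SD_BASELINE)
    if architecture.forward_mask.any():
        names.append("scale_Af"); sds.append(SD_COUPLING)
    if architecture.backward_mask.any():
        names.append("scale_Ab"); sds.append(SD_COUPLING)
    if architecture.lateral_mask.any():
        names.append("scale_Al"); sds.append(SD_COUPLING)
    baseline = min(doses)
    for param in EFFECT_PARAMS:
        for region in regions:
            for dose in doses:
                if np.isclose(dose, baseline):
                    continue
                names.append(f"b_{param}_{region}_{dose:g}")
                sds.append(SD_EFFECT)
    for noise_name in ("log_inno_white", "log_inno_pink",
                       "log_chan_white", "log_chan_pink", "log_shared"):
        names.append(noise_name); sds.append(SD_NOISE)
    sds = np.asarray(sds)
    return PriorSpec(names=tuple(names), mean=np.zeros(len(names)),
                     cov=sds ** 2, hyper_mean=hyper_mean, hyper_var=hyper_var)


@dataclass
class DCMModel:
    """Generative model of one recording's per-condition cross-spectra.

    Calling :meth:`predict_vector` with a full parameter vector returns the
    stacked vectorized CSDs over all conditions (ordering: conditions in
    ascending dose; per condition the :func:`~ssrdcm.inversion.vectorize_csd`
    layout).
    """

    architecture: ArchitectureSpec
    doses: tuple = DOSES
    regions: tuple = REGIONS
    freqs: np.ndarray = field(default_factory=default_freqs)
    base_params: NeuralMassParams | None = None
    base_noise: NoiseParams | None = None
    freq_floor: float = 1.0

    def __post_init__(self):
        if isinstance(self.architecture, str):
            self.architecture = ArchitectureSpec(self.architecture)
        if self.base_params is None:
            self.base_params = default_params(self.architecture)
        if self.base_noise is None:
            self.base_noise = default_noise(self.base_params.n_sources)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.priors = build_priors(self.architecture, self.doses, self.regions)
        self._idx = {name: i for i, name in enumerate(self.priors.names)}
        p = self.base_params
        self._B = nm.input_matrix(p)
        self._L = nm.leadfield_matrix(p)
        w = 2 * np.pi * self.freqs
        self._iw = (1j * w)[:, None, None] * np.eye(p.n_states)[None]
        self._ph_i = np.exp(-1j * w * p.delay_intrinsic)[:, None, None]
        self._ph_e = np.exp(-1j * w * p.delay_extrinsic)[:, None, None]
        self._inv_f = 1.0 / np.maximum(self.freqs, self.freq_floor)
        c = self.base_noise.n_channels
        self._triu_r = np.triu_indices(c)
        self._triu_i = np.triu_indices(c, k=1)
        # constant structure matrices of the subunit-space frequency solve
        n = p.n_sources
        sp = nm.sigmoid_slope(0.0, p.rho1, p.rho2)
        Ci = np.zeros((5 * n, 5 * n))
        for s in range(n):
            g1, g2, g3, g4, g5 = p.gamma[s]
            o = 5 * s
            Ci[o + 0, o + 1] = g2 * sp
            Ci[o + 0, o + 2] = -g2 * sp
            Ci[o + 1, o + 0] = g1 * sp
            Ci[o + 2, o + 3] = g4 * sp
            Ci[o + 2, o + 4] = -g4 * sp
            Ci[o + 3, o + 1] = g3 * sp
            Ci[o + 3, o + 2] = -g3 * sp
            Ci[o + 4, o + 3] = g5 * sp
            Ci[o + 4, o + 4] = -g5 * sp
        self._Ci = Ci
        lp, ls, li = p.leadfield
        Lv = np.zeros((n, 5 * n))
        for s in range(n):
            Lv[s, 5 * s + 0] = ls
            Lv[s, 5 * s + 1] = lp
            Lv[s, 5 * s + 2] = -lp
            Lv[s, 5 * s + 3] = li
            Lv[s, 5 * s + 4] = -li
        self._Lv = Lv

    # -- parameter mapping ------------------------------------------------

    def _get(self, theta, name, default=0.0):
        i = self._idx.get(name)
        return theta[i] if i is not None else default

    def condition_params(self, theta: np.ndarray) -> list[NeuralMassParams]:
        """Per-condition parameter structures implied by a vector ϑ."""
        out = []
        for dose in sorted(self.doses):
            out.append(self._params_for(theta, dose))
        return out

    def _params_for(self, theta, dose) -> NeuralMassParams:
        p = self.base_params.copy()
        baseline = min(self.doses)
        sHe = np.array([self._get(theta, f"scale_He_{r}") for r in self.regions])
        sHi = np.array([self._get(theta, f"scale_Hi_{r}") for r in self.regions])
        ski = np.array([self._get(theta, f"scale_ki_{r}") for r in self.regions])
        if not np.isclose(dose, baseline):
            sHe = sHe + np.array(
                [self._get(theta, f"b_H_e_{r}_{dose:g}") for r in self.regions])
            sHi = sHi + np.array(
                [self._get(theta, f"b_H_i_{r}_{dose:g}") for r in self.regions])
            ski = ski + np.array(
                [self._get(theta, f"b_kappa_i_{r}_{dose:g}") for r in self.regions])
        p.H_e = p.H_e * np.exp(sHe)
        p.H_i = p.H_i * np.exp(sHi)
        p.kappa_i = p.kappa_i * np.exp(ski)
        p.A_forward = p.A_forward * np.exp(self._get(theta, "scale_Af"))
        p.A_backward = p.A_backward * np.exp(self._get(theta, "scale_Ab"))
        p.A_lateral = p.A_lateral * np.exp(self._get(theta, "scale_Al"))
        return p

    def noise_params(self, theta: np.ndarray) -> NoiseParams:
        nz = self.base_noise.copy()
        nz.innovation_white = nz.innovation_white * \
            np.exp(self._get(theta, "log_inno_white"))
        nz.innovation_pink = nz.innovation_pink * \
            np.exp(self._get(theta, "log_inno_pink"))
        nz.channel_white = nz.channel_white * \
            np.exp(self._get(theta, "log_chan_white"))
        nz.channel_pink = nz.channel_pink * \
            np.exp(self._get(theta, "log_chan_pink"))
        shared = np.exp(self._get(theta, "log_shared"))
        nz.shared_white = nz.shared_white * shared
        nz.shared_pink = nz.shared_pink * shared
        return nz

    # -- fast forward prediction ------------------------------------------

    def _column(self, pattern: str, default_zero: bool = True) -> np.ndarray:
        """Indices of per-(condition, region) parameter entries, -1 if absent."""
        out = np.full((len(self.doses), len(self.regions)), -1, dtype=int)
        baseline = min(self.doses)
        for k, dose in enumerate(sorted(self.doses)):
            if np.isclose(dose, baseline):
                continue
            for r, region in enumerate(self.regions):
                out[k, r] = self._idx.get(
                    pattern.format(region=region, dose=f"{dose:g}"), -1)
        return out

    def _theta_tables(self):
        """Cache index tables mapping ϑ entries to model quantities."""
        if hasattr(self, "_tab"):
            return self._tab
        regions = self.regions
        tab = {
            "scale_He": np.array([self._idx.get(f"scale_He_{r}", -1)
                                  for r in regions]),
            "scale_Hi": np.array([self._idx.get(f"scale_Hi_{r}", -1)
                                  for r in regions]),
            "scale_ki": np.array([self._idx.get(f"scale_ki_{r}", -1)
                                  for r in regions]),
            "b_He": self._column("b_H_e_{region}_{dose}"),
            "b_Hi": self._column("b_H_i_{region}_{dose}"),
            "b_ki": self._column("b_kappa_i_{region}_{dose}"),
            "Af": self._idx.get("scale_Af", -1),
            "Ab": self._idx.get("scale_Ab", -1),
            "Al": self._idx.get("scale_Al", -1),
            "noise": {k: self._idx.get(k, -1) for k in
                      ("log_inno_white", "log_inno_pink", "log_chan_white",
                       "log_chan_pink", "log_shared")},
        }
        self._tab = tab
        return tab

    @staticmethod
    def _take(thetas: np.ndarray, idx) -> np.ndarray:
        """Gather ϑ entries by index table, treating -1 as fixed zero."""
        idx = np.asarray(idx)
        out = thetas[:, idx.clip(min=0)]
        return np.where(idx < 0, 0.0, out)

    def predict_matrix(self, thetas: np.ndarray) -> np.ndarray:
        """Vectorized forward map for a batch of parameter vectors.

        ``thetas`` is (B, n_params); returns (B, n_data).  All B·n_cond
        linearizations are assembled, checked for stability and solved in
        single batched calls, which is what makes finite-difference
        Jacobians affordable.
        """
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        B = thetas.shape[0]
        tab = self._theta_tables()
        p0 = self.base_params
        n = p0.n_sources
        ns = p0.n_states
        n_f = self.freqs.size
        n_cond = len(self.doses)
        sp = nm.sigmoid_slope(0.0, p0.rho1, p0.rho2)   # fixed point at origin

        # condition-specific synaptic gains, shape (B, n_cond, n)
        logHe = self._take(thetas, tab["scale_He"])[:, None, :] \
            + self._take(thetas, tab["b_He"])[:, :, :]
        logHi = self._take(thetas, tab["scale_Hi"])[:, None, :] \
            + self._take(thetas, tab["b_Hi"])[:, :, :]
        logki = self._take(thetas, tab["scale_ki"])[:, None, :] \
            + self._take(thetas, tab["b_ki"])[:, :, :]
        He = p0.H_e[None, None, :] * np.exp(logHe)
        Hi = p0.H_i[None, None, :] * np.exp(logHi)
        ki = p0.kappa_i[None, None, :] * np.exp(logki)
        ke = np.broadcast_to(p0.kappa_e[None, None, :], He.shape)

        def scal(key):
            i = tab[key]
            return np.exp(thetas[:, i]) if i >= 0 else np.ones(B)

        afl = p0.A_forward[None] * scal("Af")[:, None, None] \
            + p0.A_lateral[None] * scal("Al")[:, None, None]
        abl = p0.A_backward[None] * scal("Ab")[:, None, None] \
            + p0.A_lateral[None] * scal("Al")[:, None, None]

        ge = ke * He            # (B, n_cond, n)
        gi = ki * Hi
        g1, g2, g3, g4, g5 = (p0.gamma[:, k] for k in range(5))

        J0 = np.zeros((B, n_cond, ns, ns))
        Ji = np.zeros((B, n_cond, ns, ns))
        Je = np.zeros((B, n_cond, ns, ns))
        for s in range(n):
            o = 10 * s
            for v_idx, g_idx, kap in (
                    (nm.V_S, nm.G_S, ke[..., s]), (nm.V_PE, nm.G_PE, ke[..., s]),
                    (nm.V_PI, nm.G_PI, ki[..., s]), (nm.V_IE, nm.G_IE, ke[..., s]),
                    (nm.V_II, nm.G_II, ki[..., s])):
                J0[..., o + v_idx, o + g_idx] = 1.0
                J0[..., o + g_idx, o + v_idx] = -kap ** 2
                J0[..., o + g_idx, o + g_idx] = -2 * kap
            w_p = ge[..., s] * g2[s] * sp
            Ji[..., o + nm.G_S, o + nm.V_PE] = w_p
            Ji[..., o + nm.G_S, o + nm.V_PI] = -w_p
            Ji[..., o + nm.G_PE, o + nm.V_S] = ge[..., s] * g1[s] * sp
            w_i = gi[..., s] * g4[s] * sp
            Ji[..., o + nm.G_PI, o + nm.V_IE] = w_i
            Ji[..., o + nm.G_PI, o + nm.V_II] = -w_i
            w_3 = ge[..., s] * g3[s] * sp
            Ji[..., o + nm.G_IE, o + nm.V_PE] = w_3
            Ji[..., o + nm.G_IE, o + nm.V_PI] = -w_3
            w_5 = gi[..., s] * g5[s] * sp
            Ji[..., o + nm.G_II, o + nm.V_IE] = w_5
            Ji[..., o + nm.G_II, o + nm.V_II] = -w_5
        for i in range(n):
            oi = 10 * i
            for j in range(n):
                if i == j:
                    continue
                oj = 10 * j
                w_f = ge[..., i] * afl[:, None, i, j] * sp
                w_b = ge[..., i] * abl[:, None, i, j] * sp
                Je[..., oi + nm.G_S, oj + nm.V_PE] = w_f
                Je[..., oi + nm.G_S, oj + nm.V_PI] = -w_f
                Je[..., oi + nm.G_PE, oj + nm.V_PE] = w_b
                Je[..., oi + nm.G_PE, oj + nm.V_PI] = -w_b
                Je[..., oi + nm.G_IE, oj + nm.V_PE] = w_b
                Je[..., oi + nm.G_IE, oj + nm.V_PI] = -w_b

        abscissa = np.linalg.eigvals((J0 + Ji + Je).reshape(-1, ns, ns)
                                     ).real.max()
        if abscissa >= 0:
            raise InstabilityError(
                f"unstable condition model (spectral abscissa {abscissa:.3g})",
                spectral_abscissa=float(abscissa))

        # Frequency response in the 10-dim subunit space: each synaptic
        # subunit is a second-order kernel with scalar transfer
        # h(ω) = κH / (iω + κ)², so the network solve is
        # (I − diag(h)·(C_intr·e^{−iωτi} + C_extr·e^{−iωτe}))·v = diag(h)·B·u.
        nq = 5 * n
        kap10 = np.stack([ke, ke, ki, ke, ki], axis=-1).reshape(B, n_cond, nq)
        KH10 = np.stack([ge, ge, gi, ge, gi], axis=-1).reshape(B, n_cond, nq)
        w = 2 * np.pi * self.freqs
        Hd = KH10[:, :, None, :] / (1j * w[None, None, :, None]
                                    + kap10[:, :, None, :]) ** 2
        Ce = np.zeros((B, nq, nq))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                Ce[:, 5 * i + 0, 5 * j + 1] = afl[:, i, j] * sp
                Ce[:, 5 * i + 0, 5 * j + 2] = -afl[:, i, j] * sp
                for row in (1, 3):
                    Ce[:, 5 * i + row, 5 * j + 1] = abl[:, i, j] * sp
                    Ce[:, 5 * i + row, 5 * j + 2] = -abl[:, i, j] * sp
        ph_i = self._ph_i[:, 0, 0]
        ph_e = self._ph_e[:, 0, 0]
        A = np.empty((B, n_cond, n_f, nq, nq), dtype=complex)
        A[:] = -(Hd * ph_i[None, None, :, None])[..., None] \
            * self._Ci[None, None, None]
        A -= (Hd * ph_e[None, None, :, None])[..., None] \
            * Ce[:, None, None]
        A[..., np.arange(nq), np.arange(nq)] += 1.0
        rhs = np.zeros((B, n_cond, n_f, nq, n), dtype=complex)
        for s in range(n):
            rhs[..., 5 * s, s] = Hd[..., 5 * s] * p0.C[s]
        X = np.linalg.solve(A.reshape(-1, nq, nq), rhs.reshape(-1, nq, n))
        T = np.einsum("cv,bvs->bcs", self._Lv, X).reshape(
            B, n_cond, n_f, self._Lv.shape[0], n)

        nz0 = self.base_noise
        noise_idx = self._theta_tables()["noise"]

        def nscal(key):
            i = noise_idx[key]
            return np.exp(thetas[:, i]) if i >= 0 else np.ones(B)

        iw_s = nscal("log_inno_white")[:, None, None]
        ip_s = nscal("log_inno_pink")[:, None, None]
        Gu = nz0.innovation_white[None, None, :] * iw_s \
            + np.outer(self._inv_f, nz0.innovation_pink)[None] * ip_s
        G = np.einsum("bkfcs,bfs,bkfds->bkfcd", T, Gu, T.conj())
        c = nz0.n_channels
        own = nz0.channel_white[None, None, :] * nscal("log_chan_white")[:, None, None] \
            + np.outer(self._inv_f, nz0.channel_pink)[None] \
            * nscal("log_chan_pink")[:, None, None]
        G[:, :, :, np.arange(c), np.arange(c)] += own[:, None]
        shared = (nz0.shared_white + nz0.shared_pink * self._inv_f)[None] \
            * nscal("log_shared")[:, None]
        G += shared[:, None, :, None, None]

        re = G[:, :, :, self._triu_r[0], self._triu_r[1]].real
        im = G[:, :, :, self._triu_i[0], self._triu_i[1]].imag
        return np.concatenate([re, im], axis=3).reshape(B, -1)

    def predict_vector(self, theta: np.ndarray) -> np.ndarray:
        """Stacked vectorized CSDs for all conditions at parameters ϑ."""
        return self.predict_matrix(np.atleast_2d(theta))[0]

    def stack_data(self, csds: dict) -> np.ndarray:
        """Vectorize observed per-condition CSDs in the model's ordering."""
        parts = []
        for dose in sorted(self.doses):
            match = [d for d in csds if np.isclose(d, dose)]
            if not match:
                raise StructuralError(f"missing condition {dose:g} in data")
            csd = csds[match[0]]
            if csd.freqs.size != self.freqs.size or \
                    not np.allclose(csd.freqs, self.freqs):
                raise StructuralError("data frequency grid differs from model")
            v = csd.values
            re = v[:, self._triu_r[0], self._triu_r[1]].real
            im = v[:, self._triu_i[0], self._triu_i[1]].imag
            parts.append(np.concatenate([re, im], axis=1).reshape(-1))
        return np.concatenate(parts)


def fit_recording(csds: dict, architecture, settings: VLSettings | None = None,
                  base_params: NeuralMassParams | None = None,
                  base_noise: NoiseParams | None = None,
                  freqs=None, metadata: dict | None = None) -> Posterior:
    """Invert one recording's per-condition cross-spectra under one
    architecture.

    ``csds`` maps dose labels to :class:`CrossSpectra` (all conditions of
    one recording site and stimulus environment).  The data vector is
    normalised by its root-mean-square so the noise log-precision is on a
    comparable scale across recordings; the scale is recorded in the
    posterior metadata.
    """
    if isinstance(architecture, str):
        architecture = ArchitectureSpec(architecture)
    doses = tuple(sorted(csds.keys()))
    any_csd = csds[doses[0]]
    model = DCMModel(architecture=architecture, doses=doses,
                     freqs=any_csd.freqs if freqs is None else freqs,
                     base_params=base_params, base_noise=base_noise)
    y = model.stack_data(csds)
    scale = float(np.sqrt(np.mean(y ** 2)))
    if scale <= 0:
        raise StructuralError("degenerate (all-zero) data vector")

    def forward(theta):
        return model.predict_vector(theta) / scale

    def forward_batch(thetas):
        return model.predict_matrix(thetas) / scale

    post = variational_laplace(forward, y / scale, model.priors,
                               settings or VLSettings(),
                               forward_batch=forward_batch)
    post.metadata.update({"architecture": architecture.tag,
                          "scale": scale, "doses": doses})
    if metadata:
        post.metadata.update(metadata)
    return post
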