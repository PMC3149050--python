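# Methods

`ssrdcm` implements a steady-state dynamic-causal-modelling analysis of
local field potentials: a biophysical generative model of two coupled
auditory-cortex sources is fitted to cross-spectral densities by
variational Bayes, competing network architectures are compared by their
evidence, and drug-induced (anaesthetic dose-dependent) changes in
excitatory and inhibitory synaptic gain are recovered at the group level.
Because no real recordings ship with the package, a first-class synthetic
study generator defines the conditions under which every claim is tested.

## Generative model

### Sources

Each cortical source is a three-population macrocolumn: excitatory spiny
stellate cells (granular layer IV), excitatory pyramidal cells and
inhibitory interneurons (extra-granular layers).  Synaptic transmission is
an alpha-kernel convolution — presynaptic firing convolved with

    h(t) = H · κ · t · exp(−κt),

parameterised by the maximum postsynaptic potential H (mV; H_e excitatory,
H_i inhibitory) and rate constant κ (1/s; κ_e, κ_i).  Equivalently each
synaptic subunit obeys

    v̇ = g,    ġ = κH·(input firing) − 2κg − κ²v.

A source holds five such subunits (stellate; pyramidal excitatory and
inhibitory; interneuron excitatory and self-inhibitory), i.e. 10 states.
Population potentials are V_s = v_stellate, V_p = v_pe − v_pi,
V_i = v_ie − v_ii.  Firing is a centred sigmoid

    S(v) = 1/(1+e^{−ρ1(v−ρ2)}) − 1/(1+e^{ρ1ρ2}),

so S(0) = 0 and the origin is an exact equilibrium of the input-free
system.  ρ1, ρ2 are shared across populations and sources.

Intrinsic coupling strengths γ1..γ5 wire stellate→pyramidal (γ1),
pyramidal→stellate (γ2), pyramidal→interneuron (γ3),
interneuron→pyramidal (γ4) and recurrent interneuron self-inhibition (γ5).

### Network

Sources are coupled by extrinsic connections that originate in pyramidal
cells and are distinguished by their laminar targets: forward connections
terminate on granular stellate cells, backward connections on
extra-granular pyramidal cells and interneurons, lateral connections on
all three.  Three two-source architectures are implemented for the
A1/posterior-auditory-field (PAF) pair: FB (forward A1→PAF, backward
PAF→A1 — the anatomically expected hierarchy), BF (the reverse) and LL
(reciprocal lateral).

### Observation

Channel i reads source i through a lead field dominated by the pyramidal
potential (weight 0.8) with stellate and interneuron populations jointly
contributing 20% (0.1 each) — epidural electrodes see mainly the aligned
pyramidal dendrites.

### Defaults (all configurable)

| parameter | default | units |
|---|---|---|
| H_e / H_i | 8 / 32 | mV |
| κ_e / κ_i | 250 / 62.5 | 1/s |
| γ1..γ5 | 128, 128, 64, 64, 16 | — |
| ρ1 / ρ2 | 2 / 1 | — |
| forward / backward / lateral gain | 32 / 16 / 16 | — |
| intrinsic / extrinsic delay | 2 / 10 | ms |

ρ1, ρ2 were fixed up front so that all three default architectures have a
stable fixed point (spectral abscissa ≈ −12 s⁻¹ for FB/BF, −10 s⁻¹ for
LL); stability at the prior mean is asserted in the test suite.

## Spectral forward model

The model is linearized about its stable fixed point (the origin, for zero
mean input).  Conduction delays enter the frequency domain exactly as
phase factors on the coupling blocks,

    J(ω) = J_local + J_intrinsic·e^{−iωτ_i} + J_extrinsic·e^{−iωτ_e},

and the modulation transfer function is T(ω) = L (iωI − J(ω))⁻¹ B with B
injecting innovations into the stellate populations.  Predicted
cross-spectra on the 1–30 Hz grid (1 Hz steps) are

    G_y(f) = T(f) · diag(G_u(f)) · T(f)ᴴ + G_channel(f),

with white + 1/f innovation spectra G_u(f) = α_w + α_p/max(f, 1 Hz) per
source (the floor avoids the DC singularity of the pink component) and an
analogous channel-noise term that includes a component shared across
channels, so measured cross-spectra are not forced to zero under weak
coupling.  Predicted CSDs are Hermitian positive semidefinite by
construction; this is property-tested.

For inversion the same quantity is computed in a reduced 10-dimensional
subunit space (each subunit is a second-order kernel with scalar transfer
κH/(iω+κ)²), batched across conditions and finite-difference
perturbations; the batched path is verified against the reference
state-space path to machine precision in the test suite.

## Stochastic simulation

`simulate_timeseries` integrates the nonlinear model with a fixed-step
semi-implicit Euler–Maruyama scheme (each subunit's potential updates
before its current, which uses the updated potential).  The semi-implicit
form was chosen over the fully explicit update because the explicit form
at practical step sizes visibly misdamps the model's 15–25 Hz resonances
(up to ~2.4× PSD error at dt = 1 ms); the semi-implicit variant reduces
this to ~26% at 1 ms, ~14% at 0.5 ms (the default) and ~5% at 0.2 ms.
Conduction delays are applied as integer-step ring-buffer lags, making the
simulated process the exact time-domain counterpart of the e^{−iωτ}
factors in the frequency-domain linearization.  Innovations and channel
noise are synthesised spectrally (frequency-domain shaping of white
Gaussian series) so their long-run periodograms converge to the same
white + 1/f densities the forward model assumes.  A divergence guard
(|V| > 200 mV) raises an instability error.

The default noise amplitudes put membrane fluctuations in the sigmoid's
quasi-linear regime (LFP ≈ 25 µV rms) — the small-perturbation operating
point the steady-state treatment assumes.  At substantially larger drive
the sigmoid's curvature distorts the spectrum away from the linearized
prediction; that regime is outside the model class and is not used.

The simulation–prediction agreement is itself an acceptance check: a
240 s simulation at dt = 0.2 ms must match the analytic CSD within 3
Monte-Carlo standard errors per 1 Hz bin (Welch, 4 s segments) on both
auto-spectra and the cross-spectrum magnitude.

## Empirical spectral features

Recorded (or simulated) series are reduced to data features by:
(1) keeping the first 10 minutes (default), polyphase anti-alias
resampling to 125 Hz and per-channel mean removal; (2) ordinary
least-squares fitting of a VAR(8) (statsmodels, intercept included then
discarded); (3) the spectral transform

    S(f) = Δ · A(f)⁻¹ E A(f)⁻ᴴ,  A(f) = I − Σ_n A⁽ⁿ⁾ e^{−i2πfnΔ},

on the 1–30 Hz grid.  Band powers are means of |S_ij| over half-open bins
delta [1,4), theta [4,8), alpha [8,16), beta [16,30) Hz, so shared
endpoints belong to the upper band.  The transform is verified against
the closed-form AR(1) spectrum (value 4.0 at zero frequency for a = 0.5,
σ² = 1, Δ = 1) and against long-run Welch estimates of simulated VAR
processes.  The 0.6–60 Hz online acquisition filter of real recordings is
not re-applied to synthetic data (the model band-limits implicitly); this
is a documented fidelity gap.

## Inversion: variational Laplace

All estimated quantities are log-scaling coefficients ϑ (θ = θ̄·e^ϑ)
with Gaussian shrinkage priors; a Gaussian posterior q(ϑ) = N(m, Σ) and a
point-estimated noise log-precision λ (with its own Gaussian prior and
Laplace variance) maximise the negative free energy

    F = E_q[ln p(y|ϑ,λ)] − KL[q(ϑ)‖p(ϑ)] − KL[q(λ)‖p(λ)],

a lower bound on the log model evidence.  The data vector stacks, per
condition and frequency, the real upper triangle and strictly-upper
imaginary parts of the CSD (for 2 channels: 3 + 1 numbers per frequency;
4 conditions × 30 frequencies × 4 = 480 numbers), normalised by its rms so
λ lives on a comparable scale across recordings.  Real and imaginary
parts are weighted equally and no frequency weighting is applied.

Optimisation: Gauss–Newton steps with Levenberg–Marquardt damping on the
diagonal; the forward Jacobian uses central finite differences (step 1e-3
on the log scale) evaluated through the batched forward path.  A candidate
step is first screened with the current Jacobian, then fully re-evaluated
(own Jacobian, λ re-optimised by damped 1-D Newton) and accepted only if
the exact F increases — the recorded F trace is therefore monotone by
construction, which the suite asserts on every fit.  Convergence: ΔF <
0.01 nat on three consecutive accepted steps, or no improving step within
the damping budget (a local optimum, reported as converged), or the
iteration cap (reported as not converged, best-so-far returned).
Parameter sets whose linearization is unstable raise an instability error
and are treated as rejected steps.

Free parameters of one recording fit (31 for FB/BF, 30 for LL) and their
prior standard deviations:

* baseline log-gains of H_e, H_i, κ_i per region — SD 1/8;
* extrinsic coupling log-gains (per connection type present) — SD 1/2;
* condition effects b on H_e, H_i, κ_i per region for each non-baseline
  dose (the baseline condition is structurally fixed at zero) — SD 1/2;
* innovation white/pink, channel white/pink and shared channel-noise
  log-amplitudes — SD 1/2.

The hyperprior on λ is N(8, 16); setting its variance to zero fixes the
noise level, which is how the linear-Gaussian oracle test pins F to the
analytic log evidence (the scheme must reproduce the conjugate posterior
to 1e-6 and the log evidence to 1e-4).

## Model comparison

Fixed-effects Bayesian model selection: per-subject log-evidences
(hemisphere-averaged where animals were recorded bilaterally) are summed
across subjects, assuming conditionally independent data; the group log
Bayes factor between two architectures is the difference of the sums.
ln BF ≥ ln 150 ≈ 5.01 is labelled "very strong" evidence.  Ties are broken
lexicographically and flagged.  Random-effects selection is out of scope.

## Dose-response statistics

The posterior means (MAP estimates) of the condition effects are analysed
across animals: overall one-tailed direction tests against the zero
baseline (excitation decreases, inhibition increases); one-way ANOVAs
with dose as the single factor (df = (k−1, N−k); the full design gives
F(3,24) for 4 doses × 7 animals); paired one-tailed post-hoc t-tests
(within-animal design; an optional ×8 Bonferroni adjustment mirrors a
family of eight planned comparisons); and per-animal polynomial
dose-response fits on the raw (uncentred) dose scale — order 1 for the
EPSP decrease, order 2 for the saturating IPSP increase — whose
coefficients are tested against zero across animals (one-tailed,
reported as mean ± s.e.m.).  ANOVA and t-tests are delegated to
scipy.stats and verified against explicit sum-of-squares and textbook
formulas to 1e-10.

## Synthetic study generator

The generator emulates the target study design: 7 animals, the first 3
recorded bilaterally (10 recording sites), 4 isoflurane doses (1.4% —
the baseline — 1.8, 2.4, 2.8%), 2 stimulus environments (broadband noise
vs silence), 10-minute epochs.  Ground-truth condition effects follow
population dose-response curves on u = dose − 1.4:

* H_e: b(u) = −0.5·u (linear decrease; animal SD 0.1 on the slope),
* H_i: b(u) = 1.2·u − 0.55·u² (saturating increase peaking near the top
  dose, i.e. at most ≈ ×1.9 the baseline IPSP amplitude; animal SDs 0.2
  and 0.1),
* κ_i: flat (no dose effect) by default.

These defaults give raw-dose polynomial coefficients (linear ≈ +2.7,
quadratic −0.55 for H_i; slope −0.5 for H_e) with the sign structure the
statistics module is designed to detect, at physiologically sensible
magnitudes.  Per-animal, per-region curve coefficients are drawn once;
draws whose implied parameters are unstable at any dose are resampled
(counted).  The noise environment scales innovation amplitudes ×1.5
relative to silence — acoustic drive is absorbed into the endogenous
fluctuation level, consistent with fitting both environments with
endogenous input only.  Higher doses show reduced delta-band power, the
spectral signature of deepening anaesthesia, and this is asserted in the
suite.

Two output modes: `timeseries` (full stochastic simulation per recording,
2 kHz) and `spectra` (analytic CSD plus a complex-Wishart finite-sample
perturbation with ν = 64 effective degrees of freedom per frequency,
independent across frequencies — an idealisation of VAR estimation noise
that keeps large studies affordable).  The two modes are
cross-validated: VAR features of simulated series converge to the
spectra-mode prediction as the epoch grows.  Per-recording random streams
are spawned from the master seed with a counter-based key (animal,
hemisphere, dose, environment), so enlarging the study never reshuffles
existing recordings; everything regenerates bit-identically from the
config.

What the generator does not emulate: burst suppression as a time-domain
phenomenon (the quasi-linear regime reproduces only its spectral
signature, the dose-dependent loss of low-frequency power), volume
conduction between channels beyond the shared noise term, the online
acquisition filter, and non-Gaussian or non-stationary artefacts.
Passing tests therefore demonstrate internal consistency and
recoverability under the model's own assumptions, not performance on
real recordings.

## Problem sizes used in the tests

The recovery checks run 20 replicate studies scaled down to 4 unilateral
animals in one environment (spectra mode), fitted under all three
architectures with a 32-iteration cap — 240 fits in total, chosen to keep
the full suite comfortably on a single desktop core.  The full-design
study (10 sites × 2 environments) is exercised by the acceptance script.
Architecture recovery requires the FB generator to be selected in ≥90% of
replicates (and overall); dose-curve recovery requires significantly
negative group EPSP slopes and IPSP quadratic coefficients (one-tailed
p < 0.05) in both regions in ≥90% of replicates.

## Known limitations

* Linear, fast (AMPA/GABA_A-like) synapses only; no NMDA, conductance or
  neuromodulatory dynamics; three populations per source; two sources.
* The free-energy landscape is non-convex; the optimiser reports local
  optima.  Across the suite's replicates this has not produced a wrong
  architecture selection, but individual parameter estimates (notably
  effects at the highest dose, where H_e reduction and H_i increase trade
  off) can be shrunk toward the prior.
* The Wishart spectra mode treats frequencies as independent; real VAR
  estimates have correlated errors across frequencies.
* Evoked (time-domain) responses and induced-response models are out of
  scope; the pipeline addresses steady-state spectra only.
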