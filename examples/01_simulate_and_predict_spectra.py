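"""Simulate coupled auditory-cortex sources and predict their spectra.

Builds the default two-source hierarchy (A1 -> PAF forward, PAF -> A1
backward), drives it with white + 1/f endogenous fluctuations, and compares
the Welch periodogram of the simulated LFP with the analytic cross-spectral
density from the linearized model.  The two should agree closely: the
steady-state treatment models exactly these fluctuations about the stable
fixed point.
"""

import numpy as np
from scipy import signal

from ssrdcm import default_params, default_noise, predict_csd, \
    simulate_timeseries
from ssrdcm.forward import default_freqs

params = default_params("FB")
noise = default_noise()
freqs = default_freqs()

sim = simulate_timeseries(params, noise, dt=5e-4, duration=60.0, seed=42)
print(f"simulated {sim.data.shape[0]} samples x {len(sim.channels)} channels "
      f"at {sim.fs:.0f} Hz; LFP std = "
      + ", ".join(f"{s * 1e3:.1f} uV" for s in sim.data.std(axis=0)))

pred = predict_csd(params, noise, freqs)
f_w, P = signal.welch(sim.data[:, 0], fs=sim.fs, nperseg=int(4 * sim.fs))
idx = [np.argmin(np.abs(f_w - q)) for q in freqs]

print("\n freq   predicted PSD   simulated PSD   (A1 auto-spectrum, mV^2/Hz)")
for k in (0, 4, 9, 19, 29):
    print(f"{freqs[k]:5.0f}   {pred.auto('A1')[k]:13.3e} "
          f"  {P[idx[k]] / 2:13.3e}")
print("\nThe simulated spectrum scatters around the analytic prediction; "
      "low frequencies dominate because the innovations carry a 1/f "
      "component.")
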