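"""Turn a raw LFP series into VAR-based cross-spectra and band powers.

The empirical data features of the pipeline are not periodograms but the
spectra implied by an order-8 vector autoregression of the down-sampled
(125 Hz) recording: S(f) = dt * A(f)^-1 E A(f)^-H.  Band powers summarize
them in the conventional delta/theta/alpha/beta bins.
"""

import numpy as np

from ssrdcm import default_params, default_noise, simulate_timeseries
from ssrdcm.spectral_features import BANDS, band_power, fit_var, preprocess, \
    var_to_csd
from ssrdcm.forward import default_freqs

sim = simulate_timeseries(default_params("FB"), default_noise(),
                          dt=5e-4, duration=120.0, seed=7)
x = preprocess(sim.data, fs_in=sim.fs, fs_out=125.0, epoch_seconds=120.0)
print(f"preprocessed epoch: {x.shape[0]} samples at 125 Hz, mean removed")

model = fit_var(x, p=8, dt=1 / 125.0, channels=sim.channels)
print(f"VAR(8) fitted; stationary: {model.is_stationary()}; "
      f"innovation covariance diagonal: "
      + ", ".join(f"{v:.2e}" for v in np.diag(model.noise_cov)))

csd = var_to_csd(model, default_freqs())
print("\nband power |S| (A1 auto), mV^2/Hz:")
for name in BANDS:
    bp = band_power(csd, name)
    print(f"  {name:6s} [{BANDS[name][0]:4.0f}, {BANDS[name][1]:4.0f}) Hz:"
          f"  {bp[0, 0]:.3e}")
print("\nDelta and alpha dominate (pink innovations plus the model's ~10 Hz "
      "resonance) while beta carries the least power, as in anaesthetized "
      "cortex.")
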