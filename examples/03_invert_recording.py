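"""Invert one synthetic recording: recover dose effects on synaptic gains.

Generates the four dose conditions of one recording site with known
ground-truth condition effects (EPSP amplitude down, IPSP amplitude up with
dose), then fits the generative model by variational Laplace and compares
the posterior condition effects with the generating values.
"""

from ssrdcm import VLSettings
from ssrdcm.dcm import fit_recording
from ssrdcm.synthetic import StudyConfig, generate_study

cfg = StudyConfig(seed=3, n_animals=3, n_dual=0, environments=("noise",))
study = generate_study(cfg, mode="spectra")
csds = {r["dose"]: r["csd"] for r in study.records if r["animal"] == "a1"}

post = fit_recording(csds, "FB", settings=VLSettings(max_iter=48))
print(f"free energy F = {post.free_energy:.1f} nats "
      f"({len(post.trace) - 1} accepted steps, converged={post.converged})")

truth = study.truth.effects["a1"]
print("\ncondition effects (log-scaling of the A1 parameters):")
print(" dose   b_He est  (true)    b_Hi est  (true)")
for dose in (1.8, 2.4, 2.8):
    est_e = post[f"b_H_e_A1_{dose:g}"]
    est_i = post[f"b_H_i_A1_{dose:g}"]
    print(f" {dose:3.1f}%  {est_e:+8.3f} ({truth.get(dose, 'A1', 'H_e'):+.3f})"
          f"   {est_i:+8.3f} ({truth.get(dose, 'A1', 'H_i'):+.3f})")
print("\nNegative b_He (less glutamatergic drive) and positive b_Hi "
      "(more GABAergic inhibition) grow with dose, as generated.")
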