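"""Simulate a directed two-oscillator network and estimate its connectivity.

Builds a VAR model of two AR(2) oscillators (20 and 40 Hz) with coupling
only from site 0 to site 1, simulates epoched field potentials, estimates
multitaper coherence and nonparametric spectral Granger causality, and
compares the GC estimate with the model's exact (parametric) GC spectrum.
"""

import numpy as np

from rhythmnet import (
    VarModel,
    analytic_var_gc,
    coherence_from_csd,
    multitaper_csd,
    pairwise_spectral_gc,
    simulate_var_lfp,
)

fs = 200.0
A = np.zeros((3, 2, 2))
for i, f in enumerate((20.0, 40.0)):
    theta = 2 * np.pi * f / fs
    A[0, i, i] = 2 * 0.9 * np.cos(theta)
    A[1, i, i] = -0.9**2
A[2, 1, 0] = 0.25  # directed coupling: site 0 -> site 1, lag 3 samples
model = VarModel(coeffs=A, noise_cov=np.eye(2), sampling_rate=fs)
print(f"model spectral radius: {model.spectral_radius():.3f} (stable < 1)")

rec = simulate_var_lfp(None, model, n_epochs=500, epoch_len_s=1.0, seed=0)
csd = multitaper_csd(rec, n_tapers=3)
coh = coherence_from_csd(csd)
gc = pairwise_spectral_gc(csd)
oracle = analytic_var_gc(model, csd.freqs)

k = np.argmax(oracle.gc_spectrum[0, 1])
print(f"\nat the coupled oscillator frequency ({csd.freqs[k]:.0f} Hz):")
print(f"  coherence                  {coh.values[0, 1, k]:.3f}")
print(f"  GC site0 -> site1 (est.)   {gc.values[0, 1, k]:.3f}")
print(f"  GC site0 -> site1 (exact)  {oracle.gc_spectrum[0, 1, k]:.3f}")
print(f"  GC site1 -> site0 (est.)   {gc.values[1, 0, k]:.4f}")
print(
    "\nThe estimated GC is large only in the direction of the planted "
    "coupling;\nthe reverse direction hovers near zero (estimation bias only)."
)
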