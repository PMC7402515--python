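"""Dynamic transfer gain of a point neuron by circular statistics.

Drives an eIF neuron with noise plus a weak sine at several harmonic
frequencies, pools the spike phases into the circular resultant
r = (1/N) sum exp(j 2 pi f t_k), and reads off the normalized gain curve,
its -3 dB cutoff frequency and the high-frequency power-law exponent.
"""

import numpy as np

from aisdyn.eif import reference_eif_params, simulate_eif
from aisdyn.gain import cutoff_frequency, gain_curve, powerlaw_exponent
from aisdyn.stimulus import StimulusConfig, compose_stimulus

params = reference_eif_params(25.0)
I0, s = 0.0444, 0.178  # nA; calibrated 5 spike/s operating point
I1 = 0.1 * s

spikes_per_f = {}
for f in (1.0, 3.0, 10.0, 30.0, 60.0, 100.0, 200.0, 400.0):
    reps = []
    for seed in range(6):
        cfg = StimulusConfig(I0=I0, I1=I1, f=f, s=s, dt=0.02, duration=60.0,
                             seed=1000 + seed)
        _, sp = simulate_eif(params, compose_stimulus(cfg), dt=0.02)
        reps.append(sp.times)
    spikes_per_f[f] = reps

curve = gain_curve(spikes_per_f, r0=5.0)
print("f (cycle/s)   normalized gain")
for f, g, sd in zip(curve.f, curve.gain, curve.gain_sd):
    print(f"  {f:7.1f}      {g:.3f} +- {sd:.3f}")
cof = cutoff_frequency(curve)
alpha = powerlaw_exponent(curve)
print(f"cutoff frequency (70% attenuation): {cof:.1f} cycle/s")
print(f"high-frequency exponent alpha: {alpha:.2f}  (gain ~ 1/f^alpha)")
print("-> the neuron tracks slow input modulations faithfully and "
      "attenuates fast ones: a low-pass filter whose bandwidth is the "
      "quantity the AIS position controls in the full model.")
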