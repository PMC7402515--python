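"""AIS position shapes the somatic AP onset (ball-and-stick model).

Simulates the conductance-based soma+axon model with the high-density Na/K
compartment (the AIS) either adjacent to the soma or at the distal end of
the 50 um axon, under calibrated noisy input, and compares the phase-plane
onset metrics of the averaged somatic AP.
"""

from aisdyn.cable import build_bas, input_resistance
from aisdyn.experiments import PRESETS, bas_operating_point, noisy_run
from aisdyn.waveform import extract_waveforms, onset_metrics

preset = PRESETS["desk"]
metrics = {}
for d in (0.0, 50.0):
    model = build_bas(d=d)
    op = bas_operating_point(model, preset, seed=11)
    trace, spikes, _ = noisy_run(model, op, 40.0, preset, seed=12)
    wf = extract_waveforms(trace, spikes)
    om = onset_metrics(wf)
    rin = input_resistance(model, dt=preset.dt)
    metrics[d] = (om, rin, wf.n_aps)
    print(f"AIS at {d:4.0f} um: {wf.n_aps} APs averaged | onset threshold "
          f"{om.v_threshold:7.2f} mV | rapidity {om.rapidity:5.2f} /ms | "
          f"Rin {rin:.1f} MOhm")

r = metrics[50.0][0].rapidity / metrics[0.0][0].rapidity
dv = metrics[0.0][0].v_threshold - metrics[50.0][0].v_threshold
print(f"-> moving the AIS 50 um out sharpens the AP onset {r:.1f}-fold and "
      f"hyperpolarizes the threshold by {dv:.1f} mV, while the passive load "
      "(input resistance) is essentially unchanged: the effect is the "
      "axo-somatic current dipole, not a change in membrane properties.")
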