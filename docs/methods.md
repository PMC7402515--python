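# Methods

This note documents the models, estimators and numerical choices behind
`aisdyn`, what the synthetic inputs do and do not emulate, and the problem
sizes the tests and the acceptance script run at.

## The ball-and-stick neuron

The single-neuron model is a lumped spherical soma (default diameter 20 µm,
1 µF cm⁻², leak only) attached to a cylindrical axon of diameter 1 µm and
length 50 µm, discretized into 11 equal compartments with axial resistivity
150 Ω cm and specific capacitance 0.5625 µF cm⁻².  Every axonal compartment
carries fast-inactivating Na (m³h) and delayed-rectifier K currents plus
leak; reversal potentials are +60 / −80 / −60 mV (Na / K / leak).  The axon
initial segment (AIS) is the single compartment whose center lies nearest a
chosen distance *d* from the soma; it carries 88 nS µm⁻² Na and
17.6 nS µm⁻² K, ~110× the plain axonal densities (0.8 / 0.16 nS µm⁻²).
Relocating the AIS therefore changes *where* spike-generating conductance
sits, never how much membrane or conductance the cell has — the package
checks that the input resistance moves by well under 0.05 % across the full
sweep.

**Channel kinetics.**  The rate functions follow the classic
cortical-axon parameterization (Na activation in trap form around −35 mV
with 9 mV slope, inactivation steady state around −65 mV, a first-power
delayed-rectifier K around +25 mV), with all rates scaled by
Q10 = 2.3 between 23 °C and 37 °C (factor ≈ 3.2).  Every rate parameter is a
field of `KineticsParams` and can be changed without touching the solver.
Quantitative single-cell results (cutoff frequencies, α exponents, threshold
shifts) depend on this choice; the *relative* AIS-position effects are
robust to it.

**Somatic leak.**  The axonal leak density (3.3 × 10⁻⁵ pS µm⁻²) is
electrically negligible — each axonal compartment is dominated by its axial
coupling (~115 nS) — so the soma needs its own leak to set the cell's input
resistance and resting time constant.  The default, 1.25 pS µm⁻², gives a
somatic time constant of ≈ 8 ms, consistent with the effective membrane time
constants the eIF reduction recovers at distal AIS positions (τ_m ≈ 7.8 ms).
A lossier axonal-leak alternative (`cable.G_LEAK_AXON_ALT` = 0.33 pS µm⁻²)
is provided for passive-cable checks.

**Numerics.**  Each step updates the three gate variables by exponential
Euler using tabulated steady states and decay factors (0.05 mV grid, linear
interpolation), then solves the spatially coupled voltage system by backward
Euler with the Thomas algorithm — stable at the production step of 0.005 ms
despite the ~1.3 µS AIS conductance on a 0.08 pF compartment.  The desk
preset uses 0.01 ms; halving the step moves strongly driven spike times by
< 0.01 ms (tested).  Divergence (|V| > 1 V or NaN) aborts with the offending
compartment and time.  Somatic spikes are upward crossings of −20 mV with a
2 ms lockout, linearly interpolated between steps.  The −20 mV detector
(rather than 0 mV) is needed because with a passive soma the somatic AP
peaks near −9 mV when the AIS is distal; −20 mV still clears the
subthreshold band by > 5 SD.

## Stimulus and operating point

The somatic current is I(t) = I₀ + I₁ sin(2πft) + s·Iₙ(t), with Iₙ a
zero-mean unit-variance Ornstein–Uhlenbeck process generated by the exact
update x ← x·e^(−Δt/τ) + √(1−e^(−2Δt/τ))·ξ and a stationary start.

- **τ (noise correlation time): 5 ms.**  The value is a protocol parameter
  of the in-vitro experiments this pipeline mimics and materially affects
  the absolute bandwidth: longer correlation times preserve high-frequency
  transmission and raise the cutoff frequency of every model, shorter ones
  lower it.  All cutoff frequencies reported by this package are therefore
  to be read as "at τ = 5 ms".
- **Calibration.**  With I₁ = 0, `calibrate_operating_point` first rescales
  s linearly toward a subthreshold SD of 7.5 mV (accepted anywhere in
  5–10 mV), then brackets and bisects I₀ against the firing rate with frozen
  noise (the same realization at every iterate), stopping inside
  ±0.25 spike/s of the 5 spike/s target.  Because the model is tonically
  active at I = 0, the calibrated I₀ is hyperpolarizing: the operating point
  sits ≈ 14 mV below the leak reversal, which is also why the reduced eIF's
  effective resting potential (E_L ≈ −74 mV) lies below the cable model's
  leak reversal (−60 mV).
- **Sine amplitude: I₁ = 0.1·s.**  The modulation must stay in the linear
  regime; an explicit amplitude sweep (`experiments.linearity_check`)
  shows amplitude-independent normalized responses at I₁/s ≤ 0.1 and visible
  harmonic distortion by I₁/s ≈ 0.25.  At 5 spike/s this yields a rate
  modulation depth of ≈ 0.25.

## Gain estimation

Spike phases are pooled across repetitions (the sine has phase 0 at t = 0 in
each), and the modulation is 2‖r‖ of the pooled resultant, debiased for the
finite-sample Rayleigh floor via ρ̂² = (‖r‖² − 1/N)/(1 − 1/N).  The curve is
normalized at f = 1 cycle/s; because that single reference divides every
point, the desk and acceptance presets give the reference frequency extra
repetitions, and distance sweeps reuse the *same* noise realizations at
every distance (common random numbers) so that distance differences in the
cutoff are paired rather than swamped by shared normalization noise.

The cutoff (COF) is the first downward crossing of 0.70, interpolated
linearly in log f; the exponent α is the negated slope of log gain vs log f
over the top measured decade; the delay is −slope/2π of the unwrapped phase
Φ(f) = π/2 − arg r over the same window.  Errors per point are the SD over
repetitions (≥ 3 reps) or the analytic resultant SE.

## AP onset metrics

AP waveforms are averaged after aligning each spike at its onset — the last
upward crossing of dV/dt = 10 mV/ms before the detection point (searching
backward is robust to noise wobble in the AP foot).  On the averaged
waveform, the threshold is the voltage at the 10 mV/ms crossing
(interpolated) and the rapidity is the slope of a linear fit of dV/dt vs V
over the contiguous upstroke segment within ±2 mV/ms of the criterion; the
segment must be contiguous because the downstroke re-crosses the band near
the peak and would otherwise flatten the fit.  The phase-plane analysis is
restricted to −70…+50 mV.  Default averaging period: 40 s (≈ 200 APs at
5 spike/s).

## eIF reduction (dynamic I–V)

The empirical f(V) is the per-1-mV-bin average of dV/dt − (I − I_off)/C_m,
with centered-difference derivatives, bins below 50 samples masked, and a
blanking window after each detected spike (default 5 ms) to exclude the
downstroke/reset.  For point-neuron (reset) traces, ~3 samples before each
spike are blanked as well, because the centered difference straddles the
reset discontinuity.  C_m is estimated first by variance minimization in a
±2 mV slice around the median voltage: 1/C = Cov(dV/dt, I)/Var(I).

By default I_off is the mean injected current, so the DC holding current is
absorbed into the fitted E_L — the reduced neuron then reproduces the
operating point *at rest*, which is how the network experiments use it (and
why the reference table's E_L sits near the operating-point mean voltage).
Passing `i_offset=0` recovers the intrinsic relation instead; the
round-trip test (simulate a known eIF → re-estimate → refit, all four
parameters within 5 %) uses that mode.

The fit of f(V) = (E_L − V + Δ_T e^((V−V_T)/Δ_T))/τ_m uses weighted
(√count, capped) nonlinear least squares, multi-started over Δ_T and V_T,
and **excludes bins with f > 30 mV/ms**: beyond the initiation region the
somatic dV/dt saturates — the upstroke is slaved to the arriving axonal
spike — and no longer follows the single-exponential form.  The remaining
parameters follow the g_L = 14 nS convention with C_m = τ_m·g_L,
V_reset = −80 mV, t_ref = 2 ms, numerical cutoff 0 mV.

## Liquid state machine

1000 excitatory and 250 inhibitory eIF neurons (one parameter row per AIS
distance, from the package's reference reduction table).  Wiring: fixed
in-degree 28 (from E) and 48 (from I) per neuron, sampled without
replacement, no self-connections; 10 input units project to 70 excitatory
targets each (fixed out-degree).  Weights: recurrent ~ Normal(J, 0.7 J)
truncated at zero (J = 1.9/6.7/6.1/4.9 nA for EE/EI/IE/II), input
~ Uniform(0.5, 1.5)·8.9 nA.  Delays: Uniform(1, 10) ms from excitatory
sources and inputs, Uniform(0.1, 2) ms from inhibitory sources (an
equal-delay variant draws all from Uniform(0.1, 2) ms).  Synapses are
additive currents with instantaneous rise and exponential decay (3 ms
excitatory, 2 ms inhibitory).  Background noise: one independent
20 event/s Poisson source per neuron, 2 nA, excitatory kinetics, no delay,
no plasticity.

All recurrent synapses follow the standard short-term-plasticity recursion
uₙ = U + uₙ₋₁(1−U)e^(−Δt/F), Rₙ = 1 + (Rₙ₋₁ − Rₙ₋₁uₙ₋₁ − 1)e^(−Δt/D),
wₙ = w₀Rₙuₙ with R₁ = 1, u₁ = U and class constants
(U, D, F) = (0.59, 813, 1) EE, (0.049, 399, 1790) EI, (0.016, 45, 376) IE,
(0.25, 706, 21) II (ms).  Input synapses are static.  Since every synapse of
one presynaptic neuron onto one target population shares its constants and
spike history, the simulator keeps one (R, u) state per (neuron, target
population) pair — an exact optimization, verified against the per-synapse
recursion and a continuous-time RK4 oracle (≤ 10⁻⁶ relative error).

Integration: fixed 0.1 ms step, forward-Euler membrane update with the
spike-generating exponential tabulated, delays rounded to the grid, delivery
through a circular buffer.  Liquid states are the exponentially filtered
(τ = 20 ms) spike trains of 200 fixed random excitatory neurons, sampled at
the end of every 50 ms template presentation.  Templates: two fixed
10-channel Poisson patterns (20 event/s, 50 ms), presented in i.i.d. random
order, each spike jittered by N(0, 5 ms) and clipped to the window (a drop
mode exists).  The readout is regularized linear least squares (ridge 1.0,
unpenalized intercept) on the 200-dimensional states with a 0.5 threshold,
trained on 100 random 80/20 splits; the label is the XOR of the identities
of the last two templates.  A mean population rate above 200 spike/s raises
a runaway-activity warning.

## Scale presets and what the tests show

`production` matches the full-scale protocol: 0.005 ms step, 100 s × 100
repetitions per frequency on a 15-points-per-decade grid (1–1000 cycle/s),
11 distances, 50 networks, 500 s of network training.  `desk`, used by the
test suite and the acceptance script, runs at 0.01 ms with a 9-point grid,
60 s repetitions (3 below 100 cycle/s, 5 above, 6 at the f = 1 reference),
4 distances, 10 networks and 100 s of training; the acceptance script uses
120 s repetitions and 100 s recordings.  At desk scale the gain tail above
~300 cycle/s sits near the resultant noise floor, so the power-law fit
drops unresolved points (gain below twice its error) and uses a fixed
30–150 cycle/s window, keeping the exponent comparable across AIS
distances (beyond ~150 cycle/s the debiased tail estimates that survive
the resolution cut are upward noise fluctuations and flatten the fit); desk α values are therefore transition-region estimates, and
desk accuracies sit a few points below their 500 s asymptote (network
accuracy grows with training length and saturates near the full-scale
values).

The synthetic inputs emulate the *statistics* of the in-vitro protocol
(stationary colored noise, weak sinusoidal probe, Poisson templates with
Gaussian jitter).  They do not emulate synaptic conductances (input is
current-based), dendritic load (the model has no dendrites — effects tied
to large dendritic trees are outside this model's reach), channel noise, or
slow adaptation.  Passing tests therefore demonstrate the resistive-coupling
mechanism and the estimator chain, not a quantitative match to any specific
real neuron.

## Known limitations

- Absolute cutoff frequencies depend strongly on the noise correlation time
  τ and on the Na-kinetics parameterization; cross-study comparisons should
  match both before comparing numbers.
- The soma is passive; somatic Na/K would add a second (somatic)
  depolarizing phase to the AP and raise its peak.
- The eIF reduction is a plain eIF: no adaptation current, so
  spike-frequency adaptation and resonance phenomena are out of scope.
- The network takes its connectivity and weight constants as given; no
  parameter search is performed, and input synapses are assumed static.
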