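"""Synthetic stimulation waveforms and operating-point calibration.

The somatic current used throughout the package is the superposition of a DC
offset, a weak sine at harmonic frequency ``f`` and Ornstein--Uhlenbeck (OU)
colored noise,

    I(t) = I0 + I1 sin(2 pi f t) + s * In(t),

where ``In`` has zero mean, unit variance and exponential autocorrelation with
time constant ``tau_noise``.  The module also generates the 10-channel Poisson
spike templates (and their Gaussian-jittered versions) that drive the network
classification task.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "StimulusConfig",
    "OperatingPoint",
    "SpikeTemplate",
    "ou_noise",
    "compose_stimulus",
    "calibrate_operating_point",
    "make_templates",
    "jitter",
]


@dataclass(frozen=True)
class StimulusConfig:
    """Parameters of the sinusoid-in-noise current waveform.

    Currents in nA, times in ms except ``duration`` (s) and ``f`` (cycle/s).
    """

    I0: float = 0.0
    I1: float = 0.0
    f: float = 0.0
    s: float = 0.0
    tau_noise: float = 5.0
    dt: float = 0.01
    duration: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("noise SD s must be >= 0")
        if self.I1 < 0:
            raise ValueError("sine amplitude I1 must be >= 0")
        if self.f < 0:
            raise ValueError("harmonic frequency f must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * 1000.0 / self.dt))


@dataclass(frozen=True)
class OperatingPoint:
    """Calibrated DC offset and noise SD, with the achieved statistics."""

    I0: float
    s: float
    rate: float  # spike/s
    subthreshold_sd: float  # mV


def ou_noise(tau: float, n_samples: int, dt: float, seed) -> np.ndarray:
    """Stationary unit-variance OU series via the exact update
    ``x[k+1] = x[k] e^{-dt/tau} + sqrt(1 - e^{-2 dt/tau}) xi[k]``.

    ``tau`` and ``dt`` in ms.  The initial sample is drawn from the stationary
    distribution, so the series is stationary from the first sample.
    """
    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be positive")
    rng = np.random.default_rng(seed)
    a = np.exp(-dt / tau)
    b = np.sqrt(1.0 - a * a)
    xi = rng.standard_normal(n_samples)
    x = np.empty(n_samples)
    # scipy.signal.lfilter would do, but the recursion is the definition here
    acc = xi[0]  # stationary start
    x[0] = acc
    for k in range(1, n_samples):
        acc = acc * a + b * xi[k]
        x[k] = acc
    return x


def _ou_noise_fast(tau: float, n_samples: int, dt: float, seed) -> np.ndarray:
    """Vectorized equivalent of :func:`ou_noise` (same recursion via lfilter)."""
    from scipy.signal import lfilter

    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be positive")
    rng = np.random.default_rng(seed)
    a = np.exp(-dt / tau)
    b = np.sqrt(1.0 - a * a)
    xi = rng.standard_normal(n_samples)
    xi[0] /= b  # so that x[0] = xi_raw[0] ~ N(0, 1), matching the loop version
    return lfilter([b], [1.0, -a], xi)


def compose_stimulus(cfg: StimulusConfig) -> np.ndarray:
    """Sample-wise Eq-form current ``I0 + I1 sin(2 pi f t) + s In(t)`` (nA).

    The sine has phase 0 at t = 0; sample k sits at t = k*dt.
    """
    n = cfg.n_samples
    t_s = np.arange(n) * (cfg.dt * 1e-3)  # seconds
    wave = np.full(n, cfg.I0)
    if cfg.I1 > 0 and cfg.f > 0:
        wave += cfg.I1 * np.sin(2.0 * np.pi * cfg.f * t_s)
    if cfg.s > 0:
        wave += cfg.s * _ou_noise_fast(cfg.tau_noise, n, cfg.dt, cfg.seed)
    return wave


def calibrate_operating_point(
    run,
    target_rate: float = 5.0,
    rate_tol: float = 0.25,
    sd_range: tuple[float, float] = (5.0, 10.0),
    I0_init: float = 0.0,
    s_init: float = 0.02,
    max_iter: int = 40,
    seed: int = 0,
) -> OperatingPoint:
    """Adapt the DC offset ``I0`` and noise SD ``s`` so that a neuron fires at
    ``target_rate`` with subthreshold voltage fluctuations inside ``sd_range``.

    ``run(I0, s, seed)`` must return ``(rate, subthreshold_sd)`` for a
    simulation with the sine disabled (I1 = 0).  The search first rescales
    ``s`` linearly toward the middle of ``sd_range`` (voltage SD is close to
    proportional to ``s`` in the subthreshold regime), then brackets and
    bisects ``I0`` against the firing rate with frozen noise, so the
    rate-vs-I0 relation seen by the bisection is deterministic and monotone.
    """
    sd_target = 0.5 * (sd_range[0] + sd_range[1])
    s = float(s_init)
    rate, sd = run(I0_init, s, seed)
    for _ in range(4):
        if sd_range[0] <= sd <= sd_range[1]:
            break
        if sd <= 0:
            raise RuntimeError("calibration: measured zero subthreshold SD")
        s *= sd_target / sd
        rate, sd = run(I0_init, s, seed)
    else:
        raise RuntimeError(
            f"calibration: subthreshold SD {sd:.2f} mV not inside {sd_range}"
        )

    # bracket the target rate in I0
    I_lo = I_hi = float(I0_init)
    r_ref = rate
    step = max(0.5 * s, 1e-3)
    it = 0
    while r_ref < target_rate:  # push up
        I_hi += step
        r_hi, _ = run(I_hi, s, seed)
        if r_hi >= target_rate:
            I_lo = I_hi - step
            break
        step *= 2.0
        it += 1
        if it > max_iter:
            raise RuntimeError("calibration: failed to bracket target rate (high)")
    else:
        while True:  # r_ref >= target: push down
            I_lo -= step
            r_lo, _ = run(I_lo, s, seed)
            if r_lo <= target_rate:
                I_hi = I_lo + step
                break
            step *= 2.0
            it += 1
            if it > max_iter:
                raise RuntimeError(
                    "calibration: failed to bracket target rate (low); "
                    f"last iterate I0={I_lo:.4g}, rate={r_lo:.3g}"
                )

    rate = sd_last = None
    for _ in range(max_iter):
        I_mid = 0.5 * (I_lo + I_hi)
        rate, sd_last = run(I_mid, s, seed)
        if abs(rate - target_rate) <= rate_tol:
            return OperatingPoint(I0=I_mid, s=s, rate=rate, subthreshold_sd=sd_last)
        if rate < target_rate:
            I_lo = I_mid
        else:
            I_hi = I_mid
    raise RuntimeError(
        "calibration: bisection did not converge; "
        f"last iterate I0={0.5 * (I_lo + I_hi):.4g}, rate={rate:.3g}"
    )


# ---------------------------------------------------------------------------
# Poisson spike templates for the network task
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpikeTemplate:
    """Fixed multi-channel spike pattern (times in ms within [0, duration])."""

    times: tuple[tuple[float, ...], ...]  # per-channel spike times, ms
    n_channels: int = 10
    duration: float = 50.0  # ms
    rate: float = 20.0  # event/s per channel
    jitter_sd: float = 0.0  # ms; 0 for a base template

    def __post_init__(self) -> None:
        if len(self.times) != self.n_channels:
            raise ValueError("times must have one tuple per channel")
        for ch in self.times:
            for t in ch:
                if not (0.0 <= t <= self.duration):
                    raise ValueError("spike time outside [0, duration]")

    @property
    def n_spikes(self) -> int:
        return sum(len(ch) for ch in self.times)


def _poisson_template(rng: np.random.Generator, n_channels, duration, rate) -> SpikeTemplate:
    chans = []
    for _ in range(n_channels):
        n = rng.poisson(rate * duration * 1e-3)
        chans.append(tuple(np.sort(rng.uniform(0.0, duration, n))))
    return SpikeTemplate(times=tuple(chans), n_channels=n_channels,
                         duration=duration, rate=rate)


def make_templates(seed, n_channels: int = 10, duration: float = 50.0,
                   rate: float = 20.0) -> tuple[SpikeTemplate, SpikeTemplate]:
    """Two fixed base templates: homogeneous Poisson spikes per channel
    (default 10 channels, 50 ms, 20 event/s)."""
    rng = np.random.default_rng(seed)
    return (_poisson_template(rng, n_channels, duration, rate),
            _poisson_template(rng, n_channels, duration, rate))


def jitter(template: SpikeTemplate, sd: float = 5.0, seed=None, mode: str = "clip") -> SpikeTemplate:
    """Add i.i.d. zero-mean Gaussian shifts (SD ``sd`` ms) to every spike.

    Times leaving [0, duration] are clipped to the boundary (``mode="clip"``,
    default) or removed (``mode="drop"``).
    """
    if mode not in ("clip", "drop"):
        raise ValueError("mode must be 'clip' or 'drop'")
    rng = np.random.default_rng(seed)
    chans = []
    for ch in template.times:
        t = np.asarray(ch) + sd * rng.standard_normal(len(ch))
        if mode == "clip":
            t = np.clip(t, 0.0, template.duration)
        else:
            t = t[(t >= 0.0) & (t <= template.duration)]
        chans.append(tuple(np.sort(t)))
    return replace(template, times=tuple(chans), jitter_sd=sd)
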