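"""Dynamic transfer gain and phase from spike times via circular statistics.

For spikes at times ``t_k`` (s) recorded under a stimulus containing a weak
sine at harmonic frequency ``f`` (cycle/s), the resultant

    r = (1/N) sum_k exp(j 2 pi f t_k)

estimates the modulation of the instantaneous firing rate: writing
``r(t) = r0 + r1 sin(2 pi f t + Phi)``, the transfer gain (modulation index
``r1/r0``) equals ``2 |r|`` and the phase satisfies ``Phi = pi/2 - angle(r)``.
Gain curves are normalized at f = 1 cycle/s; the cutoff frequency (COF) is
the first downward crossing of 0.70 (~ -3 dB), the high-frequency tail is a
``1/f^alpha`` power law, and the linear trend of ``Phi(f)`` at high f gives
the propagation delay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "PhaseVector",
    "GainCurve",
    "GainFit",
    "LogisticFit",
    "vector_strength",
    "gain_curve",
    "cutoff_frequency",
    "powerlaw_exponent",
    "phase_delay",
    "fit_logistic",
    "logistic",
]


@dataclass(frozen=True)
class PhaseVector:
    """Complex resultant of spike phases at one harmonic frequency."""

    r: complex
    n: int
    f: float  # cycle/s

    @property
    def magnitude(self) -> float:
        return abs(self.r)

    @property
    def angle(self) -> float:
        return float(np.angle(self.r))

    @property
    def phase(self) -> float:
        """Response phase Phi in r(t) = r0 + r1 sin(2 pi f t + Phi),
        wrapped to (-pi, pi]."""
        phi = math.pi / 2.0 - self.angle
        return float((phi + math.pi) % (2.0 * math.pi) - math.pi)


def vector_strength(spike_times_s: np.ndarray, f: float) -> PhaseVector:
    """Resultant ``(1/N) sum exp(j 2 pi f t_k)`` of spike times (s)."""
    t = np.asarray(spike_times_s, dtype=float)
    if t.size == 0:
        raise ValueError("vector strength undefined for an empty spike train")
    z = np.exp(2j * np.pi * f * t)
    return PhaseVector(r=complex(z.mean()), n=t.size, f=float(f))


@dataclass(frozen=True)
class GainCurve:
    """Transfer gain/phase vs harmonic frequency.

    ``raw`` is twice the pooled resultant magnitude per frequency (debiased
    for the finite-N Rayleigh floor), ``gain`` the same normalized to the
    value at 1 cycle/s.  ``gain_sd`` is the SD over repetitions, propagated
    through the normalization.
    """

    f: np.ndarray
    raw: np.ndarray
    gain: np.ndarray
    gain_sd: np.ndarray
    phase: np.ndarray
    n_spikes: np.ndarray
    r0: float
    n_reps: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "f": self.f, "gain": self.gain, "gain_sd": self.gain_sd,
            "phase": self.phase, "N": self.n_spikes,
        })


def _debiased_modulation(z_sum: complex, n: int) -> float:
    """2|r| with the incoherent floor removed: E|r|^2 = rho^2 + (1-rho^2)/N,
    so rho_hat^2 = (|r|^2 - 1/N) / (1 - 1/N), clipped at zero."""
    r2 = abs(z_sum / n) ** 2
    rho2 = max((r2 - 1.0 / n) / (1.0 - 1.0 / n), 0.0) if n > 1 else r2
    return 2.0 * math.sqrt(rho2)


def gain_curve(spikes_per_f: dict[float, list[np.ndarray]], r0: float,
               f_ref: float = 1.0, debias: bool = True) -> GainCurve:
    """Build the normalized gain curve from spike sets per frequency.

    ``spikes_per_f`` maps each harmonic frequency to a list of spike-time
    arrays (s), one per repetition; repetitions are pooled before the
    resultant is taken (the sine has phase 0 at t = 0 in every repetition, so
    pooling is phase-coherent).  The curve is normalized by its value at
    ``f_ref`` (must be present).
    """
    freqs = np.array(sorted(spikes_per_f))
    if not np.any(np.isclose(freqs, f_ref)):
        raise ValueError(f"reference frequency {f_ref} cycle/s missing: "
                         "the gain curve cannot be normalized")
    raw = np.empty(freqs.size)
    phase = np.empty(freqs.size)
    n_spk = np.zeros(freqs.size, dtype=int)
    n_reps = np.zeros(freqs.size, dtype=int)
    sd_raw = np.zeros(freqs.size)
    for i, f in enumerate(freqs):
        reps = [np.asarray(s, dtype=float) for s in spikes_per_f[f]]
        pooled = np.concatenate(reps) if reps else np.empty(0)
        if pooled.size == 0:
            raise ValueError(f"no spikes at f = {f} cycle/s")
        z = np.exp(2j * np.pi * f * pooled).sum()
        n = pooled.size
        raw[i] = _debiased_modulation(z, n) if debias else 2.0 * abs(z) / n
        phase[i] = PhaseVector(r=z / n, n=n, f=f).phase
        n_spk[i] = n
        n_reps[i] = len(reps)
        per_rep = [_debiased_modulation(np.exp(2j * np.pi * f * s).sum(), s.size)
                   for s in reps if s.size > 1]
        if len(per_rep) >= 3:
            sd_raw[i] = np.std(per_rep, ddof=1) / math.sqrt(len(per_rep))
        else:  # analytic resultant SE for a single long run
            sd_raw[i] = 2.0 * math.sqrt(max(1.0 - (raw[i] / 2) ** 2, 0.0) / (2 * n))
    i_ref = int(np.argmin(np.abs(freqs - f_ref)))
    g_ref = raw[i_ref]
    if g_ref <= 0:
        raise ValueError("zero gain at the reference frequency")
    return GainCurve(f=freqs, raw=raw, gain=raw / g_ref, gain_sd=sd_raw / g_ref,
                     phase=phase, n_spikes=n_spk, r0=float(r0), n_reps=n_reps)


def cutoff_frequency(curve: GainCurve, level: float = 0.70) -> float:
    """COF: first downward crossing of ``level`` on the normalized curve,
    interpolated linearly in log f."""
    g = curve.gain
    f = curve.f
    for i in range(len(f) - 1):
        if g[i] >= level > g[i + 1]:
            lf = np.log(f[i]) + (level - g[i]) * (np.log(f[i + 1]) - np.log(f[i])) / (g[i + 1] - g[i])
            return float(np.exp(lf))
    raise ValueError("COF outside measured band: the normalized gain never "
                     f"crosses {level} downward on the grid")


def _top_decade(f: np.ndarray) -> np.ndarray:
    return f >= f.max() / 10.0


def powerlaw_exponent(curve: GainCurve, f_window: tuple[float, float] | None = None,
                      min_snr: float = 0.0) -> float:
    """Exponent alpha of the high-frequency ``1/f^alpha`` tail: negated
    least-squares slope of log(gain) vs log(f).

    Default window: the top measured frequency decade.  With ``min_snr`` set,
    points whose gain is below ``min_snr`` times their error are dropped
    first and the decade is taken over the remaining (resolved) frequencies —
    at reduced problem sizes the extreme tail sits at the resultant noise
    floor and would otherwise contribute pure noise to the fit.
    """
    ok = curve.gain > 0
    if min_snr > 0:
        ok &= curve.gain >= min_snr * curve.gain_sd
    if f_window is None:
        if np.any(ok):
            mask = ok & (curve.f >= curve.f[ok].max() / 10.0)
        else:
            mask = ok
        if mask.sum() < 3:  # sparse data: highest three positive-gain points
            pos = np.flatnonzero(curve.gain > 0)
            if pos.size < 3:
                raise ValueError("power-law fit needs >= 3 positive-gain points")
            mask = np.zeros_like(ok)
            mask[pos[-3:]] = True
    else:
        in_win = (curve.f >= f_window[0]) & (curve.f <= f_window[1])
        mask = ok & in_win
        if mask.sum() < 3:  # sparse data: drop the SNR mask before giving up
            mask = (curve.gain > 0) & in_win
    if mask.sum() < 3:
        raise ValueError("power-law fit needs >= 3 positive-gain points in the window")
    slope = np.polyfit(np.log(curve.f[mask]), np.log(curve.gain[mask]), 1)[0]
    return float(-slope)


def phase_delay(curve: GainCurve, f_window: tuple[float, float] | None = None) -> float:
    """Propagation delay (ms) from the linear high-f trend of the phase:
    delta_t = -slope(Phi vs f) / (2 pi)."""
    if f_window is None:
        mask = _top_decade(curve.f)
    else:
        mask = (curve.f >= f_window[0]) & (curve.f <= f_window[1])
    if mask.sum() < 2:
        raise ValueError("phase-delay fit needs >= 2 points in the window")
    f = curve.f[mask]
    phi = np.unwrap(curve.phase[mask])
    slope = np.polyfit(f, phi, 1)[0]  # rad per (cycle/s) = rad*s
    return float(-slope / (2.0 * np.pi) * 1e3)  # ms


@dataclass(frozen=True)
class GainFit:
    """Summary descriptors of one gain curve."""

    alpha: float
    cof: float  # cycle/s
    delay_ms: float
    f_window: tuple[float, float]


def logistic(d, a, k, d0, b):
    """COF(d) = a / (1 + exp(-k (d - d0))) + b."""
    x = np.clip(-k * (np.asarray(d, dtype=float) - d0), -500.0, 500.0)
    return a / (1.0 + np.exp(x)) + b


@dataclass(frozen=True)
class LogisticFit:
    a: float
    k: float
    d0: float
    b: float
    residual: float  # RMS of the fit residuals

    def __call__(self, d):
        return logistic(d, self.a, self.k, self.d0, self.b)

    @property
    def degenerate(self) -> bool:
        """Flat data: no resolvable sigmoid (negligible amplitude or slope)."""
        return abs(self.a) < 1e-6 or abs(self.k) < 1e-6


def fit_logistic(d_values, cof_values, sd=None) -> LogisticFit:
    """Nonlinear least squares of the four-parameter logistic to COF(d),
    with multi-start initialization over the midpoint and steepness."""
    d = np.asarray(d_values, dtype=float)
    y = np.asarray(cof_values, dtype=float)
    if np.unique(d).size < 4:
        raise ValueError("logistic fit needs >= 4 distinct distances")
    span = max(y.max() - y.min(), 1e-12)
    starts = []
    for k0 in (0.02, 0.05, 0.15, 0.5):
        for d00 in (np.median(d), d.min() + 0.75 * (d.max() - d.min()), d.max()):
            starts.append((span, k0, d00, y.min()))
    best = None
    tried = []
    import warnings as _warnings

    from scipy.optimize import OptimizeWarning
    for p0 in starts:
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(logistic, d, y, p0=p0, sigma=sd, maxfev=20000)
        except RuntimeError:
            tried.append(p0)
            continue
        res = float(np.sqrt(np.mean((logistic(d, *popt) - y) ** 2)))
        if best is None or res < best[1]:
            best = (popt, res)
    if best is None:
        raise RuntimeError(f"logistic fit did not converge; starts tried: {tried}")
    (a, k, d0, b), res = best
    return LogisticFit(a=float(a), k=float(k), d0=float(d0), b=float(b), residual=res)
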