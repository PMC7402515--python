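"""Phase-plane analysis of somatic action-potential waveforms.

APs recorded under noisy-only stimulation are aligned at their onset — the
first moment the somatic dV/dt exceeds 10 mV/ms — and averaged.  From the
mean waveform, the onset (threshold) voltage is the potential at that
crossing and the rapidity is the slope of the phase-plane trajectory
d(dV/dt)/dV at the crossing, obtained from a local linear fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cable import SpikeTrain, VoltageTrace

__all__ = ["APWaveform", "OnsetMetrics", "extract_waveforms", "onset_metrics"]

ONSET_DVDT = 10.0  # mV/ms, conventional AP onset criterion
PHASE_WINDOW = (-70.0, 50.0)  # mV, voltage range of the phase-plane analysis


@dataclass(frozen=True)
class APWaveform:
    """Spike-aligned average AP (time grid relative to onset)."""

    t: np.ndarray  # ms, 0 at the onset crossing
    v: np.ndarray  # mV
    dvdt: np.ndarray  # mV/ms
    n_aps: int
    n_skipped: int  # APs dropped because of overlapping windows


@dataclass(frozen=True)
class OnsetMetrics:
    v_threshold: float  # mV at the 10 mV/ms crossing
    rapidity: float  # 1/ms, phase slope at onset
    onset_time: float  # ms within the waveform grid


def _onset_index(v: np.ndarray, dvdt: np.ndarray, lo: int, hi: int) -> int | None:
    """First upward crossing of ONSET_DVDT inside [lo, hi), restricted to the
    phase-plane voltage window."""
    for i in range(max(lo, 1), min(hi, v.size)):
        if (dvdt[i] >= ONSET_DVDT and dvdt[i - 1] < ONSET_DVDT
                and PHASE_WINDOW[0] <= v[i] <= PHASE_WINDOW[1]):
            return i
    return None


def extract_waveforms(trace: VoltageTrace, spikes: SpikeTrain,
                      window: tuple[float, float] = (-3.0, 4.0)) -> APWaveform:
    """Average somatic AP waveform, aligned at the 10 mV/ms onset crossing.

    ``window`` (ms) is taken around the onset of each AP.  APs whose window
    would overlap a neighbor (ISI shorter than the window) or run off the
    trace are skipped and counted.
    """
    if spikes.n == 0:
        raise ValueError("no spikes: cannot extract AP waveforms")
    dt = trace.dt
    v = trace.v_soma
    dvdt = np.gradient(v, dt)
    pre = int(round(-window[0] / dt))
    post = int(round(window[1] / dt))
    t_ms = spikes.times * 1e3
    acc_v = np.zeros(pre + post + 1)
    acc_d = np.zeros(pre + post + 1)
    n_ok = 0
    n_skip = 0
    win_ms = window[1] - window[0]
    for j, ts in enumerate(t_ms):
        if (j > 0 and ts - t_ms[j - 1] < win_ms) or \
           (j + 1 < t_ms.size and t_ms[j + 1] - ts < win_ms):
            n_skip += 1
            continue
        k_det = int(round(ts / dt)) - 1  # sample index of threshold crossing
        # walk back from the detection point to the last upward crossing of
        # the onset criterion (robust to noise wobble in the AP foot)
        j = min(k_det + 1, v.size - 1)
        lim = k_det - int(round(3.0 / dt))
        while j > max(lim, 1) and dvdt[j] < ONSET_DVDT:
            j -= 1
        while j > max(lim, 1) and dvdt[j - 1] >= ONSET_DVDT:
            j -= 1
        onset = j if dvdt[j] >= ONSET_DVDT > dvdt[j - 1] else None
        if onset is None or onset - pre < 0 or onset + post >= v.size:
            n_skip += 1
            continue
        acc_v += v[onset - pre:onset + post + 1]
        acc_d += dvdt[onset - pre:onset + post + 1]
        n_ok += 1
    if n_ok == 0:
        raise ValueError("no usable APs after skipping overlaps")
    t = (np.arange(pre + post + 1) - pre) * dt
    return APWaveform(t=t, v=acc_v / n_ok, dvdt=acc_d / n_ok,
                      n_aps=n_ok, n_skipped=n_skip)


def onset_metrics(wf: APWaveform, fit_band: float = 2.0) -> OnsetMetrics:
    """Threshold potential and rapidity at the 10 mV/ms onset.

    The rapidity is the slope of a linear fit of dV/dt vs V over the
    phase-plane points within ``fit_band`` mV/ms of the onset criterion
    (default +-2 mV/ms), on the upstroke.
    """
    i = _onset_index(wf.v, wf.dvdt, 1, wf.v.size)
    if i is None:
        raise ValueError("subthreshold waveform: dV/dt never crosses "
                         f"{ONSET_DVDT} mV/ms inside {PHASE_WINDOW} mV")
    # interpolate the crossing voltage
    f = (ONSET_DVDT - wf.dvdt[i - 1]) / (wf.dvdt[i] - wf.dvdt[i - 1])
    v_thr = wf.v[i - 1] + f * (wf.v[i] - wf.v[i - 1])
    # local tangent in the phase plane: contiguous upstroke segment whose
    # dV/dt lies within the band around the criterion (the downstroke
    # recrosses the band near the peak and must not contaminate the fit)
    lo = i - 1
    while lo > 0 and wf.dvdt[lo - 1] >= ONSET_DVDT - fit_band:
        lo -= 1
    hi = i
    while hi + 1 < wf.v.size and wf.dvdt[hi + 1] <= ONSET_DVDT + fit_band:
        hi += 1
    if hi - lo + 1 < 3:  # steep waveform: use the nearest samples instead
        lo, hi = max(i - 2, 0), min(i + 1, wf.v.size - 1)
    slope = np.polyfit(wf.v[lo:hi + 1], wf.dvdt[lo:hi + 1], 1)[0]
    return OnsetMetrics(v_threshold=float(v_thr), rapidity=float(slope),
                        onset_time=float(wf.t[i - 1] + f * (wf.t[1] - wf.t[0])))
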