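"""Exponential integrate-and-fire (eIF) reduction via the dynamic I-V method.

The membrane equation of the eIF point neuron is

    C_m dV/dt = g_L (E_L - V) + g_L Delta_T exp((V - V_T)/Delta_T) + I(t),

equivalently dV/dt = f(V) + I/C_m with

    f(V) = (1/tau_m) (E_L - V + Delta_T exp((V - V_T)/Delta_T)).

From a voltage trace of a spiking neuron driven by a known current, f(V) is
estimated empirically as the voltage-conditioned average of dV/dt - I/C_m
(the "dynamic I-V curve"), with a blanking window after each spike to exclude
the stereotyped AP/reset trajectory.  Fitting the analytic f(V) to the
empirical curve yields tau_m, E_L, V_T and Delta_T; the membrane capacitance
is estimated beforehand by minimizing, within a subthreshold voltage slice,
the variance of dV/dt - I/C over C.

``REFERENCE_EIF_TABLE`` holds the package's reference eIF parameter sets
for the ball-and-stick reduction at AIS distances 0..50 um; the network
experiments take these as their neuron models.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import curve_fit

from .cable import SpikeTrain, VoltageTrace

__all__ = [
    "IVCurve",
    "EIFParams",
    "REFERENCE_EIF_TABLE",
    "reference_eif_params",
    "estimate_capacitance",
    "empirical_iv",
    "fit_eif",
    "simulate_eif",
    "rheobase",
    "coincidence_fraction",
]

G_L_DEFAULT = 14.0  # nS; C_m = tau_m * g_L

# Reference reduction of the ball-and-stick model: one eIF parameter set per
# AIS-soma distance (um). Columns: d, tau_m (ms), E_L (mV), V_T (mV), Delta_T (mV).
_REFERENCE_TABLE_CSV = """d,tau_m,E_L,V_T,Delta_T
0,3.40,-74.14,-62.34,4.57
5,5.05,-74.04,-61.28,3.31
10,5.93,-74.09,-60.61,2.66
15,6.89,-74.27,-59.90,2.09
20,7.85,-74.51,-59.14,1.63
25,7.60,-74.39,-59.16,1.50
30,7.86,-74.46,-58.95,1.29
35,7.58,-74.36,-59.14,1.25
40,7.70,-74.39,-59.01,1.10
45,7.74,-74.40,-58.96,0.98
50,7.76,-74.40,-58.89,0.87
"""

REFERENCE_EIF_TABLE: pd.DataFrame = pd.read_csv(_io.StringIO(_REFERENCE_TABLE_CSV))


@dataclass(frozen=True)
class EIFParams:
    """eIF parameters.  tau_m = C_m / g_L always holds."""

    tau_m: float  # ms
    E_L: float  # mV
    V_T: float  # mV
    Delta_T: float  # mV
    g_L: float = G_L_DEFAULT  # nS
    V_reset: float = -80.0  # mV
    t_ref: float = 2.0  # ms
    V_cut: float = 0.0  # mV, numerical spike cutoff

    def __post_init__(self) -> None:
        if self.Delta_T <= 0:
            raise ValueError("Delta_T must be positive")
        if self.V_reset >= self.V_T:
            raise ValueError("V_reset must lie below V_T")

    @property
    def C_m(self) -> float:
        return self.tau_m * self.g_L  # ms * nS = pF

    def f(self, v) -> np.ndarray:
        """Analytic f(V) in mV/ms."""
        v = np.asarray(v, dtype=float)
        return (self.E_L - v + self.Delta_T
                * np.exp((v - self.V_T) / self.Delta_T)) / self.tau_m

    @property
    def rheobase(self) -> float:
        """Minimal sustained current for repetitive firing (nA):
        I = g_L (V_T - E_L - Delta_T), the maximum of -f(V)*C_m."""
        return self.g_L * (self.V_T - self.E_L - self.Delta_T) * 1e-3


def reference_eif_params(d: float, **overrides) -> EIFParams:
    """The reference eIF parameter set for AIS distance ``d`` (um)."""
    row = REFERENCE_EIF_TABLE[REFERENCE_EIF_TABLE.d == d]
    if row.empty:
        raise KeyError(f"no reference eIF parameters for d = {d} um "
                       f"(available: {list(REFERENCE_EIF_TABLE.d)})")
    r = row.iloc[0]
    return EIFParams(tau_m=float(r.tau_m), E_L=float(r.E_L), V_T=float(r.V_T),
                     Delta_T=float(r.Delta_T), **overrides)


@dataclass(frozen=True)
class IVCurve:
    """Binned dynamic I-V estimate: mean of dV/dt - I/C_m per voltage bin."""

    v: np.ndarray  # bin centers, mV
    f: np.ndarray  # mV/ms
    counts: np.ndarray
    bin_width: float
    C_m: float  # pF, capacitance used for the I/C term
    min_count: int = 50

    @property
    def usable(self) -> np.ndarray:
        return self.counts >= self.min_count

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"v": self.v, "f": self.f, "count": self.counts})


def _subthreshold_mask(n: int, dt: float, spikes: SpikeTrain,
                       blank_after_ms: float, blank_before_ms: float) -> np.ndarray:
    mask = np.ones(n, dtype=bool)
    for ts in spikes.times * 1e3:
        lo = max(int((ts - blank_before_ms) / dt), 0)
        hi = min(int((ts + blank_after_ms) / dt) + 1, n)
        mask[lo:hi] = False
    mask[0] = mask[-1] = False  # centered differences undefined at the ends
    return mask


def estimate_capacitance(trace: VoltageTrace, current_nA: np.ndarray,
                         spikes: SpikeTrain, slice_halfwidth: float = 2.0,
                         blank_after_ms: float = 5.0) -> float:
    """Membrane capacitance (pF) by variance minimization: within a
    subthreshold voltage slice around the median potential, the C that
    minimizes Var(dV/dt - I/C) is Var(I)/Cov(dV/dt, I)."""
    v = trace.v_soma
    dvdt = np.gradient(v, trace.dt)
    mask = _subthreshold_mask(v.size, trace.dt, spikes, blank_after_ms, 1.0)
    v_mid = np.median(v[mask])
    sel = mask & (np.abs(v - v_mid) <= slice_halfwidth)
    if sel.sum() < 100:
        raise ValueError("too few subthreshold samples for capacitance estimation")
    i_pa = current_nA[:v.size][sel] * 1e3
    dv = dvdt[sel]
    cov = np.cov(dv, i_pa)
    if cov[0, 1] <= 0:
        raise ValueError("non-positive Cov(dV/dt, I): capacitance undefined")
    return float(cov[1, 1] / cov[0, 1])  # pF (pA per mV/ms)


def empirical_iv(trace: VoltageTrace, current_nA: np.ndarray, C_m: float,
                 bin_width: float = 1.0, spikes: SpikeTrain | None = None,
                 blank_after_ms: float = 5.0, blank_before_ms: float = 0.0,
                 v_range: tuple[float, float] = (-100.0, -30.0),
                 min_count: int = 50, i_offset: float | None = None) -> IVCurve:
    """Dynamic I-V curve: per-voltage-bin average of dV/dt - (I - I_off)/C_m.

    Samples within ``blank_after_ms`` after each detected spike (and
    optionally ``blank_before_ms`` before) are excluded, removing the
    AP downstroke/reset transient; the exponential rise before the spike is
    deliberately kept, as it carries the spike-initiation current.

    ``i_offset`` (nA) is removed from the injected current before the
    subtraction.  By default it is the mean of the current, so the DC holding
    current of the operating point is absorbed into the effective resting
    potential E_L of the reduced neuron (which is then used at rest, without
    a holding current, in the network experiments).  Pass ``i_offset=0.0``
    to subtract the full current and recover the intrinsic I-V relation.
    """
    v = trace.v_soma
    n = v.size
    if current_nA.size < n:
        raise ValueError("current and trace must be sampled identically")
    dvdt = np.gradient(v, trace.dt)
    if spikes is not None:
        mask = _subthreshold_mask(n, trace.dt, spikes, blank_after_ms, blank_before_ms)
    else:
        mask = np.ones(n, dtype=bool)
        mask[[0, -1]] = False
    if i_offset is None:
        i_offset = float(current_nA[:n].mean())
    fval = dvdt - (current_nA[:n] - i_offset) * 1e3 / C_m  # mV/ms
    edges = np.arange(v_range[0], v_range[1] + bin_width / 2, bin_width)
    if edges.size < 3:
        raise ValueError("voltage range too narrow for the bin width")
    which = np.digitize(v, edges) - 1
    ok = mask & (which >= 0) & (which < edges.size - 1)
    if not np.any(ok):
        raise ValueError("no usable samples for the I-V estimate")
    nb = edges.size - 1
    counts = np.bincount(which[ok], minlength=nb)
    sums = np.bincount(which[ok], weights=fval[ok], minlength=nb)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = edges[:-1] + bin_width / 2
    return IVCurve(v=centers, f=means, counts=counts, bin_width=bin_width,
                   C_m=C_m, min_count=min_count)


def _eif_f(v, tau_m, E_L, V_T, Delta_T):
    # exp clamped: keeps ill-posed intermediate steps of the optimizer finite
    x = np.minimum((v - V_T) / Delta_T, 50.0)
    return (E_L - v + Delta_T * np.exp(x)) / tau_m


def fit_eif(iv: IVCurve, g_L: float = G_L_DEFAULT, f_max: float = 30.0,
            **eif_kwargs) -> tuple[EIFParams, float]:
    """Nonlinear least squares of the analytic eIF f(V) to the usable bins.

    Bins above ``f_max`` (mV/ms) are excluded: beyond the initiation region
    the somatic dV/dt saturates (the upstroke is slaved to the arriving
    axonal spike) and no longer follows the single-exponential form.
    Multi-start over Delta_T and V_T; bin weights are sqrt(count), capped so
    the densely sampled subthreshold bins cannot swamp the sparse initiation
    region.  Returns the fitted parameters and the RMS residual (mV/ms).
    """
    use = iv.usable & np.isfinite(iv.f)
    use &= ~(np.isfinite(iv.f) & (iv.f > f_max))
    v, y = iv.v[use], iv.f[use]
    if v.size < 6:
        raise ValueError("too few usable bins for the eIF fit")
    w = np.sqrt(np.minimum(iv.counts[use].astype(float), 1000.0))
    # the subthreshold branch sets tau_m / E_L starting values; the location
    # of the f(V) minimum approximates V_T
    v_min_f = float(v[np.argmin(y)])
    lin_sel = v <= v_min_f - 5.0
    if lin_sel.sum() >= 3:
        lin = np.polyfit(v[lin_sel], y[lin_sel], 1)
    else:
        lin = np.polyfit(v[: max(v.size // 2, 3)], y[: max(v.size // 2, 3)], 1)
    tau0 = -1.0 / lin[0] if lin[0] < 0 else 10.0
    el0 = -lin[1] / lin[0] if lin[0] < 0 else float(np.median(v))
    best = None
    import warnings as _warnings
    from scipy.optimize import OptimizeWarning
    for dt0 in (0.5, 1.0, 2.0, 4.0, 8.0):
        for vt0 in (v_min_f, v_min_f + 5.0, v.max()):
            try:
                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore", OptimizeWarning)
                    popt, _ = curve_fit(_eif_f, v, y, p0=(tau0, el0, vt0, dt0),
                                        sigma=1.0 / w, maxfev=20000)
            except RuntimeError:
                continue
            if popt[3] <= 0 or popt[0] <= 0:
                continue
            res = float(np.sqrt(np.mean((_eif_f(v, *popt) - y) ** 2)))
            if best is None or res < best[1]:
                best = (popt, res)
    if best is None:
        raise RuntimeError("eIF fit did not converge (or Delta_T <= 0 at optimum)")
    (tau_m, E_L, V_T, Delta_T), res = best
    return EIFParams(tau_m=float(tau_m), E_L=float(E_L), V_T=float(V_T),
                     Delta_T=float(Delta_T), g_L=g_L, **eif_kwargs), res


@njit(cache=True)
def _run_eif(v0, tau_m, E_L, V_T, Delta_T, v_reset, v_cut, refr_steps,
             inj_over_c, dt, v_rec, spikes):
    """inj_over_c: I/C_m in mV/ms, per step."""
    n_steps = inj_over_c.size
    v = v0
    n_sp = 0
    refr = 0
    exp_max = (v_cut - V_T) / Delta_T + 3.0
    for k in range(n_steps):
        if refr > 0:
            refr -= 1
        else:
            x = (v - V_T) / Delta_T
            if x > exp_max:
                x = exp_max
            dv = (E_L - v + Delta_T * np.exp(x)) / tau_m + inj_over_c[k]
            v = v + dt * dv
            if v >= v_cut:
                if n_sp < spikes.size:
                    spikes[n_sp] = (k + 1) * dt
                    n_sp += 1
                v = v_reset
                refr = refr_steps
        v_rec[k] = v
    return n_sp


def simulate_eif(params: EIFParams, stimulus_nA: np.ndarray, dt: float = 0.01,
                 v_init: float | None = None) -> tuple[VoltageTrace, SpikeTrain]:
    """Integrate the eIF under an injected current (nA, sampled at ``dt`` ms).

    A spike is recorded when V reaches ``V_cut``; V is then reset to
    ``V_reset`` and held for the absolute refractory period.
    """
    stim = np.ascontiguousarray(stimulus_nA, dtype=np.float64)
    v_rec = np.empty(stim.size)
    max_spikes = int(stim.size * dt / params.t_ref) + 16
    spikes = np.empty(max_spikes)
    v0 = params.E_L if v_init is None else v_init
    n_sp = _run_eif(v0, params.tau_m, params.E_L, params.V_T, params.Delta_T,
                    params.V_reset, params.V_cut,
                    max(1, int(round(params.t_ref / dt))),
                    stim * 1e3 / params.C_m, dt, v_rec, spikes)
    t = (np.arange(stim.size) + 1) * dt
    trace = VoltageTrace(t=t, v_soma=v_rec, dt=dt)
    train = SpikeTrain(times=spikes[:n_sp] * 1e-3, duration=stim.size * dt * 1e-3)
    return trace, train


def rheobase(params: EIFParams, i_max: float = 2.0, tol: float = 1e-4,
             probe_ms: float = 500.0) -> float:
    """Brute-force rheobase (nA): bisection on the DC current between a
    silent and a firing simulation."""
    def fires(i):
        stim = np.full(int(probe_ms / 0.01), i)
        _, sp = simulate_eif(params, stim, dt=0.01)
        return sp.n > 0

    lo, hi = 0.0, i_max
    if not fires(hi):
        raise ValueError("i_max below rheobase")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def coincidence_fraction(reference: SpikeTrain, test: SpikeTrain,
                         window_ms: float = 5.0) -> float:
    """Fraction of reference spikes matched by a test spike within
    +-``window_ms`` (each test spike used at most once)."""
    if reference.n == 0:
        raise ValueError("empty reference train")
    ref = reference.times * 1e3
    oth = test.times * 1e3
    used = np.zeros(oth.size, dtype=bool)
    hits = 0
    j = 0
    for t in ref:
        while j < oth.size and oth[j] < t - window_ms:
            j += 1
        k = j
        while k < oth.size and oth[k] <= t + window_ms:
            if not used[k]:
                used[k] = True
                hits += 1
                break
            k += 1
    return hits / ref.size
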