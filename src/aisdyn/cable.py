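"""Ball-and-stick (BAS) conductance-based neuron with a relocatable AIS.

The model is a single lumped soma attached to a cylindrical axon (default
1 um x 50 um) discretized into equal compartments (default 11).  Every axonal
compartment carries fast-inactivating Na (m^3 h) and delayed-rectifier K
currents plus leak; one compartment — the axon initial segment (AIS), the one
whose center is nearest a chosen distance ``d`` from the soma — carries ~100x
higher Na/K densities.  The soma is passive (leak only): the somatic spike is
the signature of the axo-somatic current dipole, which is the phenomenon under
study.

Numerics: spatially discretized cable equation advanced with a staggered
scheme — channel gates by exponential Euler (tabulated rates), then a
backward-Euler tridiagonal solve for the voltages.  This is stable at the
production step of 0.005 ms despite the stiff AIS conductances.

Units: mV, ms, nS, pF, um; membrane currents internally in pA, injected
currents at the API in nA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "CableGeometry",
    "ChannelDensities",
    "KineticsParams",
    "BASModel",
    "VoltageTrace",
    "SpikeTrain",
    "build_bas",
    "simulate",
    "input_resistance",
]


@dataclass(frozen=True)
class CableGeometry:
    """Geometry and passive constants of the soma + axon cable."""

    axon_diameter: float = 1.0  # um
    axon_length: float = 50.0  # um
    n_axon_compartments: int = 11
    soma_diameter: float = 20.0  # um (sphere)
    axial_resistivity: float = 150.0  # Ohm*cm
    specific_capacitance: float = 0.5625  # uF/cm^2 (axon)
    soma_specific_capacitance: float = 1.0  # uF/cm^2

    def __post_init__(self) -> None:
        for name in ("axon_diameter", "axon_length", "soma_diameter",
                     "axial_resistivity", "specific_capacitance",
                     "soma_specific_capacitance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_axon_compartments < 2:
            raise ValueError("need at least 2 axonal compartments")

    @property
    def compartment_length(self) -> float:
        return self.axon_length / self.n_axon_compartments

    @property
    def soma_area(self) -> float:
        return math.pi * self.soma_diameter**2  # sphere: pi d^2

    @property
    def compartment_area(self) -> float:
        return math.pi * self.axon_diameter * self.compartment_length

    def compartment_centers(self) -> np.ndarray:
        """Axon positions of compartment centers, um from the soma:
        (i + 0.5) * dx."""
        dx = self.compartment_length
        return (np.arange(self.n_axon_compartments) + 0.5) * dx


#: Alternative axonal leak density (pS/um^2).  The default axonal leak is
#: electrically negligible; this lossier value gives the cable a finite
#: passive length constant, useful for passive-circuit cross-checks.
G_LEAK_AXON_ALT = 0.33


@dataclass(frozen=True)
class ChannelDensities:
    """Maximal conductance densities and reversal potentials.

    Na/K densities in nS/um^2, leak in pS/um^2 (note the unit difference:
    leak is orders of magnitude sparser), potentials in mV.  ``g_leak_soma``
    sets the somatic leak (the soma is otherwise passive) and hence the input
    resistance and membrane time constant of the cell.
    """

    gNa_ais: float = 88.0
    gK_ais: float = 17.6
    gNa_axon: float = 0.8
    gK_axon: float = 0.16
    g_leak: float = 3.3e-5  # pS/um^2, axonal leak
    g_leak_soma: float = 1.25  # pS/um^2 -> somatic tau ~ 8 ms
    E_Na: float = 60.0
    E_K: float = -80.0
    E_leak: float = -60.0

    def __post_init__(self) -> None:
        if not self.gNa_ais > self.gNa_axon:
            raise ValueError("AIS Na density must exceed the axonal density")
        if not self.gK_ais > self.gK_axon:
            raise ValueError("AIS K density must exceed the axonal density")
        if not (self.E_Na > self.E_leak > self.E_K):
            raise ValueError("require E_Na > E_leak > E_K")


@dataclass(frozen=True)
class KineticsParams:
    """HH-style rate-function parameters for the axonal Na (m^3 h) and
    delayed-rectifier K (n) channels, in the trapezoid ('trap') form used for
    cortical axons; all voltages mV, rates 1/ms.

    Defaults follow the classic cortical-axon parameterization (Na activation
    half-slope 9 mV around -35 mV, inactivation steady state around -65 mV,
    Kv activation around +25 mV), with a Q10 temperature factor applied to
    all rates.
    """

    na_tha: float = -35.0
    na_qa: float = 9.0
    na_Ra: float = 0.182
    na_Rb: float = 0.124
    na_thi1: float = -50.0
    na_thi2: float = -75.0
    na_qi: float = 5.0
    na_Rd: float = 0.024
    na_Rg: float = 0.0091
    na_thinf: float = -65.0
    na_qinf: float = 6.2
    kv_tha: float = 25.0
    kv_qa: float = 9.0
    kv_Ra: float = 0.02
    kv_Rb: float = 0.002
    v_shift: float = 0.0
    q10: float = 2.3
    temp_c: float = 37.0
    temp_ref_c: float = 23.0

    @property
    def tadj(self) -> float:
        return self.q10 ** ((self.temp_c - self.temp_ref_c) / 10.0)


def _trap_pos(v, th, q):
    """(v-th) / (1 - exp(-(v-th)/q)), with the removable singularity at th."""
    x = np.asarray(v, dtype=float) - th
    with np.errstate(over="ignore"):
        den = 1.0 - np.exp(-x / q)
    out = np.where(np.abs(x) < 1e-6 * q, q * np.ones_like(x), x / np.where(den == 0, np.nan, den))
    return out


def rate_tables(kin: KineticsParams, dt: float,
                v_min: float = -130.0, v_max: float = 70.0,
                dv: float = 0.05):
    """Tabulate steady states and exponential-Euler decay factors for the
    three gates on a uniform voltage grid, for a fixed time step ``dt``."""
    v = np.arange(v_min, v_max + dv / 2, dv) + kin.v_shift
    tadj = kin.tadj
    # Na activation m
    am = kin.na_Ra * _trap_pos(v, kin.na_tha, kin.na_qa)
    bm = kin.na_Rb * _trap_pos(-v, -kin.na_tha, kin.na_qa)
    minf = am / (am + bm)
    em = np.exp(-dt * tadj * (am + bm))
    # Na inactivation h: tau from trap rates, steady state sigmoidal
    ah = kin.na_Rd * _trap_pos(v, kin.na_thi1, kin.na_qi)
    bh = kin.na_Rg * _trap_pos(-v, -kin.na_thi2, kin.na_qi)
    hinf = 1.0 / (1.0 + np.exp((v - kin.na_thinf) / kin.na_qinf))
    eh = np.exp(-dt * tadj * (ah + bh))
    # Kv activation n (first power)
    an = kin.kv_Ra * _trap_pos(v, kin.kv_tha, kin.kv_qa)
    bn = kin.kv_Rb * _trap_pos(-v, -kin.kv_tha, kin.kv_qa)
    ninf = an / (an + bn)
    en = np.exp(-dt * tadj * (an + bn))
    return (v_min, dv, minf, em, hinf, eh, ninf, en)


@dataclass(frozen=True)
class BASModel:
    """Compiled ball-and-stick model: per-compartment conductance table.

    Compartment 0 is the soma; 1..n are the axonal compartments ordered by
    distance.  Exactly one axonal compartment (``ais_index``, 0-based along
    the axon) carries the AIS densities.
    """

    geometry: CableGeometry
    densities: ChannelDensities
    kinetics: KineticsParams
    ais_distance: float  # um
    ais_index: int  # 0-based axonal compartment index
    cm: np.ndarray = field(repr=False)  # pF, len n+1
    g_na: np.ndarray = field(repr=False)  # nS
    g_k: np.ndarray = field(repr=False)  # nS
    g_leak: np.ndarray = field(repr=False)  # nS
    g_axial: np.ndarray = field(repr=False)  # nS, len n (soma-ax0, ax0-ax1, ...)

    @property
    def n_compartments(self) -> int:
        return self.cm.size

    def passive_copy(self) -> "BASModel":
        """Same cable with the active conductances zeroed (leak only)."""
        return replace(self, g_na=np.zeros_like(self.g_na),
                       g_k=np.zeros_like(self.g_k))

    def total_membrane_area(self) -> float:
        g = self.geometry
        return g.soma_area + g.n_axon_compartments * g.compartment_area


def build_bas(geometry: CableGeometry = CableGeometry(),
              densities: ChannelDensities = ChannelDensities(),
              d: float = 25.0,
              kinetics: KineticsParams = KineticsParams()) -> BASModel:
    """Assemble the BAS model with the AIS at axon distance ``d`` (um).

    The AIS densities land on the single compartment whose center is nearest
    ``d``; every other axonal compartment gets the plain axonal densities.
    """
    if not (0.0 <= d <= geometry.axon_length):
        raise ValueError(
            f"AIS distance d={d} um outside the axon [0, {geometry.axon_length}] um"
        )
    centers = geometry.compartment_centers()
    ais_index = int(np.argmin(np.abs(centers - d)))

    n = geometry.n_axon_compartments
    a_comp = geometry.compartment_area
    a_soma = geometry.soma_area

    cm = np.empty(n + 1)
    cm[0] = a_soma * geometry.soma_specific_capacitance * 1e-2  # uF/cm^2 -> pF/um^2
    cm[1:] = a_comp * geometry.specific_capacitance * 1e-2

    g_na = np.zeros(n + 1)
    g_k = np.zeros(n + 1)
    g_na[1:] = densities.gNa_axon * a_comp
    g_k[1:] = densities.gK_axon * a_comp
    g_na[1 + ais_index] = densities.gNa_ais * a_comp
    g_k[1 + ais_index] = densities.gK_ais * a_comp

    g_leak = np.empty(n + 1)
    g_leak[0] = densities.g_leak_soma * a_soma * 1e-3  # pS -> nS
    g_leak[1:] = densities.g_leak * a_comp * 1e-3

    # axial conductances: resistivity Ohm*cm -> Ohm*um (x 1e4)
    rho = geometry.axial_resistivity * 1e4
    a_cross = math.pi * geometry.axon_diameter**2 / 4.0
    dx = geometry.compartment_length
    g_seg = a_cross / (rho * dx) * 1e9  # S -> nS
    g_axial = np.full(n, g_seg)
    g_axial[0] = 2.0 * g_seg  # soma (isopotential) to first compartment center

    return BASModel(geometry=geometry, densities=densities, kinetics=kinetics,
                    ais_distance=float(d), ais_index=ais_index, cm=cm,
                    g_na=g_na, g_k=g_k, g_leak=g_leak, g_axial=g_axial)


@dataclass(frozen=True)
class VoltageTrace:
    """Uniformly sampled somatic voltage (and optionally all compartments)."""

    t: np.ndarray  # ms
    v_soma: np.ndarray  # mV
    dt: float  # ms between recorded samples
    v_all: np.ndarray | None = None  # (n_samples, n_compartments)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.v_soma)):
            raise ValueError("voltage trace contains non-finite values")


@dataclass(frozen=True)
class SpikeTrain:
    """Somatic spike times in seconds."""

    times: np.ndarray  # s, strictly increasing
    duration: float  # s

    def __post_init__(self) -> None:
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def rate(self) -> float:
        return self.n / self.duration


@njit(cache=True)
def _thomas(lo, di, up, rhs, x):
    n = di.size
    cp = np.empty(n)
    dp = np.empty(n)
    cp[0] = up[0] / di[0]
    dp[0] = rhs[0] / di[0]
    for i in range(1, n):
        m = di[i] - lo[i] * cp[i - 1]
        cp[i] = up[i] / m
        dp[i] = (rhs[i] - lo[i] * dp[i - 1]) / m
    x[n - 1] = dp[n - 1]
    for i in range(n - 2, -1, -1):
        x[i] = dp[i] - cp[i] * x[i + 1]


@njit(cache=True)
def _run_cable(v, m, h, nn, cm, g_na, g_k, g_leak, g_axial,
               e_na, e_k, e_leak, inj_pa, dt,
               tab_vmin, tab_dv, t_minf, t_em, t_hinf, t_eh, t_ninf, t_en,
               thresh, refr_steps, rec_every, v_rec, v_all_rec, record_all,
               spikes, settle_steps):
    """Advance the cable; returns (n_spikes, status, bad_comp, bad_step).

    status 0 = ok, 1 = non-finite/overflow voltage.
    """
    nc = v.size
    n_steps = inj_pa.size
    nv = t_minf.size
    lo = np.empty(nc)
    di = np.empty(nc)
    up = np.empty(nc)
    rhs = np.empty(nc)
    vn = np.empty(nc)
    n_sp = 0
    last_sp_step = -10**9
    rec_i = 0
    v_prev_soma = v[0]
    for k in range(-settle_steps, n_steps):
        i_inj = inj_pa[0] if k < 0 else inj_pa[k]
        # gate update (exponential Euler, tabulated)
        for i in range(1, nc):
            x = (v[i] - tab_vmin) / tab_dv
            if x < 0.0:
                x = 0.0
            elif x > nv - 1.001:
                x = nv - 1.001
            j = int(x)
            w = x - j
            minf = t_minf[j] + w * (t_minf[j + 1] - t_minf[j])
            em = t_em[j] + w * (t_em[j + 1] - t_em[j])
            hinf = t_hinf[j] + w * (t_hinf[j + 1] - t_hinf[j])
            eh = t_eh[j] + w * (t_eh[j + 1] - t_eh[j])
            ninf = t_ninf[j] + w * (t_ninf[j + 1] - t_ninf[j])
            en = t_en[j] + w * (t_en[j + 1] - t_en[j])
            m[i] = minf + (m[i] - minf) * em
            h[i] = hinf + (h[i] - hinf) * eh
            nn[i] = ninf + (nn[i] - ninf) * en
        # assemble tridiagonal backward-Euler system
        for i in range(nc):
            gna = g_na[i] * m[i] * m[i] * m[i] * h[i]
            gk = g_k[i] * nn[i]
            gtot = gna + gk + g_leak[i]
            diag = cm[i] / dt + gtot
            r = cm[i] / dt * v[i] + gna * e_na + gk * e_k + g_leak[i] * e_leak
            if i == 0:
                r += i_inj
                diag += g_axial[0]
                up[i] = -g_axial[0]
                lo[i] = 0.0
            else:
                diag += g_axial[i - 1]
                lo[i] = -g_axial[i - 1]
                if i < nc - 1:
                    diag += g_axial[i]
                    up[i] = -g_axial[i]
                else:
                    up[i] = 0.0
            di[i] = diag
            rhs[i] = r
        _thomas(lo, di, up, rhs, vn)
        for i in range(nc):
            if not (-1000.0 < vn[i] < 1000.0) or vn[i] != vn[i]:
                return n_sp, 1, i, k
            v[i] = vn[i]
        if k >= 0:
            # somatic spike detection: upward crossing with lockout
            if (v[0] >= thresh and v_prev_soma < thresh
                    and k - last_sp_step >= refr_steps):
                if n_sp < spikes.size:
                    frac = (thresh - v_prev_soma) / (v[0] - v_prev_soma)
                    spikes[n_sp] = (k + frac) * dt
                    n_sp += 1
                last_sp_step = k
            v_prev_soma = v[0]
            if (k + 1) % rec_every == 0 and rec_i < v_rec.size:
                v_rec[rec_i] = v[0]
                if record_all:
                    for i in range(nc):
                        v_all_rec[rec_i, i] = v[i]
                rec_i += 1
        else:
            v_prev_soma = v[0]
    return n_sp, 0, -1, 0


def _initial_state(model: BASModel, v0: float):
    nc = model.n_compartments
    v = np.full(nc, v0)
    tabs = rate_tables(model.kinetics, 0.005)
    vmin, dv = tabs[0], tabs[1]
    j = int((v0 - vmin) / dv)
    m = np.full(nc, float(tabs[2][j]))
    h = np.full(nc, float(tabs[4][j]))
    n = np.full(nc, float(tabs[6][j]))
    return v, m, h, n


def simulate(model: BASModel, stimulus: np.ndarray, dt: float = 0.005,
             record_every: int = 1, settle_ms: float = 100.0,
             detect_threshold: float = 0.0, refractory_ms: float = 2.0,
             record_all: bool = False, v_init: float | None = None
             ) -> tuple[VoltageTrace, SpikeTrain]:
    """Integrate the model under an injected somatic current.

    ``stimulus`` is the current in nA sampled at ``dt`` (ms).  Before t = 0
    the model is settled for ``settle_ms`` holding the first stimulus sample.
    Somatic spike times are detected as upward crossings of
    ``detect_threshold`` (mV) with a ``refractory_ms`` lockout, linearly
    interpolated between steps, and returned in seconds.
    """
    stimulus = np.ascontiguousarray(stimulus, dtype=np.float64)
    n_steps = stimulus.size
    if n_steps == 0:
        raise ValueError("empty stimulus")
    v0 = model.densities.E_leak if v_init is None else v_init
    v, m, h, n = _initial_state(model, v0)
    tabs = rate_tables(model.kinetics, dt)
    n_rec = n_steps // record_every
    v_rec = np.empty(n_rec)
    v_all = np.empty((n_rec, model.n_compartments)) if record_all else np.empty((1, 1))
    max_spikes = int(n_steps * dt / refractory_ms) + 16
    spikes = np.empty(max_spikes)
    d = model.densities
    n_sp, status, bad_comp, bad_step = _run_cable(
        v, m, h, n, model.cm, model.g_na, model.g_k, model.g_leak,
        model.g_axial, d.E_Na, d.E_K, d.E_leak, stimulus * 1e3, dt,
        tabs[0], tabs[1], tabs[2], tabs[3], tabs[4], tabs[5], tabs[6], tabs[7],
        detect_threshold, max(1, int(round(refractory_ms / dt))), record_every,
        v_rec, v_all, record_all, spikes, int(round(settle_ms / dt)))
    if status != 0:
        raise FloatingPointError(
            f"cable integration diverged at compartment {bad_comp}, "
            f"step {bad_step} (t = {bad_step * dt:.3f} ms)"
        )
    dt_rec = dt * record_every
    t = (np.arange(n_rec) + 1) * dt_rec
    trace = VoltageTrace(t=t, v_soma=v_rec, dt=dt_rec,
                         v_all=v_all if record_all else None)
    train = SpikeTrain(times=spikes[:n_sp] * 1e-3, duration=n_steps * dt * 1e-3)
    return trace, train


def input_resistance(model: BASModel, probe_nA: float = -0.01,
                     hold_nA: float = -0.03, settle_ms: float = 300.0,
                     probe_ms: float = 400.0, dt: float = 0.01) -> float:
    """Somatic steady-state input resistance (MOhm) from a small
    hyperpolarizing current step, measured after transients decay.

    ``hold_nA`` is a holding current that keeps the cell at a quiescent
    membrane potential near the noisy-stimulation operating point (the model
    is tonically active at zero current); the probe step rides on top of it.
    Raises if the probe elicits spikes (probe too large / model unstable).
    """
    n_pre = int(round(settle_ms / dt))
    n_probe = int(round(probe_ms / dt))
    stim = np.full(n_pre + n_probe, hold_nA)
    stim[n_pre:] += probe_nA
    trace, train = simulate(model, stim, dt=dt, settle_ms=200.0)
    if train.n:
        raise RuntimeError("input-resistance probe elicited spikes; "
                           "reduce the probe amplitude")
    n_win = int(round(100.0 / trace.dt))
    v_base = trace.v_soma[n_pre - n_win:n_pre].mean()
    v_step = trace.v_soma[-n_win:].mean()
    return (v_step - v_base) / probe_nA  # mV/nA = MOhm
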