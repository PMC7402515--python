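"""Liquid State Machine: recurrent eIF network with short-term plasticity,
liquid-state extraction and a linear readout trained on the delayed-XOR task.

The liquid is a randomly wired network of 1000 excitatory and 250 inhibitory
eIF neurons with current-based exponential synapses (decay 3 ms excitatory,
2 ms inhibitory), conduction delays, per-neuron background Poisson input, and
Tsodyks-Markram short-term depression/facilitation on all recurrent
connections: at the n-th presynaptic spike the efficacy is w0 * R_n * u_n
with

    u_n = U + u_{n-1} (1 - U) exp(-dt/F)
    R_n = 1 + (R_{n-1} - R_{n-1} u_{n-1} - 1) exp(-dt/D)

and R_1 = 1, u_1 = U.  Ten input units drive the network with jittered
50 ms Poisson spike templates; liquid states are exponentially filtered
(tau 20 ms) spike trains of 200 readout neurons sampled every 50 ms, and a
regularized linear classifier maps each state to the XOR of the identities of
the last two presented templates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.stats import ranksums

from .eif import EIFParams, reference_eif_params
from .stimulus import jitter, make_templates

__all__ = [
    "STPParams",
    "SynapseState",
    "stp_update",
    "NetworkConfig",
    "Network",
    "build_network",
    "simulate_network",
    "extract_states",
    "train_readout",
    "XORTaskResult",
    "run_experiment",
]


@dataclass(frozen=True)
class STPParams:
    """Short-term plasticity constants of one connection class."""

    U: float
    D: float  # ms, depression recovery time constant
    F: float  # ms, facilitation time constant

    def __post_init__(self) -> None:
        if not (0.0 < self.U <= 1.0):
            raise ValueError("U must be in (0, 1]")
        if self.D < 1.0 or self.F < 1.0:
            raise ValueError("D and F must be >= 1 ms")


@dataclass(frozen=True)
class SynapseState:
    R: float = 1.0
    u: float | None = None  # None until the first spike
    t_last: float | None = None  # ms


def stp_update(state: SynapseState, dt_ms: float | None, p: STPParams
               ) -> tuple[SynapseState, float]:
    """Advance the depression/facilitation recursion by one presynaptic spike.

    ``dt_ms`` is the interval since the previous presynaptic spike (None for
    the first spike).  Returns the new state and the efficacy factor
    ``R_n * u_n`` (multiply by w0 for the effective weight).
    """
    if dt_ms is None or state.u is None:
        new = SynapseState(R=1.0, u=p.U, t_last=0.0)
        return new, new.R * new.u
    if dt_ms <= 0:
        raise ValueError("inter-spike interval must be positive")
    u_prev, r_prev = state.u, state.R
    u_n = p.U + u_prev * (1.0 - p.U) * np.exp(-dt_ms / p.F)
    r_n = 1.0 + (r_prev - r_prev * u_prev - 1.0) * np.exp(-dt_ms / p.D)
    new = SynapseState(R=float(r_n), u=float(u_n),
                       t_last=(state.t_last or 0.0) + dt_ms)
    return new, new.R * new.u


# Connection classes, Table-4 style defaults.
_CLASS_DEFAULTS = {
    #        J (nA)  U      D     F     delay (ms)   degree
    "in": dict(J=8.9, stp=None, delay=(1.0, 10.0), degree=70, kind="out"),
    "EE": dict(J=1.9, stp=STPParams(0.59, 813.0, 1.0), delay=(1.0, 10.0), degree=28, kind="in"),
    "EI": dict(J=6.7, stp=STPParams(0.049, 399.0, 1790.0), delay=(1.0, 10.0), degree=28, kind="in"),
    "IE": dict(J=6.1, stp=STPParams(0.016, 45.0, 376.0), delay=(0.1, 2.0), degree=48, kind="in"),
    "II": dict(J=4.9, stp=STPParams(0.25, 706.0, 21.0), delay=(0.1, 2.0), degree=48, kind="in"),
}


@dataclass(frozen=True)
class NetworkConfig:
    """Liquid topology, weights, delays and background-noise parameters."""

    n_exc: int = 1000
    n_inh: int = 250
    n_inputs: int = 10
    n_readout: int = 200
    classes: dict = field(default_factory=lambda: dict(_CLASS_DEFAULTS))
    tau_syn_exc: float = 3.0  # ms
    tau_syn_inh: float = 2.0  # ms
    noise_rate: float = 20.0  # event/s per neuron
    J_noise: float = 2.0  # nA
    dt: float = 0.1  # ms
    equal_delays: bool = False  # variant: all delays ~ U(0.1, 2) ms
    seed: int = 0

    @property
    def n_neurons(self) -> int:
        return self.n_exc + self.n_inh

    def delay_range(self, cls: str) -> tuple[float, float]:
        if self.equal_delays:
            return (0.1, 2.0)
        return self.classes[cls]["delay"]


@dataclass
class Network:
    """Wired liquid: presynapse-sorted synapse arrays ready for simulation."""

    cfg: NetworkConfig
    # recurrent synapses in CSR-by-presynapse layout
    indptr: np.ndarray
    targets: np.ndarray
    w0: np.ndarray  # nA, signed (negative for inhibitory presynapse)
    delay_steps: np.ndarray
    # STP constants per (presyn neuron, target-population) pair
    stp_U: np.ndarray  # (n, 2): column 0 = excitatory targets, 1 = inhibitory
    stp_D: np.ndarray
    stp_F: np.ndarray
    # input projections, CSR by input unit
    in_indptr: np.ndarray
    in_targets: np.ndarray
    in_w: np.ndarray  # nA
    in_delay_steps: np.ndarray
    readout: np.ndarray  # indices of the readout (liquid-state) neurons

    def in_degree(self, post: int) -> int:
        return int(np.sum(self.targets == post))


def build_network(cfg: NetworkConfig, seed=None) -> Network:
    """Draw the random wiring, weights and delays.

    EE/EI/IE/II connections use a fixed in-degree per postsynaptic neuron
    (presynapses sampled without replacement, self-connections excluded);
    input units use a fixed out-degree onto excitatory targets.  Recurrent
    weights ~ Normal(J, 0.7 J) truncated at zero; input weights
    ~ Uniform(0.5 J, 1.5 J); delays uniform in the class range, rounded to
    the integration grid.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    nE, nI = cfg.n_exc, cfg.n_inh
    n = nE + nI
    pre_lists: list[list] = [[] for _ in range(n)]  # (target, w, delay_steps)

    def add_class(cls, pre_pop, post_pop, sign):
        spec = cfg.classes[cls]
        deg = spec["degree"]
        if deg > len(pre_pop) - 1:
            raise ValueError(f"in-degree {deg} impossible for class {cls}")
        lo, hi = cfg.delay_range(cls)
        for post in post_pop:
            choices = rng.choice(pre_pop, size=deg + 1, replace=False)
            choices = choices[choices != post][:deg]
            w = rng.normal(spec["J"], 0.7 * spec["J"], size=deg)
            w = np.clip(w, 0.0, None) * sign
            dly = np.round(rng.uniform(lo, hi, size=deg) / cfg.dt).astype(np.int64)
            dly = np.maximum(dly, 1)
            for t, wi, di in zip(choices, w, dly):
                pre_lists[t].append((post, wi, di))

    exc = np.arange(nE)
    inh = np.arange(nE, n)
    add_class("EE", exc, exc, +1.0)
    add_class("EI", exc, inh, +1.0)
    add_class("IE", inh, exc, -1.0)
    add_class("II", inh, inh, -1.0)

    counts = np.array([len(p) for p in pre_lists])
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    m = indptr[-1]
    targets = np.empty(m, dtype=np.int64)
    w0 = np.empty(m)
    delay_steps = np.empty(m, dtype=np.int64)
    for j in range(n):
        for k, (t, wi, di) in enumerate(pre_lists[j]):
            targets[indptr[j] + k] = t
            w0[indptr[j] + k] = wi
            delay_steps[indptr[j] + k] = di

    # STP constants per presyn neuron x target population
    stp_U = np.empty((n, 2))
    stp_D = np.empty((n, 2))
    stp_F = np.empty((n, 2))
    for j in range(n):
        for c, cls in enumerate(("EE", "EI") if j < nE else ("IE", "II")):
            p = cfg.classes[cls]["stp"]
            stp_U[j, c], stp_D[j, c], stp_F[j, c] = p.U, p.D, p.F

    # input: fixed out-degree onto excitatory neurons
    spec = cfg.classes["in"]
    lo, hi = cfg.delay_range("in")
    in_indptr = np.arange(cfg.n_inputs + 1, dtype=np.int64) * spec["degree"]
    in_targets = np.empty(in_indptr[-1], dtype=np.int64)
    in_w = np.empty(in_indptr[-1])
    in_delay = np.empty(in_indptr[-1], dtype=np.int64)
    for u in range(cfg.n_inputs):
        sl = slice(in_indptr[u], in_indptr[u + 1])
        in_targets[sl] = rng.choice(nE, size=spec["degree"], replace=False)
        in_w[sl] = rng.uniform(0.5 * spec["J"], 1.5 * spec["J"], size=spec["degree"])
        in_delay[sl] = np.maximum(np.round(rng.uniform(lo, hi, spec["degree"]) / cfg.dt), 1)

    readout = rng.choice(nE, size=cfg.n_readout, replace=False)
    return Network(cfg=cfg, indptr=indptr, targets=targets, w0=w0,
                   delay_steps=delay_steps, stp_U=stp_U, stp_D=stp_D,
                   stp_F=stp_F, in_indptr=in_indptr, in_targets=in_targets,
                   in_w=in_w, in_delay_steps=in_delay, readout=readout)


@njit(cache=True, fastmath=True)
def _run_lsm(n, n_exc, tau_m, E_L, V_T, Delta_T, v_reset, v_cut, tref_steps,
             c_m, dt, indptr, targets, w0_pa, delay_steps, stp_U, stp_D,
             stp_F, in_indptr, in_targets, in_w_pa, in_delay_steps,
             ev_step, ev_unit, noise_step, noise_neuron, noise_w_pa,
             dec_e, dec_i, ro_slot, dec_k, epoch_steps, states,
             n_steps, v_init, stp_enabled):
    H = 128  # delay buffer horizon (steps); max delay is 100 steps at 0.1 ms
    buf_e = np.zeros((H, n))
    buf_i = np.zeros((H, n))
    ge = np.zeros(n)
    gi = np.zeros(n)
    x = np.zeros(states.shape[1])
    v = v_init.copy()
    refr = np.zeros(n, dtype=np.int64)
    R = np.ones((n, 2))
    u = np.zeros((n, 2))
    seen = np.zeros((n, 2), dtype=np.int64)
    t_last = np.zeros(n)
    # tabulated spike-generating exponential: Delta_T * exp((v - V_T)/Delta_T)
    etab_v0 = V_T - 40.0 * Delta_T
    etab_dv = 0.05 * Delta_T
    netab = 1401  # covers (v - V_T)/Delta_T in [-40, 30]
    etab = np.empty(netab)
    for j in range(netab):
        etab[j] = Delta_T * np.exp((etab_v0 + j * etab_dv - V_T) / Delta_T)
    ev_i = 0
    nz_i = 0
    epoch = 0
    n_spikes_total = 0
    inv_tau = 1.0 / tau_m
    inv_c = 1.0 / c_m
    for k in range(n_steps):
        t_now = k * dt
        slot = k % H
        # external input events (with per-synapse delay)
        while ev_i < ev_step.size and ev_step[ev_i] == k:
            uu = ev_unit[ev_i]
            for s in range(in_indptr[uu], in_indptr[uu + 1]):
                dslot = (k + in_delay_steps[s]) % H
                buf_e[dslot, in_targets[s]] += in_w_pa[s]
            ev_i += 1
        # background noise (no delay, excitatory kinetics)
        while nz_i < noise_step.size and noise_step[nz_i] == k:
            ge[noise_neuron[nz_i]] += noise_w_pa
            nz_i += 1
        # deliver delayed events, advance membranes, decay synapses
        for i in range(n):
            gei = ge[i] + buf_e[slot, i]
            gii = gi[i] + buf_i[slot, i]
            buf_e[slot, i] = 0.0
            buf_i[slot, i] = 0.0
            if refr[i] > 0:
                refr[i] -= 1
            else:
                vi = v[i]
                xf = (vi - etab_v0) / etab_dv
                if xf < 0.0:
                    xf = 0.0
                elif xf > netab - 1.001:
                    xf = netab - 1.001
                j = int(xf)
                sgen = etab[j] + (xf - j) * (etab[j + 1] - etab[j])
                vi += dt * ((E_L - vi + sgen) * inv_tau + (gei + gii) * inv_c)
                if vi >= v_cut:
                    # spike: STP update once per target population, deliver
                    n_spikes_total += 1
                    dtd = t_now - t_last[i]
                    for c in range(2):
                        if seen[i, c] == 0 or not stp_enabled:
                            R[i, c] = 1.0
                            u[i, c] = stp_U[i, c]
                            seen[i, c] = 1
                        else:
                            u_prev = u[i, c]
                            R[i, c] = 1.0 + (R[i, c] - R[i, c] * u_prev - 1.0) \
                                * np.exp(-dtd / stp_D[i, c])
                            u[i, c] = stp_U[i, c] + u_prev * (1.0 - stp_U[i, c]) \
                                * np.exp(-dtd / stp_F[i, c])
                    t_last[i] = t_now
                    for s in range(indptr[i], indptr[i + 1]):
                        tgt = targets[s]
                        c = 0 if tgt < n_exc else 1
                        w = w0_pa[s]
                        if stp_enabled:
                            w *= R[i, c] * u[i, c]
                        dslot = (k + delay_steps[s]) % H
                        if w >= 0.0:
                            buf_e[dslot, tgt] += w
                        else:
                            buf_i[dslot, tgt] += w
                    if ro_slot[i] >= 0:
                        x[ro_slot[i]] += 1.0
                    vi = v_reset
                    refr[i] = tref_steps
                v[i] = vi
            ge[i] = gei * dec_e
            gi[i] = gii * dec_i
        for j in range(x.size):
            x[j] *= dec_k
        if (k + 1) % epoch_steps == 0 and epoch < states.shape[0]:
            for j in range(x.size):
                states[epoch, j] = x[j]
            epoch += 1
    return n_spikes_total


def _input_events(cfg: NetworkConfig, templates, pattern_ids, jitter_sd, rng):
    """Contiguous 50 ms presentations of jittered templates ->
    (step, unit) event arrays sorted by step, plus the epoch length in steps."""
    epoch_steps = int(round(templates[0].duration / cfg.dt))
    steps, units = [], []
    for e, pid in enumerate(pattern_ids):
        jt = jitter(templates[pid], sd=jitter_sd,
                    seed=rng.integers(2**31)) if jitter_sd > 0 else templates[pid]
        for ch, times in enumerate(jt.times):
            for t in times:
                steps.append(e * epoch_steps + int(round(t / cfg.dt)))
                units.append(ch)
    steps = np.asarray(steps, dtype=np.int64)
    units = np.asarray(units, dtype=np.int64)
    order = np.argsort(steps, kind="stable")
    return steps[order], units[order], epoch_steps


def simulate_network(net: Network, eif: EIFParams, input_events,
                     n_steps: int, epoch_steps: int, seed=0,
                     stp_enabled: bool = True,
                     rate_bound: float = 200.0) -> tuple[np.ndarray, float]:
    """Run the liquid for ``n_steps`` and return (liquid states, mean rate).

    ``input_events`` is a (step, unit) pair of arrays.  Liquid states (the
    exponentially filtered readout spike trains, tau 20 ms) are sampled at
    the end of every epoch.  A mean population rate above ``rate_bound``
    (spike/s) flags runaway activity with a warning.
    """
    cfg = net.cfg
    rng = np.random.default_rng(seed)
    n = cfg.n_neurons
    # pregenerated background Poisson events
    t_total_s = n_steps * cfg.dt * 1e-3
    n_ev = rng.poisson(cfg.noise_rate * n * t_total_s)
    nz_step = np.sort(rng.integers(0, n_steps, size=n_ev))
    nz_neuron = rng.integers(0, n, size=n_ev)
    ro_slot = np.full(n, -1, dtype=np.int64)
    ro_slot[net.readout] = np.arange(net.readout.size)
    n_epochs = n_steps // epoch_steps
    states = np.zeros((n_epochs, net.readout.size))
    v_init = rng.uniform(eif.V_reset, eif.V_T, size=n)
    ev_step, ev_unit = input_events
    total = _run_lsm(
        n, cfg.n_exc, eif.tau_m, eif.E_L, eif.V_T, eif.Delta_T, eif.V_reset,
        eif.V_cut, max(1, int(round(eif.t_ref / cfg.dt))), eif.C_m, cfg.dt,
        net.indptr, net.targets, net.w0 * 1e3, net.delay_steps,
        net.stp_U, net.stp_D, net.stp_F,
        net.in_indptr, net.in_targets, net.in_w * 1e3, net.in_delay_steps,
        np.ascontiguousarray(ev_step), np.ascontiguousarray(ev_unit),
        nz_step, nz_neuron, cfg.J_noise * 1e3,
        np.exp(-cfg.dt / cfg.tau_syn_exc), np.exp(-cfg.dt / cfg.tau_syn_inh),
        ro_slot, np.exp(-cfg.dt / 20.0), epoch_steps, states, n_steps,
        v_init, stp_enabled)
    mean_rate = total / n / t_total_s
    if mean_rate > rate_bound:
        warnings.warn(f"runaway liquid activity: mean rate {mean_rate:.1f} "
                      f"spike/s exceeds {rate_bound}", RuntimeWarning)
    return states, mean_rate


def extract_states(spike_times_ms: list[np.ndarray], t_sample_ms: np.ndarray,
                   tau: float = 20.0) -> np.ndarray:
    """Reference liquid-state extraction from explicit spike times:
    state[e, i] = sum over spikes t <= T_e of exp(-(T_e - t)/tau)."""
    out = np.zeros((t_sample_ms.size, len(spike_times_ms)))
    for i, st in enumerate(spike_times_ms):
        st = np.asarray(st, dtype=float)
        for e, T in enumerate(t_sample_ms):
            d = T - st[st <= T]
            out[e, i] = np.exp(-d / tau).sum()
    return out


def train_readout(states: np.ndarray, labels: np.ndarray, n_splits: int = 100,
                  train_frac: float = 0.8, ridge: float = 1.0,
                  seed=0) -> float:
    """Mean test accuracy of regularized linear least-squares readouts over
    random train/test splits (0.5 decision threshold on 0/1 targets)."""
    y = np.asarray(labels, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("need both classes present to train a readout")
    X = np.column_stack([states, np.ones(states.shape[0])])
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    n_train = int(round(train_frac * n))
    accs = np.empty(n_splits)
    eye = np.eye(X.shape[1])
    eye[-1, -1] = 0.0  # do not penalize the intercept
    # the train-set normal equations are the full-data ones minus the test block
    A_full = X.T @ X
    b_full = X.T @ y
    for s in range(n_splits):
        perm = rng.permutation(n)
        te = perm[n_train:]
        Xte = X[te]
        A = A_full - Xte.T @ Xte + ridge * eye
        w = np.linalg.solve(A, b_full - Xte.T @ y[te])
        pred = (Xte @ w) >= 0.5
        accs[s] = np.mean(pred == (y[te] >= 0.5))
    return float(accs.mean())


@dataclass(frozen=True)
class XORTaskResult:
    """Per-AIS-distance XOR accuracies and pairwise rank-sum p-values."""

    distances: tuple[float, ...]
    accuracies: dict  # distance -> np.ndarray of per-network accuracies
    mean_rates: dict  # distance -> np.ndarray of per-network mean rates
    p_values: np.ndarray  # (n_dist, n_dist), two-sided rank-sum

    def mean(self, d) -> float:
        return float(np.mean(self.accuracies[d]))

    def sd(self, d) -> float:
        return float(np.std(self.accuracies[d], ddof=1))


def run_experiment(distances=(0.0, 25.0, 50.0), n_networks: int = 50,
                   train_seconds: float = 500.0, cfg: NetworkConfig | None = None,
                   jitter_sd: float = 5.0, n_splits: int = 100,
                   delta_t_override: float | None = None,
                   eif_table=None, seed=0) -> XORTaskResult:
    """Evaluate the delayed-XOR performance for each AIS distance.

    Each of ``n_networks`` random liquids (the same wiring seeds are reused
    across distances) is driven with a fresh random sequence of jittered
    templates; the XOR of the identities of the last two templates is the
    label at each epoch end.  ``delta_t_override`` replaces Delta_T while
    keeping the other parameters of the given distance (the AP-sharpness-only
    variant); ``eif_table`` may supply an alternative distance -> EIFParams
    mapping.
    """
    cfg = cfg or NetworkConfig()
    root = np.random.default_rng(seed)
    net_seeds = root.integers(2**31, size=n_networks)
    run_seeds = root.integers(2**31, size=(len(distances), n_networks, 3))
    accs = {d: np.empty(n_networks) for d in distances}
    rates = {d: np.empty(n_networks) for d in distances}
    templates = make_templates(root.integers(2**31), n_channels=cfg.n_inputs)
    epoch_ms = templates[0].duration
    n_epochs = int(round(train_seconds * 1000.0 / epoch_ms))
    for di, d in enumerate(distances):
        if eif_table is not None:
            eif = eif_table[d]
        else:
            eif = reference_eif_params(d)
        if delta_t_override is not None:
            eif = EIFParams(tau_m=eif.tau_m, E_L=eif.E_L, V_T=eif.V_T,
                            Delta_T=delta_t_override, g_L=eif.g_L,
                            V_reset=eif.V_reset, t_ref=eif.t_ref,
                            V_cut=eif.V_cut)
        for ni in range(n_networks):
            net = build_network(cfg, seed=net_seeds[ni])
            rng_in = np.random.default_rng(run_seeds[di, ni, 0])
            pattern_ids = rng_in.integers(0, 2, size=n_epochs)
            ev_step, ev_unit, epoch_steps = _input_events(
                cfg, templates, pattern_ids, jitter_sd, rng_in)
            states, rate = simulate_network(
                net, eif, (ev_step, ev_unit), n_epochs * epoch_steps,
                epoch_steps, seed=run_seeds[di, ni, 1])
            labels = pattern_ids[1:] ^ pattern_ids[:-1]
            accs[d][ni] = train_readout(states[1:], labels,
                                        n_splits=n_splits,
                                        seed=run_seeds[di, ni, 2])
            rates[d][ni] = rate
    nd = len(distances)
    pvals = np.ones((nd, nd))
    for i in range(nd):
        for j in range(nd):
            if i != j:
                pvals[i, j] = ranksums(accs[distances[i]],
                                       accs[distances[j]]).pvalue
    return XORTaskResult(distances=tuple(distances), accuracies=accs,
                         mean_rates=rates, p_values=pvals)
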