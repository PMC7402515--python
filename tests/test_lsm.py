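import numpy as np
import pytest

from aisdyn.eif import reference_eif_params
from aisdyn.lsm import (NetworkConfig, STPParams, SynapseState, build_network,
                        extract_states, run_experiment, simulate_network,
                        stp_update, train_readout)


class TestSTP:
    P = STPParams(U=0.59, D=813.0, F=1.0)

    def test_first_spike(self):
        state, w = stp_update(SynapseState(), None, self.P)
        assert state.R == 1.0 and state.u == self.P.U
        assert w == pytest.approx(self.P.U)

    def test_full_recovery_at_long_intervals(self):
        state, _ = stp_update(SynapseState(), None, self.P)
        for _ in range(5):
            state, w = stp_update(state, 1e7, self.P)
        assert state.R == pytest.approx(1.0)
        assert state.u == pytest.approx(self.P.U)

    def test_rejects_nonpositive_interval(self):
        state, _ = stp_update(SynapseState(), None, self.P)
        with pytest.raises(ValueError):
            stp_update(state, 0.0, self.P)

    @pytest.mark.parametrize("p,isi", [
        (STPParams(U=0.59, D=813.0, F=1.0), 50.0),     # depressing (EE-like)
        (STPParams(U=0.049, D=399.0, F=1790.0), 50.0),  # facilitating (EI-like)
    ])
    def test_periodic_train_reaches_map_fixed_point(self, p, isi):
        """Iterating the recursion on a periodic train must converge to the
        analytic fixed point of the two-variable map."""
        eF, eD = np.exp(-isi / p.F), np.exp(-isi / p.D)
        u_star = p.U / (1.0 - (1.0 - p.U) * eF)
        r_star = (1.0 - eD) / (1.0 - (1.0 - u_star) * eD)
        state, _ = stp_update(SynapseState(), None, p)
        for _ in range(1000):
            state, w = stp_update(state, isi, p)
        assert state.u == pytest.approx(u_star, rel=1e-9)
        assert state.R == pytest.approx(r_star, rel=1e-9)

    def test_invariants(self):
        with pytest.raises(ValueError):
            STPParams(U=0.0, D=10.0, F=10.0)
        with pytest.raises(ValueError):
            STPParams(U=0.5, D=0.5, F=10.0)


@pytest.fixture(scope="module")
def net():
    return build_network(NetworkConfig(), seed=17)


class TestBuildNetwork:
    def test_fixed_in_degrees(self, net):
        cfg = net.cfg
        pre_is_exc = np.zeros(cfg.n_neurons, dtype=bool)
        pre_is_exc[:cfg.n_exc] = True
        pre_of_syn = np.repeat(np.arange(cfg.n_neurons),
                               np.diff(net.indptr))
        for post_pop, want_e, want_i in (
                (range(cfg.n_exc), 28, 48),
                (range(cfg.n_exc, cfg.n_neurons), 28, 48)):
            tgt = net.targets
            for post in list(post_pop)[::137]:  # spot-check a spread
                sel = tgt == post
                n_e = np.sum(pre_is_exc[pre_of_syn[sel]])
                n_i = np.sum(~pre_is_exc[pre_of_syn[sel]])
                assert n_e == want_e and n_i == want_i

    def test_input_out_degree(self, net):
        for u in range(net.cfg.n_inputs):
            sl = slice(net.in_indptr[u], net.in_indptr[u + 1])
            assert sl.stop - sl.start == 70
            assert np.unique(net.in_targets[sl]).size == 70
            assert np.all(net.in_targets[sl] < net.cfg.n_exc)

    def test_weight_signs_and_delays(self, net):
        cfg = net.cfg
        pre_of_syn = np.repeat(np.arange(cfg.n_neurons), np.diff(net.indptr))
        exc_syn = pre_of_syn < cfg.n_exc
        assert np.all(net.w0[exc_syn] >= 0)
        assert np.all(net.w0[~exc_syn] <= 0)
        # delays: U(1,10) ms for excitatory sources, U(0.1,2) ms inhibitory
        dt = cfg.dt
        assert net.delay_steps[exc_syn].max() <= round(10.0 / dt)
        assert net.delay_steps[~exc_syn].max() <= round(2.0 / dt)

    def test_deterministic_given_seed(self):
        a = build_network(NetworkConfig(), seed=3)
        b = build_network(NetworkConfig(), seed=3)
        np.testing.assert_array_equal(a.targets, b.targets)
        np.testing.assert_array_equal(a.w0, b.w0)
        np.testing.assert_array_equal(a.delay_steps, b.delay_steps)
        np.testing.assert_array_equal(a.readout, b.readout)


class TestSimulateNetwork:
    def test_silent_without_input_and_noise(self):
        cfg = NetworkConfig(noise_rate=0.0, seed=1)
        net = build_network(cfg, seed=1)
        eif = reference_eif_params(25.0)
        states, rate = simulate_network(
            net, eif, (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)),
            n_steps=5000, epoch_steps=500, seed=2)
        assert rate == 0.0
        assert np.all(states == 0.0)

    def test_stp_gates_repeated_drive(self):
        """Strongly depressing recurrent synapses attenuate the network's
        response to a repeated input volley; with STP disabled the repeat
        response matches the first."""
        cfg = NetworkConfig(noise_rate=0.0, seed=5)
        net = build_network(cfg, seed=5)
        eif = reference_eif_params(25.0)
        # two identical strong volleys, 250 ms apart (well within D_EE=813)
        ev_step = np.array(sorted([0] * 10 + [2500] * 10), dtype=np.int64)
        ev_unit = np.array(list(range(10)) + list(range(10)), dtype=np.int64)
        out = {}
        for stp_on in (True, False):
            states, _ = simulate_network(net, eif, (ev_step, ev_unit),
                                         n_steps=5000, epoch_steps=250,
                                         seed=7, stp_enabled=stp_on)
            act = states.sum(axis=1)
            first, second = act[:10].max(), act[10:].max()
            out[stp_on] = (first, second)
        f_on, s_on = out[True]
        f_off, s_off = out[False]
        assert f_on > 0 and f_off > 0
        # static synapses: repeat reproduces the first volley's response
        assert s_off == pytest.approx(f_off, rel=0.05)
        # depression: the repeated volley drives visibly less activity
        assert s_on < 0.9 * f_on


class TestExtractStates:
    def test_kernel_values(self):
        spikes = [np.array([50.0]), np.array([30.0]), np.array([])]
        states = extract_states(spikes, t_sample_ms=np.array([50.0]), tau=20.0)
        assert states[0, 0] == pytest.approx(1.0)  # at the epoch end
        assert states[0, 1] == pytest.approx(np.exp(-1.0))  # 20 ms before
        assert states[0, 2] == 0.0  # silent neuron


class TestReadout:
    def test_separable_states_reach_perfect_accuracy(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, size=400)
        X = rng.normal(0, 0.1, (400, 20))
        X[:, 0] += y  # linearly separable along one axis
        assert train_readout(X, y, n_splits=20, seed=1) == 1.0

    def test_shuffled_labels_at_chance(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, size=600)
        X = rng.normal(0, 1.0, (600, 20))
        acc = train_readout(X, y, n_splits=50, seed=2)
        assert abs(acc - 0.5) < 0.06

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_readout(np.ones((10, 3)), np.zeros(10))

    def test_deterministic(self):
        rng = np.random.default_rng(10)
        y = rng.integers(0, 2, size=100)
        X = rng.normal(0, 1, (100, 5))
        assert train_readout(X, y, seed=4) == train_readout(X, y, seed=4)


class TestExperiment:
    def test_smoke_run_shapes_and_ranges(self):
        res = run_experiment(distances=(0.0, 25.0), n_networks=2,
                             train_seconds=20.0, n_splits=20, seed=11)
        assert set(res.accuracies) == {0.0, 25.0}
        for d in res.distances:
            a = res.accuracies[d]
            assert a.shape == (2,)
            assert np.all((0.0 <= a) & (a <= 1.0))
        assert res.p_values.shape == (2, 2)
        assert np.allclose(res.p_values, res.p_values.T)
        assert res.p_values[0, 0] == 1.0
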