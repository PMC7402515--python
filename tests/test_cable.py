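import numpy as np
import pytest

from aisdyn.cable import (CableGeometry, ChannelDensities, build_bas,
                          input_resistance, simulate)
from conftest import ladder_steady_state


class TestBuild:
    def test_default_has_twelve_compartments(self):
        model = build_bas(d=25.0)
        assert model.n_compartments == 12  # soma + 11 axonal

    def test_ais_at_origin_lands_next_to_soma(self):
        assert build_bas(d=0.0).ais_index == 0

    def test_nearest_center_rule(self):
        # 11 compartments of 4.545 um: centers 2.27, 6.82, ... -> d=25 is #5
        model = build_bas(d=25.0)
        centers = model.geometry.compartment_centers()
        assert model.ais_index == int(np.argmin(np.abs(centers - 25.0))) == 5

    def test_exactly_one_ais_compartment(self):
        for d in (0.0, 12.0, 37.5, 50.0):
            model = build_bas(d=d)
            dens = model.densities
            area = model.geometry.compartment_area
            n_ais = np.sum(np.isclose(model.g_na[1:], dens.gNa_ais * area))
            assert n_ais == 1

    def test_relocation_preserves_total_area_and_conductance(self):
        a = build_bas(d=0.0)
        b = build_bas(d=50.0)
        assert a.total_membrane_area() == b.total_membrane_area()
        assert a.g_na.sum() == pytest.approx(b.g_na.sum())
        np.testing.assert_array_equal(a.g_leak, b.g_leak)

    def test_rejects_ais_outside_axon(self):
        with pytest.raises(ValueError, match="outside the axon"):
            build_bas(d=60.0)
        with pytest.raises(ValueError, match="outside the axon"):
            build_bas(d=-1.0)

    def test_rejects_nonpositive_geometry(self):
        with pytest.raises(ValueError):
            CableGeometry(axon_diameter=0.0)
        with pytest.raises(ValueError):
            CableGeometry(n_axon_compartments=1)

    def test_density_invariants(self):
        with pytest.raises(ValueError):
            ChannelDensities(gNa_ais=0.5, gNa_axon=0.8)


class TestPassiveLimit:
    def test_relaxes_to_leak_reversal(self, default_model):
        passive = default_model.passive_copy()
        stim = np.zeros(int(300 / 0.01))
        trace, spikes = simulate(passive, stim, dt=0.01, v_init=-75.0,
                                 settle_ms=0.0)
        assert spikes.n == 0
        assert trace.v_soma[-1] == pytest.approx(-60.0, abs=0.01)

    def test_dc_steady_state_matches_ladder_solution(self, passive_leaky_model):
        """Backward-Euler steady state vs the exact linear ladder solve."""
        i0 = 0.01  # nA
        stim = np.full(int(400 / 0.01), i0)
        trace, _ = simulate(passive_leaky_model, stim, dt=0.01,
                            settle_ms=300.0, record_all=True)
        exact = ladder_steady_state(passive_leaky_model, i0)
        np.testing.assert_allclose(trace.v_all[-1], exact, rtol=1e-3)

    def test_uniform_decay_time_constant(self, default_model):
        """From a spatially uniform start, no axial current flows: the decay
        is a single exponential with tau = C_total / g_leak_total."""
        passive = default_model.passive_copy()
        stim = np.zeros(int(40 / 0.005))
        trace, _ = simulate(passive, stim, dt=0.005, v_init=-70.0, settle_ms=0.0)
        tau_exact = passive.cm.sum() / passive.g_leak.sum()
        dv = trace.v_soma - (-60.0)
        # log-linear fit over the first 2 tau
        n = int(2 * tau_exact / trace.dt)
        fit = np.polyfit(trace.t[:n], np.log(-dv[:n]), 1)
        assert -1.0 / fit[0] == pytest.approx(tau_exact, rel=1e-3)


class TestSimulate:
    def test_spike_times_deterministic(self, default_model):
        from aisdyn.stimulus import StimulusConfig, compose_stimulus
        stim = compose_stimulus(StimulusConfig(I0=-0.03, s=0.02, dt=0.01,
                                               duration=4.0, seed=0))
        _, a = simulate(default_model, stim, dt=0.01, detect_threshold=-20.0)
        _, b = simulate(default_model, stim, dt=0.01, detect_threshold=-20.0)
        assert a.n == b.n > 0
        np.testing.assert_array_equal(a.times, b.times)

    def test_spike_times_converge_with_dt(self, default_model):
        """Halving the step from the production value must leave the spike
        times of a strongly driven deterministic run nearly unchanged."""
        def pulses(dt):
            n = int(200 / dt)
            stim = np.full(n, -0.03)
            for k in range(3):
                a = int((40 + 60 * k) / dt)
                stim[a:a + int(3 / dt)] = 0.15
            return stim

        _, sp1 = simulate(default_model, pulses(0.005), dt=0.005,
                          detect_threshold=-20.0)
        _, sp2 = simulate(default_model, pulses(0.0025), dt=0.0025,
                          detect_threshold=-20.0)
        assert sp1.n == sp2.n == 3
        np.testing.assert_allclose(sp1.times, sp2.times, atol=1e-5)  # 0.01 ms

    def test_divergence_reports_compartment(self, default_model):
        stim = np.full(10_000, 1e7)
        with pytest.raises(FloatingPointError, match="compartment"):
            simulate(default_model, stim, dt=0.01)

    def test_empty_stimulus_rejected(self, default_model):
        with pytest.raises(ValueError):
            simulate(default_model, np.array([]))


class TestInputResistance:
    def test_passive_matches_ladder_oracle(self, passive_leaky_model):
        rin = input_resistance(passive_leaky_model, probe_nA=-0.01, hold_nA=0.0)
        v_probe = ladder_steady_state(passive_leaky_model, -0.01)[0]
        v_rest = ladder_steady_state(passive_leaky_model, 0.0)[0]
        exact = (v_probe - v_rest) / (-0.01)
        assert rin == pytest.approx(exact, rel=1e-3)

    def test_invariant_to_ais_relocation(self):
        r0 = input_resistance(build_bas(d=0.0))
        r50 = input_resistance(build_bas(d=50.0))
        assert abs(r50 - r0) / r0 <= 5e-4  # <= 0.05 %

    def test_larger_soma_lowers_input_resistance(self):
        small = build_bas(geometry=CableGeometry(soma_diameter=20.0), d=25.0)
        big = build_bas(geometry=CableGeometry(soma_diameter=28.3), d=25.0)
        assert input_resistance(big) < input_resistance(small)
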