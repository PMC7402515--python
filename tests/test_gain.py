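import numpy as np
import pytest

from aisdyn.gain import (GainCurve, cutoff_frequency, fit_logistic, gain_curve,
                         logistic, phase_delay, powerlaw_exponent,
                         vector_strength)


def modulated_poisson(r0, m, f, duration, seed, delay=0.0):
    """Inhomogeneous Poisson spikes with rate r0 (1 + m sin(2 pi f (t - delay)))
    by thinning a homogeneous process."""
    rng = np.random.default_rng(seed)
    n = rng.poisson(r0 * (1 + abs(m)) * duration)
    t = np.sort(rng.uniform(0, duration, n))
    keep = rng.uniform(0, 1 + abs(m), n) <= 1 + m * np.sin(2 * np.pi * f * (t - delay))
    return t[keep]


def make_curve(f, gain, phase=None):
    f = np.asarray(f, dtype=float)
    g = np.asarray(gain, dtype=float)
    return GainCurve(f=f, raw=g.copy(), gain=g, gain_sd=np.zeros_like(g),
                     phase=np.zeros_like(g) if phase is None else np.asarray(phase),
                     n_spikes=np.full(f.size, 1000), r0=5.0,
                     n_reps=np.ones(f.size, dtype=int))


class TestVectorStrength:
    def test_identical_phases_give_unit_resultant(self):
        pv = vector_strength(np.array([0.0, 1.0, 2.0]), f=1.0)
        assert pv.magnitude == pytest.approx(1.0)
        assert pv.angle == pytest.approx(0.0, abs=1e-12)

    def test_two_spikes_quarter_cycle_apart(self):
        # phases 0 and pi/2 at f = 1: r = (1 + j)/2
        pv = vector_strength(np.array([1.0, 0.25]), f=1.0)
        assert pv.r == pytest.approx((1 + 1j) / 2)
        assert pv.magnitude == pytest.approx(np.sqrt(2) / 2)

    def test_uniform_phases_near_zero(self):
        rng = np.random.default_rng(0)
        pv = vector_strength(rng.uniform(0, 1000, 10**5), f=1.0)
        assert pv.magnitude < 0.01

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            vector_strength(np.array([]), f=10.0)

    def test_rayleigh_noise_floor(self):
        """For unmodulated spikes E|r| ~ sqrt(pi / 4N)."""
        rng = np.random.default_rng(1)
        N = 400
        mags = [vector_strength(rng.uniform(0, 100, N), 7.0).magnitude
                for _ in range(300)]
        assert np.mean(mags) == pytest.approx(np.sqrt(np.pi / (4 * N)), rel=0.1)


class TestGainCurve:
    def test_modulation_recovered_from_poisson_spikes(self):
        t = modulated_poisson(r0=50.0, m=0.3, f=5.0, duration=2000.0, seed=2)
        curve = gain_curve({1.0: [modulated_poisson(50, 0.3, 1.0, 500, 3)],
                            5.0: [t]}, r0=50.0, debias=False)
        assert curve.raw[curve.f == 5.0][0] == pytest.approx(0.3, rel=0.05)

    def test_unmodulated_gain_sits_at_noise_floor(self):
        rng = np.random.default_rng(4)
        spikes = {f: [np.sort(rng.uniform(0, 400, 2000))] for f in (1.0, 10.0, 100.0)}
        curve = gain_curve(spikes, r0=5.0, debias=False)
        floor = 2 * np.sqrt(np.pi / (4 * 2000))
        assert np.all(curve.raw < 4 * floor)

    def test_missing_reference_frequency_errors(self):
        with pytest.raises(ValueError, match="reference"):
            gain_curve({10.0: [np.arange(10.0)]}, r0=5.0)

    def test_normalized_at_reference(self):
        t = modulated_poisson(20, 0.4, 1.0, 200, 5)
        curve = gain_curve({1.0: [t], 3.0: [t]}, r0=20.0)
        assert curve.gain[curve.f == 1.0][0] == 1.0


class TestCutoff:
    def test_one_pole_low_pass_closed_form(self):
        # |H| = 1/sqrt(1 + (f/fc)^2) crosses 0.70 at fc*sqrt(1/0.49 - 1)
        fc = 85.0
        f = np.logspace(0, 3, 40)
        curve = make_curve(f, 1.0 / np.sqrt(1 + (f / fc) ** 2))
        expected = fc * np.sqrt(1 / 0.49 - 1.0)
        assert cutoff_frequency(curve) == pytest.approx(expected, rel=0.02)

    def test_flat_curve_has_no_cutoff(self):
        with pytest.raises(ValueError, match="COF"):
            cutoff_frequency(make_curve([1, 10, 100], [1.0, 0.99, 0.98]))

    def test_first_crossing_wins(self):
        curve = make_curve([1, 10, 100, 1000], [1.0, 0.5, 0.9, 0.3])
        assert 1 < cutoff_frequency(curve) < 10


class TestPowerlaw:
    def test_exact_power_law(self):
        f = np.logspace(0, 3, 30)
        curve = make_curve(f, f ** -1.5)
        assert powerlaw_exponent(curve) == pytest.approx(1.5, abs=1e-9)

    def test_invariant_to_rescaling(self):
        f = np.logspace(0, 3, 30)
        a = powerlaw_exponent(make_curve(f, f ** -1.2))
        b = powerlaw_exponent(make_curve(f, 7.3 * f ** -1.2))
        assert a == pytest.approx(b, abs=1e-9)

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            powerlaw_exponent(make_curve([1.0, 500.0, 1000.0], [1, 0.1, 0.05]),
                              f_window=(400.0, 1000.0))


class TestPhaseDelay:
    @staticmethod
    def curve_with_delay(delay_s):
        freqs = [1.0, 100.0, 150.0, 200.0, 300.0, 400.0]
        spikes = {}
        for f in freqs:
            # spikes locked to the (delayed) modulation peak: t = 1/(4f) + delay
            base = 1 / (4 * f) + delay_s
            spikes[f] = [base + np.arange(200) / f]
        return gain_curve(spikes, r0=5.0)

    def test_pure_delay_of_one_ms(self):
        curve = self.curve_with_delay(1e-3)
        assert phase_delay(curve, f_window=(100.0, 400.0)) == pytest.approx(1.0, abs=0.01)

    def test_zero_delay(self):
        curve = self.curve_with_delay(0.0)
        assert phase_delay(curve, f_window=(100.0, 400.0)) == pytest.approx(0.0, abs=0.01)


class TestLogisticFit:
    def test_reference_parameters_at_origin(self):
        # direct evaluation of the reference ball-and-stick fit at d = 0
        assert logistic(0.0, 57.69, 0.0541, 53.32, 81.3) == pytest.approx(84.35, abs=0.01)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(6)
        d = np.arange(0, 55, 5.0)
        true = (60.0, 0.08, 25.0, 80.0)
        y = logistic(d, *true) + rng.normal(0, 0.3, d.size)
        fit = fit_logistic(d, y)
        for got, want in zip((fit.a, fit.k, fit.d0, fit.b), true):
            assert got == pytest.approx(want, rel=0.05, abs=0.5)
        np.testing.assert_allclose(fit(d), y, atol=4 * 0.3)

    def test_flat_data_flagged_degenerate(self):
        d = np.arange(0, 55, 5.0)
        fit = fit_logistic(d, np.full(d.size, 90.0))
        assert fit.degenerate

    def test_needs_four_distances(self):
        with pytest.raises(ValueError):
            fit_logistic([0, 10, 20], [80, 90, 95])
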