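import json

import numpy as np
import pytest
from click.testing import CliRunner

from aisdyn.cable import SpikeTrain, VoltageTrace, build_bas
from aisdyn.cli import main
from aisdyn.experiments import (PRESETS, ExperimentConfig, ScalePreset,
                                run_fig2_sweep, run_lsm_experiment,
                                run_reduction_sweep)
from aisdyn.io import (load_model_json, load_spikes_text, load_template_text,
                       load_trace, save_model_json, save_spikes_text,
                       save_template_text, save_trace,
                       stimulus_config_from_json, stimulus_config_to_json)
from aisdyn.stimulus import StimulusConfig, make_templates

# tiny preset for orchestrator contract tests (quality is tested elsewhere)
PRESETS["micro"] = ScalePreset(
    name="micro", dt=0.01, cal_duration=20.0, waveform_duration=20.0,
    iv_duration=30.0, freqs=(1.0, 10.0, 30.0, 60.0),
    gain_rep_seconds=40.0, gain_reps_low=2, gain_reps_high=2,
    gain_split=np.inf, lsm_networks=2, lsm_train_seconds=20.0,
    distances=(0.0, 50.0), gain_reps_ref=4)


class TestFig2Sweep:
    @pytest.fixture(scope="class")
    def sweep(self, tmp_path_factory):
        out = tmp_path_factory.mktemp("sweep")
        cfg = ExperimentConfig(preset="micro", seed=7, out_dir=str(out))
        return run_fig2_sweep(cfg), out

    def test_emits_one_record_per_distance(self, sweep):
        result, _ = sweep
        assert result.manifest["failures"] == []
        assert list(result.table.d) == [0.0, 50.0]
        assert set(result.curves) == {0.0, 50.0}

    def test_calibration_hits_target_rate(self, sweep):
        result, _ = sweep
        assert np.all(np.abs(result.table.rate - 5.0) <= 0.25)
        assert np.all((result.table.subthreshold_sd >= 5.0)
                      & (result.table.subthreshold_sd <= 10.0))

    def test_outputs_written(self, sweep):
        result, out = sweep
        assert (out / "sweep.csv").exists()
        assert (out / "gain_d0.csv").exists()
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["seed"] == 7
        assert len(manifest["stages"]) == 2


class TestReductionSweep:
    def test_reproducible_table(self, tmp_path):
        cfg = ExperimentConfig(preset="micro", distances=(25.0,), seed=3,
                               out_dir=str(tmp_path))
        a = run_reduction_sweep(cfg)
        b = run_reduction_sweep(cfg)
        assert list(a.columns[:5]) == ["d", "tau_m", "E_L", "V_T", "Delta_T"]
        assert a.equals(b)
        assert (tmp_path / "eif_table.csv").exists()
        assert a.Delta_T.iloc[0] > 0


class TestLSMDriver:
    def test_accuracy_table_shape(self, tmp_path):
        cfg = ExperimentConfig(preset="micro", seed=5, out_dir=str(tmp_path),
                               lsm_distances=(0.0, 25.0), n_networks=2)
        res = run_lsm_experiment(cfg)
        rows = sum(len(res.accuracies[d]) for d in res.distances)
        assert rows == 4
        assert (tmp_path / "lsm_accuracy.csv").exists()
        assert (tmp_path / "lsm_pvalues.csv").exists()


class TestCLI:
    def test_subcommands_exposed(self):
        result = CliRunner().invoke(main, ["--help"])
        assert result.exit_code == 0
        for cmd in ("fig2-sweep", "reduce", "lsm"):
            assert cmd in result.output


class TestIO:
    def test_model_json_roundtrip_is_bit_exact(self, tmp_path):
        model = build_bas(d=35.0)
        path = tmp_path / "model.json"
        save_model_json(path, model)
        back = load_model_json(path)
        assert back.ais_distance == model.ais_distance
        assert back.geometry == model.geometry
        assert back.densities == model.densities
        assert back.kinetics == model.kinetics
        np.testing.assert_array_equal(back.g_na, model.g_na)
        np.testing.assert_array_equal(back.g_axial, model.g_axial)

    def test_stimulus_config_roundtrip(self):
        cfg = StimulusConfig(I0=-0.031875, I1=0.002, f=30.0, s=0.02,
                             duration=12.5, seed=9)
        assert stimulus_config_from_json(stimulus_config_to_json(cfg)) == cfg

    def test_trace_hdf5_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        trace = VoltageTrace(t=np.arange(1, 101) * 0.01,
                             v_soma=rng.normal(-65, 5, 100), dt=0.01,
                             v_all=rng.normal(-65, 5, (100, 3)))
        spikes = SpikeTrain(times=np.array([0.2, 0.5]), duration=1.0)
        path = tmp_path / "trace.h5"
        save_trace(path, trace, spikes)
        tr, sp = load_trace(path)
        np.testing.assert_array_equal(tr.v_soma, trace.v_soma)
        np.testing.assert_array_equal(tr.v_all, trace.v_all)
        np.testing.assert_array_equal(sp.times, spikes.times)
        assert sp.duration == spikes.duration

    def test_stimulus_hdf5_roundtrip(self, tmp_path):
        from aisdyn.io import load_stimulus, save_stimulus
        from aisdyn.stimulus import compose_stimulus
        cfg = StimulusConfig(I0=-0.03, s=0.02, duration=0.5, dt=0.05, seed=4)
        wave = compose_stimulus(cfg)
        path = tmp_path / "stim.h5"
        save_stimulus(path, wave, cfg)
        back, back_cfg = load_stimulus(path)
        np.testing.assert_array_equal(back, wave)
        assert back_cfg == cfg

    def test_spikes_text_roundtrip(self, tmp_path):
        spikes = SpikeTrain(times=np.array([0.0123456789, 1.5]), duration=2.0)
        path = tmp_path / "spikes.txt"
        save_spikes_text(path, spikes)
        back = load_spikes_text(path)
        np.testing.assert_allclose(back.times, spikes.times, atol=1e-9)
        assert back.duration == spikes.duration

    def test_template_text_roundtrip(self, tmp_path):
        a, _ = make_templates(13)
        path = tmp_path / "template.txt"
        save_template_text(path, a)
        back = load_template_text(path)
        assert back.n_channels == a.n_channels
        assert back.duration == a.duration
        for ch_a, ch_b in zip(a.times, back.times):
            np.testing.assert_allclose(ch_b, ch_a, atol=1e-9)
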