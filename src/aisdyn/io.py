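"""Serialization: HDF5 traces/spike trains, plain-text spikes and templates,
JSON round-trips for model and experiment configuration."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

from .cable import (BASModel, CableGeometry, ChannelDensities, KineticsParams,
                    SpikeTrain, VoltageTrace, build_bas)
from .stimulus import SpikeTemplate, StimulusConfig

__all__ = [
    "save_trace", "load_trace", "save_stimulus", "load_stimulus",
    "save_spikes_text", "load_spikes_text",
    "save_template_text", "load_template_text",
    "model_to_dict", "model_from_dict", "save_model_json", "load_model_json",
    "stimulus_config_to_json", "stimulus_config_from_json",
]


def save_trace(path, trace: VoltageTrace, spikes: SpikeTrain | None = None) -> None:
    """Write a voltage trace (datasets ``times``, ``V_soma``, optionally
    ``V_all`` and ``spikes``) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=trace.t)
        f.create_dataset("V_soma", data=trace.v_soma)
        f.attrs["dt"] = trace.dt
        if trace.v_all is not None:
            f.create_dataset("V_all", data=trace.v_all)
        if spikes is not None:
            f.create_dataset("spikes", data=spikes.times)
            f["spikes"].attrs["duration"] = spikes.duration


def load_trace(path) -> tuple[VoltageTrace, SpikeTrain | None]:
    with h5py.File(path, "r") as f:
        trace = VoltageTrace(
            t=f["times"][:], v_soma=f["V_soma"][:], dt=float(f.attrs["dt"]),
            v_all=f["V_all"][:] if "V_all" in f else None)
        spikes = None
        if "spikes" in f:
            spikes = SpikeTrain(times=f["spikes"][:],
                                duration=float(f["spikes"].attrs["duration"]))
    return trace, spikes


def save_stimulus(path, current_nA: np.ndarray, cfg: StimulusConfig) -> None:
    """Current waveform to HDF5 (dataset ``I`` in nA) with its generating
    configuration stored as a JSON attribute."""
    with h5py.File(path, "w") as f:
        f.create_dataset("I", data=current_nA)
        f.attrs["config"] = stimulus_config_to_json(cfg)


def load_stimulus(path) -> tuple[np.ndarray, StimulusConfig]:
    with h5py.File(path, "r") as f:
        return f["I"][:], stimulus_config_from_json(f.attrs["config"])


def save_spikes_text(path, spikes: SpikeTrain) -> None:
    """One spike time (s) per line; duration recorded in a header comment."""
    header = f"duration_s = {spikes.duration!r}"
    np.savetxt(path, spikes.times, fmt="%.9f", header=header)


def load_spikes_text(path) -> SpikeTrain:
    duration = None
    with open(path) as f:
        first = f.readline()
        if first.startswith("#") and "duration_s" in first:
            duration = float(first.split("=")[1])
    times = np.atleast_1d(np.loadtxt(path))
    if duration is None:
        duration = float(times[-1]) if times.size else 0.0
    return SpikeTrain(times=times, duration=duration)


def save_template_text(path, template: SpikeTemplate) -> None:
    """Two-column plain text: channel index, spike time (ms)."""
    rows = [(ch, t) for ch, times in enumerate(template.times) for t in times]
    with open(path, "w") as f:
        f.write(f"# n_channels = {template.n_channels}, duration_ms = "
                f"{template.duration}, rate = {template.rate}\n")
        for ch, t in rows:
            f.write(f"{ch}\t{t:.9f}\n")


def load_template_text(path) -> SpikeTemplate:
    with open(path) as f:
        header = f.readline()
        parts = {k.strip(): v.strip() for k, v in
                 (p.split("=") for p in header.lstrip("# ").split(","))}
        n_channels = int(parts["n_channels"])
        duration = float(parts["duration_ms"])
        rate = float(parts["rate"])
        chans: list[list[float]] = [[] for _ in range(n_channels)]
        for line in f:
            ch, t = line.split()
            chans[int(ch)].append(float(t))
    return SpikeTemplate(times=tuple(tuple(sorted(c)) for c in chans),
                         n_channels=n_channels, duration=duration, rate=rate)


def model_to_dict(model: BASModel) -> dict:
    """Every scalar field of the model, bit-exact (floats via hex)."""
    def enc(dc):
        return {k: (v.hex() if isinstance(v, float) else v)
                for k, v in dataclasses.asdict(dc).items()}

    return {
        "geometry": enc(model.geometry),
        "densities": enc(model.densities),
        "kinetics": enc(model.kinetics),
        "ais_distance": model.ais_distance.hex(),
    }


def _dec(cls, d):
    kwargs = {}
    for f in dataclasses.fields(cls):
        v = d[f.name]
        if f.type in ("float", float) and isinstance(v, str):
            v = float.fromhex(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def model_from_dict(d: dict) -> BASModel:
    return build_bas(geometry=_dec(CableGeometry, d["geometry"]),
                     densities=_dec(ChannelDensities, d["densities"]),
                     d=float.fromhex(d["ais_distance"]),
                     kinetics=_dec(KineticsParams, d["kinetics"]))


def save_model_json(path, model: BASModel) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def load_model_json(path) -> BASModel:
    return model_from_dict(json.loads(Path(path).read_text()))


def stimulus_config_to_json(cfg: StimulusConfig) -> str:
    d = {k: (v.hex() if isinstance(v, float) else v)
         for k, v in dataclasses.asdict(cfg).items()}
    return json.dumps(d, indent=1)


def stimulus_config_from_json(s: str) -> StimulusConfig:
    return _dec(StimulusConfig, json.loads(s))
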