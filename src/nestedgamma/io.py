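"""Trace, spike-train and simulation-container input/output.

Traces travel as two-column tabular text (time_ms, value) with the unit
in a header comment; spike trains as one-column text; whole simulations
as one HDF5 container per run with groups /cells/<name>/V,
/spikes/<name>, /ca, /weight plus the protocol echo and seed as
attributes.
"""
from __future__ import annotations

import json
from dataclasses import asdict

import h5py
import numpy as np

from .network import SimulationResult, StimulusProtocol
from .trace import SpikeTrain, Trace


def write_trace_text(trace: Trace, path) -> None:
    header = f"unit={trace.unit} dt_ms={trace.dt!r} t0_ms={trace.t0!r}"
    data = np.column_stack([trace.times, trace.values])
    np.savetxt(path, data, header=header, fmt="%.9g")


def read_trace_text(path) -> Trace:
    unit = "a.u."
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            if tok.startswith("unit="):
                unit = tok.split("=", 1)[1]
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 2:
        raise ValueError("expected two-column (time_ms, value) text with >= 2 rows")
    t, v = data[:, 0], data[:, 1]
    dts = np.diff(t)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
        raise ValueError("trace text is not uniformly sampled")
    return Trace(v, dt=float(dts[0]), t0=float(t[0]), unit=unit)


def write_spikes_text(spikes: SpikeTrain, path) -> None:
    np.savetxt(path, spikes.times, header=f"source={spikes.source}", fmt="%.9g")


def read_spikes_text(path, source: str = "") -> SpikeTrain:
    times = np.atleast_1d(np.loadtxt(path))
    return SpikeTrain(times, source=source)


def _write_trace(group: h5py.Group, name: str, trace: Trace) -> None:
    ds = group.create_dataset(name, data=trace.values, compression="gzip",
                              compression_opts=4)
    ds.attrs["dt_ms"] = trace.dt
    ds.attrs["t0_ms"] = trace.t0
    ds.attrs["unit"] = trace.unit


def _read_trace(ds: h5py.Dataset) -> Trace:
    return Trace(ds[()], dt=float(ds.attrs["dt_ms"]),
                 t0=float(ds.attrs["t0_ms"]), unit=str(ds.attrs["unit"]))


def save_simulation(result: SimulationResult, path) -> None:
    """Write one simulation run to an HDF5 container."""
    with h5py.File(path, "w") as f:
        cells = f.create_group("cells")
        for name, tr in result.voltages.items():
            _write_trace(cells.create_group(name), "V", tr)
        _write_trace(cells["PC"], "V_dendrite", result.dendrite_voltage)
        _write_trace(cells["PC"], "V_spine", result.spine_voltage)
        spikes = f.create_group("spikes")
        for name, st in result.spikes.items():
            spikes.create_dataset(name, data=st.times)
        _write_trace(f, "ca", result.spine_ca)
        _write_trace(f, "weight", result.weight)
        _write_trace(f, "detector", result.detector)
        f.create_dataset("ca3_events", data=np.asarray(result.ca3_events, float))
        f.attrs["protocol"] = json.dumps(asdict(result.protocol))
        f.attrs["seed"] = result.seed


def load_simulation(path) -> SimulationResult:
    with h5py.File(path, "r") as f:
        voltages = {}
        spikes = {}
        for name in f["cells"]:
            voltages[name] = _read_trace(f["cells"][name]["V"])
        for name in f["spikes"]:
            spikes[name] = SpikeTrain(f["spikes"][name][()], source=name)
        proto = StimulusProtocol(**json.loads(f.attrs["protocol"]))
        return SimulationResult(
            voltages=voltages,
            dendrite_voltage=_read_trace(f["cells"]["PC"]["V_dendrite"]),
            spine_voltage=_read_trace(f["cells"]["PC"]["V_spine"]),
            spikes=spikes,
            spine_ca=_read_trace(f["ca"]),
            weight=_read_trace(f["weight"]),
            detector=_read_trace(f["detector"]),
            ca3_events=f["ca3_events"][()],
            protocol=proto,
            seed=int(f.attrs["seed"]),
        )
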