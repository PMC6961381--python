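"""The CA3->CA1 microcircuit and its stimulation protocols.

The network contains one CA1 pyramidal cell (PC), a PV basket-type
interneuron reciprocally coupled to the PC soma, an SST interneuron
driven by the PC, a feedforward interneuron (IN) driven by the external
CA3 source and inhibiting the PC's proximal apical dendrite, and the CA3
event source itself, which excites the PC's dendritic spine through AMPA
(plastic) and NMDA receptors and excites IN.

The induction protocol mirrors the in-silico pairing experiment: a 5 Hz,
20 pA oscillatory current plus a 15 pA tonic step injected into the PC
soma evokes theta-paced spike bursts; CA3 events are scheduled on the
rising phase of theta, 10 ms before the first PC spike predicted for
each cycle by a noise-free calibration run, and repeated five times at
5 Hz. With the SST cell present, its sustained inhibition of IN
disinhibits the dendrite so paired CA3 input can drive spine calcium
past the potentiation threshold; without SST the feedforward inhibition
keeps calcium subthreshold and the weight stays at 1.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import engine
from .config import merge_config
from .engine import EdgeSpec, SineCurrent, StepCurrent
from .neurons import build_pc, build_interneuron, ConfigurationError
from .synapses import CaDynamicsParams, kinetics_from_config
from .trace import Trace, SpikeTrain

CA3 = "CA3"


@dataclass
class StimulusProtocol:
    """Theta drive, CA3 pairing schedule parameters, and noise."""

    theta_freq: float = 5.0       # Hz
    theta_amp: float = 20.0       # pA
    step_amp: float = 15.0        # pA
    pairing_dt: float = 10.0      # ms, CA3 event precedes predicted PC spike
    pairing_reps: int = 5
    pairing_rate: float = 5.0     # Hz
    pairing_start_cycle: int = 2  # first theta cycle carrying a CA3 event
    noise_sigma: float = 50.0     # pA
    noise_all_cells: bool = True
    duration: float = 2000.0      # ms
    seed: int = 0

    @classmethod
    def from_config(cls, cfg: dict, **overrides) -> "StimulusProtocol":
        p = cfg["protocol"]
        kw = dict(
            theta_freq=p["theta_freq_hz"], theta_amp=p["theta_amp_pA"],
            step_amp=p["step_amp_pA"], pairing_dt=p["pairing_dt_ms"],
            pairing_reps=p["pairing_reps"], pairing_rate=p["pairing_rate_hz"],
            pairing_start_cycle=p["pairing_start_cycle"],
            noise_sigma=p["noise_sigma_pA"], noise_all_cells=p["noise_all_cells"],
            duration=p["duration_ms"],
        )
        kw.update(overrides)
        return cls(**kw)

    @property
    def theta_period(self) -> float:
        return 1000.0 / self.theta_freq


@dataclass
class NetworkGraph:
    """Cells plus synaptic edges of the microcircuit."""

    cells: list                  # ordered (name, NeuronModel)
    edges: list                  # EdgeSpec; pre == "CA3" marks the event source
    plasticity: CaDynamicsParams
    theta_p: float
    with_sst: bool
    config: dict

    @property
    def cell_names(self) -> list:
        return [n for n, _ in self.cells]

    def has_edge(self, pre: str, post: str) -> bool:
        return any(e.pre == pre and e.post == post for e in self.edges)

    def drop_edge(self, pre: str, post: str) -> "NetworkGraph":
        edges = [e for e in self.edges if not (e.pre == pre and e.post == post)]
        return replace(self, edges=edges)


@dataclass
class SimulationResult:
    """Traces and spike trains of one network run (all at 10 kHz)."""

    voltages: dict               # cell -> soma Trace (mV)
    dendrite_voltage: Trace      # PC apical dendrite (mV)
    spine_voltage: Trace         # PC spine (mV)
    spikes: dict                 # cell -> SpikeTrain
    spine_ca: Trace              # uM
    weight: Trace                # normalized W
    detector: Trace              # P
    ca3_events: np.ndarray       # ms
    protocol: StimulusProtocol
    seed: int

    @property
    def peak_spine_ca(self) -> float:
        return float(self.spine_ca.values.max())

    @property
    def final_weight(self) -> float:
        return float(self.weight.values[-1])


# edge table: name in config -> (pre, post, post compartment)
_EDGE_TABLE = {
    "CA3->spine.AMPA": (CA3, "PC", "spine"),
    "CA3->spine.NMDA": (CA3, "PC", "spine"),
    "CA3->IN": (CA3, "IN", "soma"),
    "PC->PV": ("PC", "PV", "soma"),
    "PV->PC": ("PV", "PC", "soma"),
    "PC->SST": ("PC", "SST", "soma"),
    "SST->IN": ("SST", "IN", "soma"),
    "IN->PC": ("IN", "PC", "apical_dendrite"),
}


def build_network(with_sst: bool = True, config: dict | None = None) -> NetworkGraph:
    """Assemble the microcircuit; ``with_sst=False`` removes the SST cell
    (and therefore the SST->IN disinhibitory edge) leaving everything else
    identical, including the noise streams of the remaining cells."""
    cfg = merge_config(config)
    cells = [("PC", build_pc(config)), ("PV", build_interneuron("PV", config)),
             ("IN", build_interneuron("IN", config))]
    if with_sst:
        cells.insert(2, ("SST", build_interneuron("SST", config)))
    edges = []
    for name, entry in cfg["synapses"].items():
        if name not in _EDGE_TABLE:
            raise ConfigurationError(f"unknown synapse entry {name!r}")
        pre, post, role = _EDGE_TABLE[name]
        if not with_sst and ("SST" in (pre, post)):
            continue
        kin = kinetics_from_config(entry)
        edges.append(EdgeSpec(pre=pre, post=post, post_role=role, kinetics=kin,
                              weight=float(entry.get("weight", 1.0)),
                              delay_ms=float(entry.get("delay_ms", 1.0)),
                              plastic=bool(entry.get("plastic", False))))
    plast = CaDynamicsParams.from_config(cfg["plasticity"])
    return NetworkGraph(cells=cells, edges=edges, plasticity=plast,
                        theta_p=float(cfg["plasticity"]["theta_p_uM"]),
                        with_sst=with_sst, config=cfg)


def theta_drive(protocol: StimulusProtocol, t) -> np.ndarray | float:
    """Somatic drive current in pA: step + theta_amp * sin(2 pi f t)."""
    t = np.asarray(t, dtype=float)
    out = protocol.step_amp + protocol.theta_amp * np.sin(
        2 * math.pi * protocol.theta_freq * t / 1000.0)
    return out if out.ndim else float(out)


def _packed(network: NetworkGraph) -> engine.PackedNetwork:
    dt = float(network.config["simulation"]["dt_internal_ms"])
    return engine.PackedNetwork(network.cells, network.edges,
                                plasticity=network.plasticity,
                                theta_p=network.theta_p,
                                dt_internal=dt, spine_cell="PC")


def _drive_stimuli(protocol: StimulusProtocol):
    return [("PC", "soma", SineCurrent(freq_hz=protocol.theta_freq,
                                       amp_pA=protocol.theta_amp,
                                       offset_pA=protocol.step_amp))]


class ProtocolError(RuntimeError):
    """The pairing schedule could not be constructed."""


def predict_pc_spike_times(network: NetworkGraph, protocol: StimulusProtocol,
                           n_cycles: int) -> list:
    """First PC spike per theta cycle from a noise-free calibration run
    without CA3 input. Raises ProtocolError for any spikeless cycle."""
    period = protocol.theta_period
    duration = (n_cycles + 1) * period
    packed = _packed(network)
    res = engine.run(packed, duration, stimuli=_drive_stimuli(protocol),
                     noise_sigma_pA=0.0, seed=0)
    spk = res.spikes["PC"].times
    firsts = []
    for k in range(n_cycles):
        lo, hi = k * period, (k + 1) * period
        inside = spk[(spk >= lo) & (spk < hi)]
        if inside.size == 0:
            raise ProtocolError(f"no PC spike in calibration theta cycle {k}")
        firsts.append(float(inside[0]))
    return firsts


def pairing_schedule(network: NetworkGraph, protocol: StimulusProtocol) -> np.ndarray:
    """CA3 event times: ``pairing_reps`` events at ``pairing_rate``, each
    10 ms (``pairing_dt``) before the predicted first PC spike of its
    theta cycle (rising-phase activation)."""
    if protocol.pairing_reps == 0:
        return np.empty(0)
    period = protocol.theta_period
    cycle_stride = protocol.theta_freq / protocol.pairing_rate
    cycles = [protocol.pairing_start_cycle + int(round(k * cycle_stride))
              for k in range(protocol.pairing_reps)]
    firsts = predict_pc_spike_times(network, protocol, max(cycles) + 1)
    events = np.array([firsts[c] - protocol.pairing_dt for c in cycles])
    if np.any(events < 0):
        raise ProtocolError("pairing event before t=0; increase pairing_start_cycle")
    return events


def run_simulation(network: NetworkGraph, protocol: StimulusProtocol,
                   ca3_events: np.ndarray | str | None = "pairing",
                   seed: int | None = None) -> SimulationResult:
    """Co-simulate the circuit under theta drive.

    ``ca3_events`` may be "pairing" (default; schedule computed from a
    noise-free calibration run), an explicit array of times in ms, or
    None for no CA3 input. Deterministic for fixed inputs and seed.
    """
    seed = protocol.seed if seed is None else seed
    if isinstance(ca3_events, str):
        if ca3_events != "pairing":
            raise ValueError("ca3_events must be 'pairing', an array, or None")
        ca3_events = pairing_schedule(network, protocol)
    elif ca3_events is None:
        ca3_events = np.empty(0)
    else:
        ca3_events = np.asarray(ca3_events, dtype=float)
    packed = _packed(network)
    noise_cells = None if protocol.noise_all_cells else ["PC"]
    res = engine.run(packed, protocol.duration, stimuli=_drive_stimuli(protocol),
                     noise_sigma_pA=protocol.noise_sigma, noise_cells=noise_cells,
                     seed=seed, ext_events=ca3_events)
    voltages = {name: res.voltages[(name, "soma")] for name in network.cell_names}
    return SimulationResult(
        voltages=voltages,
        dendrite_voltage=res.voltages[("PC", "apical_dendrite")],
        spine_voltage=res.voltages[("PC", "spine")],
        spikes=res.spikes,
        spine_ca=res.calcium[("PC", "spine")],
        weight=res.weight,
        detector=res.detector,
        ca3_events=ca3_events,
        protocol=protocol,
        seed=seed,
    )


def run_repetitions(network: NetworkGraph, protocol: StimulusProtocol,
                    n: int = 10, base_seed: int = 0,
                    ca3_events="pairing"):
    """Run ``n`` repetitions with seeds base_seed..base_seed+n-1.

    Returns (results, summary DataFrame) where the summary holds one row
    per repetition: peak spine calcium, final weight, and per-cell rates.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(ca3_events, str) and ca3_events == "pairing":
        ca3_events = pairing_schedule(network, protocol)  # shared schedule
    results = []
    rows = []
    for k in range(n):
        res = run_simulation(network, protocol, ca3_events=ca3_events,
                             seed=base_seed + k)
        results.append(res)
        row = {"seed": res.seed, "peak_ca_uM": res.peak_spine_ca,
               "final_W": res.final_weight}
        for name, spk in res.spikes.items():
            row[f"rate_{name}_Hz"] = spk.rate(protocol.duration)
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("seed")
    return results, summary
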