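"""Network packing and the public simulation interface.

The compiled kernel (:mod:`._kernel`) operates on flat arrays; this
module translates :class:`~.neurons.NeuronModel` objects, synapse edges
and stimulation waveforms into that representation, runs the kernel, and
returns unit-carrying :class:`~.trace.Trace` / :class:`~.trace.SpikeTrain`
containers sampled at 10 kHz (0.1 ms) regardless of the internal step.

Determinism contract: for identical models, stimuli, duration and seed
the output is bit-identical. All noise is drawn ahead of the run from
``numpy.random.default_rng([seed, stream])`` with one fixed stream id per
cell role, so adding or removing one cell never perturbs the noise of
the others.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .neurons import NeuronModel, NeuronState, ConfigurationError
from .synapses import SynapseKinetics, CaDynamicsParams
from .trace import Trace, SpikeTrain

GATE_NAMES = ("m", "h", "n", "a", "b", "s", "u", "q", "r")

# fixed noise stream ids per cell role (unknown names get stable fallbacks)
NOISE_STREAMS = {"PC": 1, "PV": 2, "SST": 3, "IN": 4}


class IntegrationError(RuntimeError):
    """Numerical blow-up; carries the time of failure in ms."""

    def __init__(self, t_fail_ms: float, cell: str = ""):
        self.t_fail_ms = t_fail_ms
        self.cell = cell
        where = f" in cell {cell}" if cell else ""
        super().__init__(f"integration failure (|V| > 200 mV or non-finite) "
                         f"at t = {t_fail_ms:.3f} ms{where}")


@dataclass
class StepCurrent:
    """Constant current step in pA between t_on and t_off (ms)."""

    amp_pA: float
    t_on: float = 0.0
    t_off: float = math.inf

    def sample(self, t: np.ndarray) -> np.ndarray:
        return np.where((t >= self.t_on) & (t < self.t_off), self.amp_pA, 0.0)


@dataclass
class SineCurrent:
    """Sinusoidal current amp*sin(2 pi f (t - t_on)) in pA, plus offset."""

    freq_hz: float
    amp_pA: float
    offset_pA: float = 0.0
    t_on: float = 0.0
    t_off: float = math.inf

    def sample(self, t: np.ndarray) -> np.ndarray:
        on = (t >= self.t_on) & (t < self.t_off)
        wave = self.offset_pA + self.amp_pA * np.sin(
            2 * math.pi * self.freq_hz * (t - self.t_on) / 1000.0)
        return np.where(on, wave, 0.0)


@dataclass
class ArrayCurrent:
    """Current given sample-by-sample on the output grid (pA)."""

    values_pA: np.ndarray

    def sample(self, t: np.ndarray) -> np.ndarray:
        out = np.zeros_like(t)
        k = min(len(self.values_pA), len(t))
        out[:k] = self.values_pA[:k]
        return out


@dataclass
class EdgeSpec:
    """One synaptic connection of the packed network.

    ``pre`` is a cell name or "CA3" for the external event source;
    ``post_role`` selects the target compartment of the posts cell.
    """

    pre: str
    post: str
    post_role: str
    kinetics: SynapseKinetics
    weight: float = 1.0
    delay_ms: float = 1.0
    plastic: bool = False


@dataclass
class RawResult:
    voltages: dict          # (cell, role) -> Trace [mV]
    spikes: dict            # cell -> SpikeTrain
    calcium: dict           # (cell, role) -> Trace [uM] (pools only)
    weight: Trace | None    # normalized synaptic weight W
    detector: Trace | None  # potentiation detector P
    states: dict            # cell -> NeuronState at end of run
    dt_output: float
    duration: float


def steady_gates(V: float, ca: float = 0.05) -> dict:
    """Steady-state gating values at a fixed voltage (kernel kinetics)."""
    def vtrap(x, s):
        u = x / s
        if abs(u) < 1e-6:
            return s * (1 + 0.5 * u)
        return x / (1.0 - math.exp(-u))

    am = 0.32 * vtrap(V + 54.0, 4.0)
    bm = 0.28 * vtrap(-(V + 27.0), 5.0)
    ah = 0.128 * math.exp(-(V + 50.0) / 18.0)
    bh = 4.0 / (1.0 + math.exp(-(V + 27.0) / 5.0))
    an = 0.032 * vtrap(V + 52.0, 5.0)
    bn = 0.5 * math.exp(-(V + 57.0) / 40.0)
    aq = min(0.004 * ca * ca, 0.05)
    bq = 0.004
    return {
        "m": am / (am + bm),
        "h": ah / (ah + bh),
        "n": an / (an + bn),
        "a": 1.0 / (1.0 + math.exp(-(V + 25.0) / 15.0)),
        "b": 1.0 / (1.0 + math.exp((V + 75.0) / 6.0)),
        "s": 1.0 / (1.0 + math.exp(-(V + 15.0) / 6.0)),
        "u": 1.0 / (1.0 + math.exp(-(V + 35.0) / 10.0)),
        "q": aq / (aq + bq),
        "r": 1.0 / (1.0 + math.exp((V + 80.0) / 8.0)),
    }


def initial_state(model: NeuronModel, V0: float | None = None) -> NeuronState:
    """Resting state: V at E_leak (or V0), gating at steady state."""
    nc = len(model.compartments)
    V = np.full(nc, model.E_leak if V0 is None else V0, dtype=float)
    ca = np.array([
        (c.ca_pool or {}).get("base_uM", 0.05) for c in model.compartments
    ])
    gates = {g: np.empty(nc) for g in GATE_NAMES}
    for i in range(nc):
        ss = steady_gates(V[i], ca[i])
        for g in GATE_NAMES:
            gates[g][i] = ss[g]
    return NeuronState(V=V, gating=gates, ca=ca, t=0.0)


class PackedNetwork:
    """Flat-array view of a set of cells plus synaptic edges."""

    def __init__(self, cells, edges=(), plasticity: CaDynamicsParams | None = None,
                 theta_p: float = 4.0, dt_internal: float = 0.025,
                 spine_cell: str | None = None):
        self.cells = list(cells)              # list of (name, NeuronModel)
        self.edges = list(edges)
        self.dt = float(dt_internal)
        self.names = [name for name, _ in self.cells]
        self.comp_index = {}                  # (cell, role) -> flat index
        self.cell_of_comp = []
        roles = []
        for ci, (name, model) in enumerate(self.cells):
            for comp in model.compartments:
                self.comp_index[(name, comp.role)] = len(self.cell_of_comp)
                self.cell_of_comp.append(ci)
                roles.append((name, comp.role))
        self.comp_labels = roles
        nc = len(roles)
        self.nc = nc

        self.cm = np.zeros(nc)
        self.gl = np.zeros(nc)
        self.el = np.zeros(nc)
        self.gch = {cid: np.zeros(nc) for cid in ("Na", "KDR", "KA", "CaL", "KM", "AHP", "H")}
        self.axial = np.zeros((nc, nc))
        self.ca_gain = np.zeros(nc)
        self.ca_tau = np.full(nc, 1.0)
        self.ca_base = np.zeros(nc)

        for name, model in self.cells:
            for comp in model.compartments:
                i = self.comp_index[(name, comp.role)]
                self.cm[i] = comp.capacitance_nF
                self.gl[i] = comp.g_abs_uS("leak")
                self.el[i] = model.E_leak
                for cid in self.gch:
                    self.gch[cid][i] = comp.g_abs_uS(cid)
                if comp.ca_pool:
                    self.ca_gain[i] = float(comp.ca_pool["gain"])
                    self.ca_tau[i] = float(comp.ca_pool["tau_ms"])
                    self.ca_base[i] = float(comp.ca_pool.get("base_uM", 0.05))
            # axial coupling inside multicompartment cells
            if len(model.compartments) > 1:
                soma = model.compartment("soma")
                dend = model.compartment("apical_dendrite")
                i_s = self.comp_index[(name, "soma")]
                i_d = self.comp_index[(name, "apical_dendrite")]
                r_sd = soma.axial_half_resistance_MOhm() + dend.axial_half_resistance_MOhm()
                g_sd = 1.0 / r_sd
                self.axial[i_s, i_d] = self.axial[i_d, i_s] = g_sd
                if "spine" in model.roles:
                    i_p = self.comp_index[(name, "spine")]
                    g_neck = 1.0 / float(model.spine_neck_MOhm or 500.0)
                    self.axial[i_d, i_p] = self.axial[i_p, i_d] = g_neck

        self.soma_comp = np.array(
            [self.comp_index[(name, "soma")] for name, _ in self.cells], dtype=np.int64)

        # plasticity / spine calcium
        self.plasticity = plasticity
        self.theta_p = theta_p
        self.spine_comp = -1
        if spine_cell is not None and (spine_cell, "spine") in self.comp_index:
            self.spine_comp = self.comp_index[(spine_cell, "spine")]
            if plasticity is not None:
                self.ca_gain[self.spine_comp] = plasticity.ca_gain * 1e3  # uM/(nA ms)
                self.ca_tau[self.spine_comp] = plasticity.tau_ca_ms
                self.ca_base[self.spine_comp] = plasticity.ca_baseline_uM

        # synapses
        ns = len(self.edges)
        self.syn_kind = np.zeros(ns, dtype=np.int64)
        self.syn_pre = np.zeros(ns, dtype=np.int64)
        self.syn_post = np.zeros(ns, dtype=np.int64)
        self.syn_e = np.zeros(ns)
        self.syn_g = np.zeros(ns)
        self.syn_plastic = np.zeros(ns, dtype=np.int64)
        self.syn_dfac1 = np.ones(ns)
        self.syn_dfac2 = np.ones(ns)
        self.syn_norm = np.ones(ns)
        self.syn_delay = np.ones(ns, dtype=np.int64)
        self.syn_mgk = np.zeros(ns)
        kind_codes = {"biexp": _kernel.K_BIEXP, "ampa_single_exp": _kernel.K_AMPA,
                      "nmda_mg_block": _kernel.K_NMDA}
        for j, e in enumerate(self.edges):
            kin = e.kinetics
            self.syn_kind[j] = kind_codes[kin.kind]
            self.syn_pre[j] = self.names.index(e.pre) if e.pre in self.names else -1
            if (e.post, e.post_role) not in self.comp_index:
                raise ConfigurationError(
                    f"edge {e.pre}->{e.post} targets unknown compartment {e.post_role!r}")
            self.syn_post[j] = self.comp_index[(e.post, e.post_role)]
            self.syn_e[j] = kin.E_rev
            self.syn_g[j] = kin.g_max * e.weight
            self.syn_plastic[j] = 1 if e.plastic else 0
            if kin.kind == "ampa_single_exp":
                self.syn_dfac1[j] = math.exp(-self.dt / kin.tau)
            else:
                self.syn_dfac1[j] = math.exp(-self.dt / kin.tau_decay)
                self.syn_dfac2[j] = math.exp(-self.dt / kin.tau_rise)
                self.syn_norm[j] = kin.biexp_norm
            self.syn_delay[j] = max(1, round(e.delay_ms / self.dt))
            self.syn_mgk[j] = kin.mg_mM / 3.57
        self.buflen = int(self.syn_delay.max() if ns else 1) + 2


def run(packed: PackedNetwork, duration: float, *, dt_output: float = 0.1,
        stimuli=(), noise_sigma_pA: float = 0.0, noise_cells=None, seed: int = 0,
        ext_events=None, init_states: dict | None = None,
        spike_threshold: float = 0.0, refractory_ms: float = 2.0) -> RawResult:
    """Integrate the packed network and return traces at ``dt_output``.

    ``stimuli`` is an iterable of (cell_name, role, waveform) with the
    waveform in pA on the output-step grid; ``ext_events`` are CA3 source
    event times in ms. Noise (sigma in pA) is injected into the soma of
    every cell in ``noise_cells`` (default: all), redrawn each output
    step and held across internal substeps.
    """
    dt = packed.dt
    if duration <= 0:
        raise ValueError("duration must be positive")
    substeps = round(dt_output / dt)
    if not math.isclose(substeps * dt, dt_output, rel_tol=1e-9):
        raise ValueError("dt_internal must divide the 0.1 ms output interval")
    nrec = int(round(duration / dt_output))
    nc = packed.nc
    ncell = len(packed.cells)

    # state
    V = np.empty(nc)
    gates = {g: np.empty(nc) for g in GATE_NAMES}
    ca = np.empty(nc)
    for ci, (name, model) in enumerate(packed.cells):
        st = (init_states or {}).get(name) or initial_state(model)
        for k, comp in enumerate(model.compartments):
            i = packed.comp_index[(name, comp.role)]
            V[i] = st.V[k]
            ca[i] = st.ca[k]
            for g in GATE_NAMES:
                gates[g][i] = st.gating[g][k]
    if packed.spine_comp >= 0 and packed.plasticity is not None:
        ca[packed.spine_comp] = max(ca[packed.spine_comp], packed.plasticity.ca_baseline_uM)

    # injected currents, nA
    t_grid = dt_output * np.arange(nrec)
    inj = np.zeros((nrec, nc))
    for cell_name, role, waveform in stimuli:
        i = packed.comp_index[(cell_name, role)]
        inj[:, i] += waveform.sample(t_grid) * 1e-3
    if noise_sigma_pA > 0:
        targets = packed.names if noise_cells is None else list(noise_cells)
        for name in targets:
            stream = NOISE_STREAMS.get(name, 100 + sorted(packed.names).index(name))
            rng = np.random.default_rng([int(seed), stream])
            i = packed.comp_index[(name, "soma")]
            inj[:, i] += rng.normal(0.0, noise_sigma_pA, nrec) * 1e-3

    # external events
    if ext_events is None or len(ext_events) == 0:
        ext_steps = np.empty(0, dtype=np.int64)
        ext_syn = np.empty(0, dtype=np.int64)
    else:
        ev = np.asarray(ext_events, dtype=float)
        steps, syns = [], []
        for j in range(len(packed.edges)):
            if packed.syn_pre[j] == -1:
                for t_ev in ev:
                    steps.append(int(round(t_ev / dt)) + int(packed.syn_delay[j]))
                    syns.append(j)
        order = np.argsort(np.asarray(steps), kind="stable")
        ext_steps = np.asarray(steps, dtype=np.int64)[order]
        ext_syn = np.asarray(syns, dtype=np.int64)[order]

    plast = packed.plasticity
    pw = np.array([0.0, 1.0])
    nmda_frac = plast.nmda_ca_fraction if plast else 0.0
    k_p = plast.k_p_per_ms if plast else 0.0
    tau_p = plast.tau_p_ms if plast else 1.0
    k_w = plast.k_w_per_ms if plast else 0.0
    w_max = plast.w_max if plast else 1.0

    refrac_steps = max(1, round(refractory_ms / dt))
    max_spikes = int(duration * 0.5) + 16
    spike_times = np.zeros((ncell, max_spikes))
    spike_counts = np.zeros(ncell, dtype=np.int64)
    spike_buf = np.zeros((ncell, packed.buflen), dtype=np.int64)
    last_spike = np.full(ncell, -(10**9), dtype=np.int64)

    out_v = np.empty((nrec, nc))
    out_ca = np.empty((nrec, nc))
    out_w = np.empty((nrec, 2))
    s1 = np.zeros(len(packed.edges))
    s2 = np.zeros(len(packed.edges))

    v0 = V.copy()
    ca0 = ca.copy()
    status = _kernel.run_network(
        dt, substeps, nrec,
        packed.cm, packed.gl, packed.el,
        packed.gch["Na"], packed.gch["KDR"], packed.gch["KA"], packed.gch["CaL"],
        packed.gch["KM"], packed.gch["AHP"], packed.gch["H"],
        packed.axial, packed.ca_gain, packed.ca_tau, packed.ca_base,
        V, gates["m"], gates["h"], gates["n"], gates["a"], gates["b"],
        gates["s"], gates["u"], gates["q"], gates["r"], ca,
        packed.soma_comp,
        packed.syn_kind, packed.syn_pre, packed.syn_post, packed.syn_e,
        packed.syn_g, packed.syn_plastic, packed.syn_dfac1, packed.syn_dfac2,
        packed.syn_norm, packed.syn_delay, packed.syn_mgk,
        s1, s2, ext_steps, ext_syn, inj,
        packed.spine_comp, nmda_frac, packed.theta_p, k_p, tau_p, k_w, w_max, pw,
        spike_threshold, refrac_steps,
        spike_buf, last_spike, spike_times, spike_counts, max_spikes,
        out_v, out_ca, out_w,
    )
    if status != _kernel.STATUS_OK:
        raise IntegrationError(t_fail_ms=(status + 1) * dt)

    voltages, calcium, states = {}, {}, {}
    for ci, (name, model) in enumerate(packed.cells):
        nc_i = len(model.compartments)
        Vst = np.empty(nc_i)
        cast = np.empty(nc_i)
        gst = {g: np.empty(nc_i) for g in GATE_NAMES}
        for k, comp in enumerate(model.compartments):
            i = packed.comp_index[(name, comp.role)]
            vals = np.concatenate(([v0[i]], out_v[:, i]))
            voltages[(name, comp.role)] = Trace(vals, dt_output, 0.0, "mV")
            if packed.ca_gain[i] > 0:
                cvals = np.concatenate(([ca0[i]], out_ca[:, i]))
                calcium[(name, comp.role)] = Trace(cvals, dt_output, 0.0, "uM")
            Vst[k] = V[i]
            cast[k] = ca[i]
            for g in GATE_NAMES:
                gst[g][k] = gates[g][i]
        states[name] = NeuronState(V=Vst, gating=gst, ca=cast, t=duration)

    spikes = {
        name: SpikeTrain(spike_times[ci, :spike_counts[ci]].copy(), source=name)
        for ci, (name, _) in enumerate(packed.cells)
    }
    weight = detector = None
    if packed.spine_comp >= 0 and plast is not None:
        weight = Trace(np.concatenate(([1.0], out_w[:, 1])), dt_output, 0.0, "a.u.")
        detector = Trace(np.concatenate(([0.0], out_w[:, 0])), dt_output, 0.0, "a.u.")
    return RawResult(voltages=voltages, spikes=spikes, calcium=calcium,
                     weight=weight, detector=detector, states=states,
                     dt_output=dt_output, duration=duration)


def integrate(model: NeuronModel, state: NeuronState | None = None, stimuli=(),
              duration: float = 1000.0, dt_internal: float = 0.025, seed: int = 0,
              noise_sigma_pA: float = 0.0):
    """Integrate a single neuron model.

    ``stimuli`` is a list of (role, waveform) pairs (waveform in pA).
    Returns ({role: Trace}, final NeuronState); traces are sampled at
    10 kHz regardless of ``dt_internal`` (which must be <= 0.05 ms).
    """
    if dt_internal > 0.05:
        raise ValueError("dt_internal must be <= 0.05 ms")
    name = model.cell_type
    packed = PackedNetwork([(name, model)], dt_internal=dt_internal)
    res = run(packed, duration,
              stimuli=[(name, role, w) for role, w in stimuli],
              noise_sigma_pA=noise_sigma_pA, seed=seed,
              init_states={name: state} if state else None)
    traces = {role: res.voltages[(name, role)] for role in model.roles}
    return traces, res.states[name]


def detect_spikes(voltage: Trace, threshold: float = 0.0,
                  refractory: float = 2.0, source: str = "") -> SpikeTrain:
    """Upward threshold crossings separated by at least ``refractory`` ms."""
    if voltage.unit != "mV":
        raise ValueError("spike detection expects a voltage trace in mV")
    v = voltage.values
    crossings = np.flatnonzero((v[1:] >= threshold) & (v[:-1] < threshold)) + 1
    kept = []
    last = -math.inf
    for idx in crossings:
        t = voltage.t0 + idx * voltage.dt
        if t - last >= refractory:
            kept.append(t)
            last = t
    return SpikeTrain(np.asarray(kept), source=source)


def f_i_curve(model: NeuronModel, current_steps_pA, step_duration: float = 500.0,
              settle: float = 300.0, dt_internal: float = 0.025) -> np.ndarray:
    """Firing rate (Hz) for each step current, from rest.

    Rate = spike count during the step divided by the step duration.
    """
    rates = []
    for amp in current_steps_pA:
        stim = [("soma", StepCurrent(float(amp), t_on=settle, t_off=settle + step_duration))]
        traces, _ = integrate(model, stimuli=stim, duration=settle + step_duration + 20.0,
                              dt_internal=dt_internal)
        spk = detect_spikes(traces["soma"])
        n = np.count_nonzero((spk.times >= settle) & (spk.times < settle + step_duration))
        rates.append(n / step_duration * 1000.0)
    return np.asarray(rates)
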