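"""Receptor kinetics and the calcium-threshold potentiation rule.

Three receptor current models are provided:

* AMPA, a single-exponential conductance: I = g_max e^(-t/tau) (V - E).
* NMDA, a peak-normalized difference of exponentials multiplied by the
  sigmoidal voltage-dependent magnesium-block factor
  B(V) = 1 / (1 + ([Mg]/3.57 mM) e^(-0.062 V)), [Mg] = 0.5 mM by default.
* A generic peak-normalized double-exponential conductance used for all
  cell-to-cell synapses; excitatory synapses decay with 15 ms,
  inhibitory with 40 ms, both rising with 3 ms.

Plasticity is potentiation-only and deterministic: the spine calcium
pool is a first-order compartment fed by a fixed fraction of the NMDA
conductance (with a Ca2+ driving force) and by the spine's L-type Ca2+
channel. Whenever calcium exceeds the 4 uM threshold a potentiation
detector P charges toward 1; P in turn drives the normalized synaptic
weight W of the CA3->CA1 AMPA synapse toward a saturating maximum, so W
is non-decreasing and equals exactly 1 if the threshold is never crossed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

MG_IC50_MM = 3.57     # Mg-block half-blocking concentration scale (mM)
MG_SLOPE_PER_MV = 0.062

# Faraday constant in the unit mix used below: converts pA*ms in a volume
# of um^3 to uM of free Ca (before buffering): 1 pA*ms / (2F) / 1 um^3.
_PAMS_PER_UM3_TO_UM = 1e-15 / (2 * 96485.332) / 1e-15 * 1e6  # ~5.182


@dataclass
class SynapseKinetics:
    """Parameters of one receptor/synapse model.

    ``kind`` selects the formulation: "ampa_single_exp" uses ``tau``;
    "biexp" and "nmda_mg_block" use ``tau_rise`` < ``tau_decay``;
    the NMDA model additionally uses ``mg_mM``.
    ``g_max`` is in uS; reversal in mV.
    """

    kind: str
    g_max: float
    E_rev: float = 0.0
    tau: float | None = None
    tau_rise: float | None = None
    tau_decay: float | None = None
    mg_mM: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("ampa_single_exp", "nmda_mg_block", "biexp"):
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        if self.g_max < 0:
            raise ValueError("g_max must be non-negative")
        if self.mg_mM < 0:
            raise ValueError("mg_mM must be non-negative")
        if self.kind == "ampa_single_exp":
            if not self.tau or self.tau <= 0:
                raise ValueError("ampa_single_exp requires tau > 0")
        else:
            if self.tau_rise is None or self.tau_decay is None:
                raise ValueError(f"{self.kind} requires tau_rise and tau_decay")
            if self.tau_rise >= self.tau_decay:
                raise ValueError("tau_rise must be smaller than tau_decay")

    @property
    def peak_time(self) -> float:
        """Time of the conductance maximum after an event (ms)."""
        if self.kind == "ampa_single_exp":
            return 0.0
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * math.log(td / tr)

    @property
    def biexp_norm(self) -> float:
        """Normalization making the double-exponential peak equal 1."""
        tp = self.peak_time
        return 1.0 / (math.exp(-tp / self.tau_decay) - math.exp(-tp / self.tau_rise))


def mg_block(Vm, mg_mM: float = 0.5):
    """Sigmoidal Mg-block factor in (0, 1), monotone increasing in Vm."""
    return 1.0 / (1.0 + (mg_mM / MG_IC50_MM) * np.exp(-MG_SLOPE_PER_MV * np.asarray(Vm, dtype=float)))


def _check_t(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_event must be non-negative")
    return t


def ampa_current(kin: SynapseKinetics, t_since_event, Vm) -> np.ndarray | float:
    """AMPA current in pA: g_max e^(-t/tau) (Vm - E_rev), g_max in uS.

    uS * mV = nA, so the conversion to pA is a factor 1000.
    """
    if kin.kind != "ampa_single_exp":
        raise ValueError("ampa_current requires ampa_single_exp kinetics")
    t = _check_t(t_since_event)
    return kin.g_max * np.exp(-t / kin.tau) * (np.asarray(Vm) - kin.E_rev) * 1e3


def biexp_conductance(kin: SynapseKinetics, t_since_event) -> np.ndarray | float:
    """Peak-normalized double-exponential conductance factor in [0, 1]."""
    if kin.kind not in ("biexp", "nmda_mg_block"):
        raise ValueError("biexp_conductance requires biexp or nmda kinetics")
    t = _check_t(t_since_event)
    g = kin.biexp_norm * (np.exp(-t / kin.tau_decay) - np.exp(-t / kin.tau_rise))
    return np.maximum(g, 0.0)


def nmda_current(kin: SynapseKinetics, t_since_event, Vm) -> np.ndarray | float:
    """NMDA current in pA with voltage-dependent magnesium block."""
    if kin.kind != "nmda_mg_block":
        raise ValueError("nmda_current requires nmda_mg_block kinetics")
    g = biexp_conductance(kin, t_since_event)
    return kin.g_max * g * (np.asarray(Vm) - kin.E_rev) * mg_block(Vm, kin.mg_mM) * 1e3


@dataclass
class CaDynamicsParams:
    """Spine calcium, detector and readout constants.

    The calcium gain (uM of free Ca per pA*ms of Ca current) is derived
    from the effective spine volume and the endogenous buffer capacity;
    extrusion is first order with ``tau_ca_ms``.
    """

    nmda_ca_fraction: float = 0.1
    spine_volume_um3: float = 0.5
    buffer_capacity: float = 250.0
    tau_ca_ms: float = 20.0
    ca_baseline_uM: float = 0.05
    k_p_per_ms: float = 0.5
    tau_p_ms: float = 50.0
    k_w_per_ms: float = 0.0025
    w_max: float = 2.0

    def __post_init__(self) -> None:
        for name in ("nmda_ca_fraction", "spine_volume_um3", "buffer_capacity",
                     "tau_ca_ms", "k_p_per_ms", "tau_p_ms", "k_w_per_ms", "w_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def ca_gain(self) -> float:
        """uM per pA*ms of calcium current."""
        return _PAMS_PER_UM3_TO_UM / (self.spine_volume_um3 * (1.0 + self.buffer_capacity))

    @classmethod
    def from_config(cls, plast_cfg: dict) -> "CaDynamicsParams":
        return cls(
            nmda_ca_fraction=plast_cfg["nmda_ca_fraction"],
            spine_volume_um3=plast_cfg["spine_volume_um3"],
            buffer_capacity=plast_cfg["buffer_capacity"],
            tau_ca_ms=plast_cfg["tau_ca_ms"],
            ca_baseline_uM=plast_cfg["ca_baseline_uM"],
            k_p_per_ms=plast_cfg["k_p_per_ms"],
            tau_p_ms=plast_cfg["tau_p_ms"],
            k_w_per_ms=plast_cfg["k_w_per_ms"],
            w_max=plast_cfg["w_max"],
        )


@dataclass
class PlasticityState:
    """The spine's (Ca, P, W) triple; W starts at 1 and never decreases."""

    ca: float = 0.05          # uM
    P: float = 0.0
    W: float = 1.0
    theta_p: float = 4.0      # uM

    def __post_init__(self) -> None:
        if self.ca < 0 or self.P < 0:
            raise ValueError("ca and P must be non-negative")
        if self.W < 1.0:
            raise ValueError("W starts at 1 and is potentiation-only")

    @property
    def above_threshold(self) -> bool:
        return self.ca > self.theta_p


def update_spine_calcium(state: PlasticityState, params: CaDynamicsParams,
                         nmda_flux_pA: float, cal_flux_pA: float,
                         dt: float) -> PlasticityState:
    """Advance the spine calcium pool by one step of length ``dt`` (ms).

    d[Ca]/dt = gain * (f_NMDA * nmda_flux + cal_flux) - ([Ca]-base)/tau.
    Fluxes are calcium currents in pA (inward positive). The update is
    the exact solution for fluxes held constant over the step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    influx = params.ca_gain * (params.nmda_ca_fraction * nmda_flux_pA + cal_flux_pA)
    target = params.ca_baseline_uM + influx * params.tau_ca_ms
    ca = target + (state.ca - target) * math.exp(-dt / params.tau_ca_ms)
    return PlasticityState(ca=max(ca, 0.0), P=state.P, W=state.W, theta_p=state.theta_p)


def stdp_update(state: PlasticityState, params: CaDynamicsParams,
                dt: float) -> PlasticityState:
    """Advance the detector P and readout W by one step of length ``dt``.

    dP/dt = k_p [Ca > theta_p] (1 - P) - P / tau_p
    dW/dt = k_w P (w_max - W)

    Both updates are exact for the indicator held constant over the step
    (W uses the closed-form integral of P over the step), so the result
    is independent of dt wherever the threshold crossings align with
    step boundaries, and W is exactly 1 for all time if Ca never crosses
    the threshold.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    drive = params.k_p_per_ms if state.above_threshold else 0.0
    rate = drive + 1.0 / params.tau_p_ms
    p_inf = drive / rate
    decay = math.exp(-dt * rate)
    p_integral = p_inf * dt + (state.P - p_inf) * (1.0 - decay) / rate
    P = p_inf + (state.P - p_inf) * decay
    W = params.w_max + (state.W - params.w_max) * math.exp(-params.k_w_per_ms * p_integral)
    return PlasticityState(ca=state.ca, P=P, W=W, theta_p=state.theta_p)


def kinetics_from_config(entry: dict) -> SynapseKinetics:
    """Build SynapseKinetics from a configuration block."""
    return SynapseKinetics(
        kind=entry["kind"],
        g_max=float(entry["g_max"]),
        E_rev=float(entry.get("E_rev", 0.0)),
        tau=entry.get("tau"),
        tau_rise=entry.get("tau_rise"),
        tau_decay=entry.get("tau_decay"),
        mg_mM=float(entry.get("mg_mM", 0.5)),
    )
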