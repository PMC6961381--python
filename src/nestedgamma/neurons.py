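"""Conductance-based neuron model definitions.

Four cell classes are provided. The CA1 pyramidal cell (PC) is a
three-compartment model (soma, apical dendrite, dendritic spine; the
spine attaches 100 um from the soma along the dendrite) carrying the full
eight-channel inventory: leak, transient Na+, delayed-rectifier K+,
A-type K+, L-type Ca2+, M-type K+, Ca-gated afterhyperpolarization K+,
and the hyperpolarization-activated cation current. The PV, SST and IN
interneurons are single-compartment models with exactly
{leak, Na, KDR, KA}; PV uses a fast-spiking parameter set and SST a
lower-gain set so that, at matched depolarizing steps, PV fires faster.

Channel kinetics are identified by ``gating_scheme`` (see ``_kernel``):
the Na/KDR rates follow Traub-Miles hippocampal kinetics, KA is a
Borg-Graham-style sigmoidal scheme, KM follows Yamada-Koch-Adams, the
AHP conductance is gated by the compartmental calcium pool, and H is a
sigmoidal hyperpolarization-activated scheme.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .config import merge_config

CHANNEL_IDS = ("leak", "Na", "KDR", "KA", "CaL", "KM", "AHP", "H")
PC_CHANNELS = set(CHANNEL_IDS)
INTERNEURON_CHANNELS = {"leak", "Na", "KDR", "KA"}
COMPARTMENT_ROLES = ("soma", "apical_dendrite", "spine")
CELL_TYPES = ("PC", "PV", "SST", "IN")

GATING_SCHEMES = {
    "leak": "ohmic",
    "Na": "rtm",
    "KDR": "rtm",
    "KA": "bg_a",
    "CaL": "hva_l",
    "KM": "yamada_m",
    "AHP": "ca_ahp",
    "H": "sigmoid_h",
}

# Fixed reversal potentials of the kinetic schemes (mV); leak uses the
# per-cell E_leak instead.
CHANNEL_EREV = {
    "Na": _kernel.E_NA,
    "KDR": _kernel.E_K,
    "KA": _kernel.E_K,
    "CaL": _kernel.E_CA,
    "KM": _kernel.E_K,
    "AHP": _kernel.E_K,
    "H": _kernel.E_H,
}


class ConfigurationError(ValueError):
    """Raised when a model configuration is missing or malformed."""


@dataclass
class ChannelSpec:
    channel_id: str
    g_max: float  # conductance density, mS/cm^2
    E_rev: float  # mV
    gating_scheme: str = ""

    def __post_init__(self) -> None:
        if self.channel_id not in CHANNEL_IDS:
            raise ConfigurationError(f"unknown channel class {self.channel_id!r}")
        if self.g_max < 0:
            raise ConfigurationError("g_max must be non-negative")
        if not math.isfinite(self.E_rev):
            raise ConfigurationError("E_rev must be finite")
        if not self.gating_scheme:
            self.gating_scheme = GATING_SCHEMES[self.channel_id]


@dataclass
class Compartment:
    role: str
    length_um: float
    diameter_um: float
    cm_uF_cm2: float = 1.0
    ra_ohm_cm: float = 150.0
    channels: list = field(default_factory=list)
    ca_pool: dict | None = None  # {"gain", "tau_ms", "base_uM"} or None

    def __post_init__(self) -> None:
        if self.role not in COMPARTMENT_ROLES:
            raise ConfigurationError(f"unknown compartment role {self.role!r}")
        if self.length_um <= 0 or self.diameter_um <= 0:
            raise ConfigurationError("compartment length and diameter must be positive")

    @property
    def area_cm2(self) -> float:
        # open cylinder
        return math.pi * self.length_um * self.diameter_um * 1e-8

    @property
    def capacitance_nF(self) -> float:
        return self.cm_uF_cm2 * self.area_cm2 * 1e3

    def g_abs_uS(self, channel_id: str) -> float:
        """Absolute conductance (uS) of a channel class, 0 if absent."""
        for ch in self.channels:
            if ch.channel_id == channel_id:
                return ch.g_max * self.area_cm2 * 1e3
        return 0.0

    def axial_half_resistance_MOhm(self) -> float:
        """Axial resistance of half this cylinder (MOhm)."""
        radius_cm = self.diameter_um / 2 * 1e-4
        length_cm = self.length_um / 2 * 1e-4
        return self.ra_ohm_cm * length_cm / (math.pi * radius_cm**2) * 1e-6


@dataclass
class NeuronModel:
    cell_type: str
    compartments: list
    E_leak: float
    spine_position_um: float | None = None
    spine_neck_MOhm: float | None = None

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ConfigurationError(f"unknown cell type {self.cell_type!r}")

    def channel_inventory(self) -> set:
        return {ch.channel_id for c in self.compartments for ch in c.channels}

    def compartment(self, role: str) -> Compartment:
        for c in self.compartments:
            if c.role == role:
                return c
        raise KeyError(role)

    @property
    def roles(self) -> list:
        return [c.role for c in self.compartments]

    def total_leak_uS(self) -> float:
        return sum(c.g_abs_uS("leak") for c in self.compartments)

    def total_capacitance_nF(self) -> float:
        return sum(c.capacitance_nF for c in self.compartments)


@dataclass
class NeuronState:
    """Per-compartment voltage, gating variables, Ca pools and time."""

    V: np.ndarray
    gating: dict  # name -> array over compartments, each in [0, 1]
    ca: np.ndarray
    t: float = 0.0


def _compartment_from_config(role: str, entry: dict) -> Compartment:
    channels = [
        ChannelSpec(cid, float(g), CHANNEL_EREV.get(cid, 0.0))
        for cid, g in entry["channels"].items()
    ]
    return Compartment(
        role=role,
        length_um=float(entry["length_um"]),
        diameter_um=float(entry["diameter_um"]),
        cm_uF_cm2=float(entry.get("cm_uF_cm2", 1.0)),
        ra_ohm_cm=float(entry.get("ra_ohm_cm", 150.0)),
        channels=channels,
        ca_pool=entry.get("ca_pool"),
    )


def build_pc(config: dict | None = None) -> NeuronModel:
    """Build the three-compartment CA1 pyramidal-cell model.

    The model must carry the full eight-channel inventory across its
    compartments; a missing class raises :class:`ConfigurationError`
    naming it. The spine attaches ``spine_position_um`` (default 100 um)
    from the soma along the apical dendrite, through a neck resistance.
    """
    cfg = merge_config(config)["cells"]["PC"]
    comps = []
    for role in COMPARTMENT_ROLES:
        if role not in cfg["compartments"]:
            raise ConfigurationError(f"PC model requires a {role!r} compartment")
        comps.append(_compartment_from_config(role, cfg["compartments"][role]))
    model = NeuronModel(
        cell_type="PC",
        compartments=comps,
        E_leak=float(cfg["E_leak"]),
        spine_position_um=float(cfg.get("spine_position_um", 100.0)),
        spine_neck_MOhm=float(cfg.get("spine_neck_MOhm", 500.0)),
    )
    missing = PC_CHANNELS - model.channel_inventory()
    if missing:
        raise ConfigurationError(
            f"PC model is missing required channel class(es): {sorted(missing)}"
        )
    dend = model.compartment("apical_dendrite")
    if model.spine_position_um > dend.length_um:
        raise ConfigurationError("spine attachment lies beyond the dendrite length")
    return model


def build_interneuron(kind: str, config: dict | None = None) -> NeuronModel:
    """Build a single-compartment interneuron model (PV, SST or IN)."""
    if kind not in ("PV", "SST", "IN"):
        raise ConfigurationError(f"unknown interneuron kind {kind!r}")
    cfg = merge_config(config)["cells"][kind]
    entry = cfg["compartments"]["soma"]
    comp = _compartment_from_config("soma", entry)
    inventory = {ch.channel_id for ch in comp.channels}
    if inventory != INTERNEURON_CHANNELS:
        raise ConfigurationError(
            f"{kind} model must have exactly channels {sorted(INTERNEURON_CHANNELS)}, "
            f"got {sorted(inventory)}"
        )
    return NeuronModel(cell_type=kind, compartments=[comp], E_leak=float(cfg["E_leak"]))


def build_neuron(kind: str, config: dict | None = None) -> NeuronModel:
    return build_pc(config) if kind == "PC" else build_interneuron(kind, config)
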