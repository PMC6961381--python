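"""Default parameter set and structured-text (YAML) configuration.

The defaults below are the package's reference parameter set: cell
geometries, channel conductance densities, synaptic conductances and
plasticity constants calibrated so that the default microcircuit
reproduces the behaviours documented in ``docs/methods.md`` (fast-spiking
PV vs lower-gain SST firing profiles, theta-paced gamma spiking of the
pyramidal cell, and calcium-threshold potentiation gated by
disinhibition). Any entry can be overridden from a YAML file with the
same nesting.
"""
from __future__ import annotations

import copy
from typing import Any, Mapping

import yaml

# Conductance densities in mS/cm^2; geometry in um; Ca pool gains in
# uM/(nA*ms) (lumped volume + buffering factor), taus in ms.
DEFAULT_CONFIG: dict = {
    "cells": {
        "PC": {
            "E_leak": -65.0,
            "spine_position_um": 100.0,  # attachment point along the apical dendrite
            "spine_neck_MOhm": 100.0,
            "compartments": {
                "soma": {
                    "length_um": 30.0, "diameter_um": 30.0,
                    "cm_uF_cm2": 1.0, "ra_ohm_cm": 150.0,
                    "channels": {"leak": 0.06, "Na": 30.0, "KDR": 25.0, "KA": 0.5,
                                 "CaL": 0.3, "KM": 0.05, "AHP": 0.5, "H": 0.05},
                    "ca_pool": {"gain": 0.3, "tau_ms": 150.0, "base_uM": 0.05},
                },
                "apical_dendrite": {
                    "length_um": 400.0, "diameter_um": 3.2,
                    "cm_uF_cm2": 1.0, "ra_ohm_cm": 150.0,
                    "channels": {"leak": 0.06, "Na": 3.0, "KDR": 3.0, "KA": 0.5,
                                 "KM": 0.05, "H": 0.05},
                },
                "spine": {
                    "length_um": 1.0, "diameter_um": 1.0,
                    "cm_uF_cm2": 1.0, "ra_ohm_cm": 150.0,
                    "channels": {"leak": 0.05, "CaL": 20.0},
                },
            },
        },
        "PV": {  # fast-spiking profile: leaky, strong Na/KDR, steep f-I
            "E_leak": -65.0,
            "compartments": {
                "soma": {
                    "length_um": 25.0, "diameter_um": 25.0,
                    "cm_uF_cm2": 1.0, "ra_ohm_cm": 150.0,
                    "channels": {"leak": 0.6, "Na": 100.0, "KDR": 80.0, "KA": 0.5},
                },
            },
        },
        "SST": {  # lower-gain, tonically active profile (low-threshold-spiking)
            "E_leak": -54.0,
            "compartments": {
                "soma": {
                    "length_um": 40.0, "diameter_um": 40.0,
                    "cm_uF_cm2": 1.0, "ra_ohm_cm": 150.0,
                    "channels": {"leak": 0.2, "Na": 60.0, "KDR": 50.0, "KA": 5.0},
                },
            },
        },
        "IN": {  # generic fast-spiking feedforward interneuron
            "E_leak": -65.0,
            "compartments": {
                "soma": {
                    "length_um": 25.0, "diameter_um": 25.0,
                    "cm_uF_cm2": 1.0, "ra_ohm_cm": 150.0,
                    "channels": {"leak": 0.4, "Na": 100.0, "KDR": 80.0, "KA": 1.0},
                },
            },
        },
    },
    # g_max in uS; taus in ms; delays in ms
    "synapses": {
        # printed AMPA conductance reads 0.3 pS; 0.3 nS gives the few-mV
        # somatic EPSP the recordings show, so nS is taken as the unit
        "CA3->spine.AMPA": {"kind": "ampa_single_exp", "g_max": 0.0004, "E_rev": 0.0,
                            "tau": 7.0, "delay_ms": 1.0, "plastic": True},
        "CA3->spine.NMDA": {"kind": "nmda_mg_block", "g_max": 0.0012, "E_rev": 0.0,
                            "tau_rise": 4.0, "tau_decay": 21.0, "mg_mM": 0.5,
                            "delay_ms": 1.0},
        "CA3->IN": {"kind": "biexp", "g_max": 0.004, "E_rev": 0.0,
                    "tau_rise": 3.0, "tau_decay": 15.0, "delay_ms": 1.0},
        "PC->PV": {"kind": "biexp", "g_max": 0.0012, "E_rev": 0.0,
                   "tau_rise": 3.0, "tau_decay": 15.0, "delay_ms": 1.0},
        "PV->PC": {"kind": "biexp", "g_max": 0.0004, "E_rev": -75.0,
                   "tau_rise": 3.0, "tau_decay": 40.0, "delay_ms": 1.0},
        "PC->SST": {"kind": "biexp", "g_max": 0.0012, "E_rev": 0.0,
                    "tau_rise": 3.0, "tau_decay": 15.0, "delay_ms": 1.0},
        "SST->IN": {"kind": "biexp", "g_max": 0.03, "E_rev": -75.0,
                    "tau_rise": 3.0, "tau_decay": 40.0, "delay_ms": 1.0},
        "IN->PC": {"kind": "biexp", "g_max": 0.03, "E_rev": -75.0,
                   "tau_rise": 3.0, "tau_decay": 40.0, "delay_ms": 1.0},
    },
    # spine calcium / potentiation detector / weight readout
    "plasticity": {
        "theta_p_uM": 4.0,          # potentiation threshold on spine [Ca2+]
        "nmda_ca_fraction": 0.1,    # fraction of NMDA conductance carrying Ca
        "spine_volume_um3": 0.5,    # effective diffusion volume of the spine head
        "buffer_capacity": 110.0,   # endogenous buffer ratio (bound:free)
        "tau_ca_ms": 20.0,
        "ca_baseline_uM": 0.05,
        "k_p_per_ms": 0.5,          # detector drive rate while Ca > theta_p
        "tau_p_ms": 50.0,           # detector decay
        "k_w_per_ms": 0.0025,       # readout rate (dW/dt = k_w * P * (w_max - W))
        "w_max": 2.0,
    },
    "protocol": {
        "theta_freq_hz": 5.0,
        "theta_amp_pA": 20.0,
        "step_amp_pA": 15.0,
        "pairing_dt_ms": 10.0,
        "pairing_reps": 5,
        "pairing_rate_hz": 5.0,
        "pairing_start_cycle": 2,
        "noise_sigma_pA": 50.0,
        "noise_all_cells": True,    # False -> PC soma only
        "duration_ms": 1700.0,
    },
    "simulation": {
        "dt_internal_ms": 0.025,
        "dt_output_ms": 0.1,        # 10 kHz output sampling
        "spike_threshold_mV": 0.0,
        "refractory_ms": 2.0,
    },
}


def _deep_merge(base: dict, override: Mapping[str, Any]) -> dict:
    """Nested merge; an explicit None value deletes the entry (e.g. to
    drop a channel class from a compartment)."""
    out = copy.deepcopy(base)
    for key, val in override.items():
        if val is None:
            out.pop(key, None)
        elif key in out and isinstance(out[key], dict) and isinstance(val, Mapping):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def merge_config(override: Mapping[str, Any] | None) -> dict:
    """Default configuration with ``override`` merged on top (nested)."""
    if override is None:
        return default_config()
    return _deep_merge(DEFAULT_CONFIG, override)


def load_config(path) -> dict:
    """Read a YAML override file and merge it over the defaults."""
    with open(path) as fh:
        override = yaml.safe_load(fh) or {}
    if not isinstance(override, dict):
        raise ValueError("configuration file must contain a mapping")
    return merge_config(override)


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
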