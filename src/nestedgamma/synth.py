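"""Seeded synthetic-signal generators with machine-readable ground truth.

Every generator returns ``(Trace, meta)`` where ``meta`` records the
parameters and the analytically known quantities (coupling depth,
preferred phase, event amplitudes, total charge, R/tau, ...) so analysis
code can be validated against a known answer. All randomness comes from
``numpy.random.default_rng(seed)``; identical seeds give identical
output bit for bit.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .synapses import SynapseKinetics
from .trace import Trace


@dataclass
class CouplingSpec:
    """Theta-nested gamma construction parameters.

    The gamma component is amplitude-modulated by a raised cosine of
    theta phase: envelope = 1 - c + c (1 + cos(theta_phase - phi)) / 2,
    so coupling_depth c = 0 gives an exactly constant envelope (no
    phase-amplitude coupling) and the modulation index grows
    monotonically with c; the envelope is maximal at theta phase
    ``preferred_phase``.
    """

    theta_freq: float = 5.0        # Hz
    gamma_freq: float = 40.0       # Hz
    coupling_depth: float = 1.0    # in [0, 1]
    preferred_phase: float = 0.0   # degrees, 0 = theta peak
    noise_sd: float = 0.0          # a.u.
    duration: float = 60.0         # s
    fs: float = 1000.0             # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling_depth <= 1.0:
            raise ValueError("coupling_depth must lie in [0, 1]")
        if self.theta_freq <= 0 or self.gamma_freq <= self.theta_freq:
            raise ValueError("need 0 < theta_freq < gamma_freq")


def gen_theta_gamma(spec: CouplingSpec):
    """Theta-nested gamma trace: sin theta + modulated sin gamma + noise.

    Theta phase is measured with 0 deg at the theta peak, matching the
    analysis convention, so the gamma envelope peaks where the
    comodulogram should report ``preferred_phase``.
    """
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    theta_phase = 2 * math.pi * spec.theta_freq * t - math.pi / 2  # 0 at peak of sin
    c = spec.coupling_depth
    phi = math.radians(spec.preferred_phase)
    env = 1.0 - c + c * (1.0 + np.cos(theta_phase - phi)) / 2.0
    x = np.sin(2 * math.pi * spec.theta_freq * t) + env * np.sin(2 * math.pi * spec.gamma_freq * t)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        x = x + rng.normal(0.0, spec.noise_sd, n)
    meta = asdict(spec)
    meta["envelope_min"] = float(env.min())
    meta["envelope_max"] = float(env.max())
    return Trace(x, dt=1000.0 / spec.fs, t0=0.0, unit="a.u."), meta


def gen_vonmises_phases(mu_deg: float, kappa: float, n: int,
                        seed: int = 0) -> np.ndarray:
    """``n`` von Mises phase draws in degrees (kappa = 0 gives uniform)."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    draws = rng.vonmises(math.radians(mu_deg), kappa, n)
    return (np.degrees(draws) + 180.0) % 360.0 - 180.0


def gen_psc_train(n_events: int = 10, interval: float = 20.0,
                  kinetics: SynapseKinetics | None = None,
                  per_event_scaling=None, amplitude_pA: float = 100.0,
                  noise_sd: float = 0.0, seed: int = 0,
                  fs: float = 10000.0, pre_ms: float = 20.0,
                  post_ms: float = 150.0):
    """Superposed double-exponential PSC train (positive-going, pA).

    Mirrors the 50 Hz, 10-pulse stimulation geometry: events every
    ``interval`` ms, each a peak-normalized biexponential scaled by
    ``amplitude_pA * per_event_scaling[k]``. The meta dict carries the
    event times, the programmed amplitudes and the analytic total charge
    (sum of scal * amp * norm * (tau_d - tau_r), in pC).
    """
    if kinetics is None:
        kinetics = SynapseKinetics("biexp", g_max=1.0, tau_rise=3.0, tau_decay=15.0)
    if per_event_scaling is None:
        per_event_scaling = np.ones(n_events)
    scal = np.asarray(per_event_scaling, dtype=float)
    if scal.size != n_events:
        raise ValueError("per_event_scaling must have one entry per event")
    dt = 1000.0 / fs
    events = pre_ms + interval * np.arange(n_events)
    duration = pre_ms + interval * max(n_events - 1, 0) + post_ms
    n = int(round(duration / dt)) + 1
    t = dt * np.arange(n)
    x = np.zeros(n)
    norm = kinetics.biexp_norm
    for ev, s in zip(events, scal):
        rel = t - ev
        m = rel >= 0
        x[m] += s * amplitude_pA * norm * (
            np.exp(-rel[m] / kinetics.tau_decay) - np.exp(-rel[m] / kinetics.tau_rise))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd, n)
    charge_pC = float(scal.sum() * amplitude_pA * norm
                      * (kinetics.tau_decay - kinetics.tau_rise) / 1000.0)
    meta = {
        "event_times_ms": events.tolist(),
        "amplitudes_pA": (amplitude_pA * scal).tolist(),
        "tau_rise_ms": kinetics.tau_rise,
        "tau_decay_ms": kinetics.tau_decay,
        "total_charge_pC": charge_pC,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return Trace(x, dt=dt, t0=0.0, unit="pA"), meta


def gen_passive_step(R_MOhm: float = 200.0, tau_ms: float = 20.0,
                     I_pA: float = 5.0, duration: float = 100.0,
                     V_rest: float = -65.0, noise_sd: float = 0.0,
                     seed: int = 0, fs: float = 10000.0):
    """Passive membrane response to a negative current step.

    V(t) = V_rest - I R (1 - e^(-t/tau)) + noise, in mV, with the step
    applied at t = 0 (``I_pA`` is the magnitude of the hyperpolarizing
    step; R in MOhm, so I R is in uV and converted to mV).
    """
    if R_MOhm <= 0 or tau_ms <= 0 or duration <= 0:
        raise ValueError("R, tau and duration must be positive")
    dt = 1000.0 / fs
    n = int(round(duration / dt)) + 1
    t = dt * np.arange(n)
    v = V_rest - I_pA * R_MOhm * 1e-3 * (1.0 - np.exp(-t / tau_ms))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, n)
    meta = {"R_MOhm": R_MOhm, "tau_ms": tau_ms, "I_pA": I_pA,
            "V_rest": V_rest, "V_steady": float(V_rest - I_pA * R_MOhm * 1e-3),
            "noise_sd": noise_sd, "seed": seed}
    return Trace(v, dt=dt, t0=0.0, unit="mV"), meta
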