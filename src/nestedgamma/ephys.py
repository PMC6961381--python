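"""Intracellular electrophysiology metrics.

Implements the standard current/voltage-clamp quantifications used on
slice recordings, applied here to simulated or synthetic traces: input
resistance from a small hyperpolarizing step, membrane time constant by
exponential fit (V = V0 + A e^(-t/tau)), EPSP rising slope by linear fit
between the 20% and 80% amplitude crossings, baseline-normalized
plasticity time courses (percent of the 10-min baseline mean, summarized
over minutes 25-30 after induction), paired-pulse ratio (2nd/1st
amplitude, with exponential-extrapolation overlap correction on trains),
total charge by integrating baseline-subtracted current, stimulus-
response curves with half-maximal intensity, and the disinhibition
subtraction (isolated IPSC during pairing = paired - alveus-alone;
disinhibition = control IPSC - isolated IPSC).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, interpolate

from .trace import Trace


@dataclass
class PassiveFit:
    """Exponential fit V = V_steady + A e^(-t/tau) of a step response."""

    tau: float                 # ms
    V0: float                  # initial voltage = V_steady + A (mV)
    V_steady: float            # fitted asymptote (mV)
    A: float                   # amplitude constant (mV)
    residual_rms: float        # mV
    R_in: float | None = None  # MOhm, set when the step current is known


@dataclass
class PlasticityTimecourse:
    timestamps_min: np.ndarray
    normalized_pct: np.ndarray   # percent of baseline mean
    summary_pct: float           # mean over the summary window
    pathway: str = "test"


@dataclass
class SRCurve:
    intensities: np.ndarray
    responses: np.ndarray
    half_max_intensity: float
    max_response: float


@dataclass
class DisinhibitionResult:
    isolated_pA: float       # SC-evoked IPSC during pairing
    disinhibition_pA: float  # reduction relative to SC stimulation alone


def input_resistance(V0: float, V_steady: float, I_pA: float) -> float:
    """(V0 - V_steady) / I in MOhm (mV / pA = GOhm, converted)."""
    if I_pA == 0:
        raise ValueError("step current must be non-zero")
    return (V0 - V_steady) / I_pA * 1000.0


def membrane_tau(trace: Trace, I_pA: float | None = None) -> PassiveFit:
    """Fit the relaxation V = V_steady + A e^(-t/tau) to a step response.

    ``trace`` should start at the step onset. When the step current is
    given, the input resistance (V0 - V_steady)/I is filled in as well.
    """
    v = trace.values
    t = trace.times - trace.t0
    if np.ptp(v) < 1e-9:
        raise ValueError("flat trace: no relaxation to fit (A = 0)")
    A0 = v[0] - v[-1]
    tau0 = max(trace.duration / 5.0, trace.dt)

    def model(tt, vs, a, tau):
        return vs + a * np.exp(-tt / tau)

    try:
        popt, _ = optimize.curve_fit(model, t, v, p0=[v[-1], A0, tau0],
                                     maxfev=10000)
    except RuntimeError as err:
        raise ValueError(f"exponential fit did not converge: {err}") from err
    vs, a, tau = popt
    if tau <= 0:
        raise ValueError("exponential fit returned non-positive tau")
    resid = float(np.sqrt(np.mean((model(t, *popt) - v) ** 2)))
    v0 = vs + a
    r_in = input_resistance(v0, vs, I_pA) if I_pA else None
    return PassiveFit(tau=float(tau), V0=float(v0), V_steady=float(vs),
                      A=float(a), residual_rms=resid, R_in=r_in)


def _crossing_time(t: np.ndarray, v: np.ndarray, level: float) -> float:
    """First upward crossing of ``level``, linearly interpolated."""
    above = v >= level
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if idx.size == 0:
        if above[0]:
            return t[0]
        raise ValueError("level not crossed on the rising limb")
    i = idx[0]
    frac = (level - v[i]) / (v[i + 1] - v[i])
    return t[i] + frac * (t[i + 1] - t[i])


def epsp_slope(trace: Trace, baseline_ms: float = 2.0) -> float:
    """Rising slope (mV/ms) by linear fit between the 20% and 80%
    crossings of the EPSP peak amplitude above baseline."""
    v = trace.values
    t = trace.times
    nb = max(1, int(round(baseline_ms / trace.dt)))
    base = float(v[:nb].mean())
    peak_idx = int(np.argmax(v))
    peak = v[peak_idx]
    if peak <= base + 1e-9:
        raise ValueError("no positive peak above baseline")
    rise_t, rise_v = t[:peak_idx + 1], v[:peak_idx + 1]
    amp = peak - base
    t20 = _crossing_time(rise_t, rise_v, base + 0.2 * amp)
    t80 = _crossing_time(rise_t, rise_v, base + 0.8 * amp)
    sel = (t >= t20) & (t <= t80)
    tt = t[sel]
    vv = v[sel]
    # include the interpolated endpoints so very fast rises still have
    # two points to fit
    tt = np.concatenate(([t20], tt, [t80]))
    vv = np.concatenate(([base + 0.2 * amp], vv, [base + 0.8 * amp]))
    slope, _ = np.polyfit(tt, vv, 1)
    return float(slope)


def normalize_timecourse(timestamps_min, slopes, induction_min: float = 10.0,
                         baseline_window_min: float = 10.0,
                         summary_window_min: tuple = (25.0, 30.0),
                         pathway: str = "test") -> PlasticityTimecourse:
    """Express slopes as percent of the baseline mean.

    Baseline = the ``baseline_window_min`` minutes before ``induction_min``;
    the summary is the mean over ``summary_window_min`` (minutes after
    induction).
    """
    t = np.asarray(timestamps_min, dtype=float)
    s = np.asarray(slopes, dtype=float)
    if t.shape != s.shape:
        raise ValueError("timestamps and slopes must be aligned")
    base_sel = (t >= induction_min - baseline_window_min) & (t < induction_min)
    if not np.any(base_sel):
        raise ValueError("no points in the baseline window")
    base = s[base_sel].mean()
    if base == 0:
        raise ValueError("baseline mean slope is zero")
    norm = 100.0 * s / base
    lo, hi = (induction_min + summary_window_min[0],
              induction_min + summary_window_min[1])
    summ_sel = (t >= lo) & (t <= hi)
    if not np.any(summ_sel):
        raise ValueError("no points in the summary window")
    return PlasticityTimecourse(timestamps_min=t, normalized_pct=norm,
                                summary_pct=float(norm[summ_sel].mean()),
                                pathway=pathway)


def ppr(amplitudes) -> float:
    """Paired-pulse ratio: second amplitude / first amplitude."""
    amps = np.asarray(amplitudes, dtype=float)
    if amps.size < 2:
        raise ValueError("ppr requires at least two amplitudes")
    if amps[0] == 0:
        raise ValueError("first amplitude is zero")
    return float(amps[1] / amps[0])


def train_amplitudes(trace: Trace, event_times, tau_decay: float,
                     window_ms: float = 15.0) -> np.ndarray:
    """Per-event amplitudes of an overlapping PSC train.

    For each event the residual of the preceding responses is estimated
    by extrapolating the value just before the event with the decay
    constant ``tau_decay`` and subtracted from the post-event peak.
    Responses are assumed positive-going (take the magnitude upstream).
    """
    events = np.asarray(event_times, dtype=float)
    v = trace.values
    t = trace.times
    amps = []
    for k, ev in enumerate(events):
        i_ev = int(round((ev - trace.t0) / trace.dt))
        i_end = min(len(v), int(round((ev + window_ms - trace.t0) / trace.dt)))
        if i_ev < 0 or i_ev >= len(v) or i_end <= i_ev:
            raise ValueError("event outside the trace span")
        pre = v[max(0, i_ev - 1)]
        seg_t = t[i_ev:i_end]
        residual = pre * np.exp(-(seg_t - t[max(0, i_ev - 1)]) / tau_decay)
        corrected = v[i_ev:i_end] - residual
        amps.append(float(corrected.max()))
    return np.asarray(amps)


def total_charge(trace: Trace, window: tuple, baseline_ms: float = 5.0) -> float:
    """Charge in pC: time integral of the baseline-subtracted current
    (pA) over ``window`` (ms). Baseline = mean of the ``baseline_ms``
    preceding the window."""
    lo, hi = window
    seg = trace.crop(lo, hi)
    b0 = max(trace.t0, lo - baseline_ms)
    if b0 < lo:
        base = float(trace.crop(b0, lo).values.mean())
    else:
        base = 0.0
    return float(np.trapezoid(seg.values - base, dx=trace.dt) / 1000.0)


def sr_curve(intensities, responses) -> SRCurve:
    """Monotone (PCHIP) interpolation of a stimulus-response curve and
    the intensity giving 50% of the maximal response."""
    x = np.asarray(intensities, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size < 3:
        raise ValueError("sr_curve requires at least three points")
    if np.any(y < 0):
        raise ValueError("responses must be non-negative")
    order = np.argsort(x)
    x, y = x[order], y[order]
    ymax = y.max()
    if ymax <= 0:
        raise ValueError("all responses are zero")
    half = ymax / 2.0
    f = interpolate.PchipInterpolator(x, y)
    grid = np.linspace(x[0], x[-1], 2048)
    vals = f(grid)
    above = vals >= half
    if not above.any() or above[0]:
        raise ValueError("curve does not cross half-maximum from below")
    i = int(np.flatnonzero(~above[:-1] & above[1:])[0])
    frac = (half - vals[i]) / (vals[i + 1] - vals[i])
    x_half = grid[i] + frac * (grid[i + 1] - grid[i])
    return SRCurve(intensities=x, responses=y,
                   half_max_intensity=float(x_half), max_response=float(ymax))


def disinhibition(ipsc_sc_alone: float, ipsc_paired: float,
                  ipsc_alveus_alone: float) -> DisinhibitionResult:
    """Disinhibition by subtraction.

    The SC-evoked IPSC during pairing is isolated by subtracting the
    IPSC evoked by alveus stimulation alone from the paired IPSC;
    disinhibition is the difference between the SC-alone IPSC and that
    isolated value. All amplitudes on a common (positive) convention.
    """
    isolated = ipsc_paired - ipsc_alveus_alone
    return DisinhibitionResult(isolated_pA=float(isolated),
                               disinhibition_pA=float(ipsc_sc_alone - isolated))
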