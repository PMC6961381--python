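"""Oscillation analysis: spectra, phase-amplitude coupling, circular stats.

The toolkit mirrors a standard slice-LFP workflow, applied here to
simulated somatic voltages and synthetic signals: zero-phase band-pass
filtering (gamma band 20-120 Hz by default), Welch power spectra over
1-s segments, short-time Fourier spectrograms (100 ms window, 1 ms
step), Hilbert instantaneous phase with zero phase at the waveform peak,
theta-phase/gamma-amplitude comodulograms (20 phase bins of 18 deg), the
Kullback-Leibler modulation index (18 bins of 20 deg, normalized by
log N so 0 = no coupling and 1 = all amplitude in one bin), spike-phase
histograms with resultant vectors, and the Watson-Williams multi-sample
circular test.

Phase convention everywhere: degrees in [-180, 180), 0 deg at the peak
of the reference oscillation (the Hilbert analytic-signal angle has
exactly this property for a narrowband signal).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .trace import Trace, SpikeTrain


@dataclass
class SpectrumResult:
    frequencies: np.ndarray
    psd: np.ndarray
    peak_power: float
    peak_frequency: float


@dataclass
class Comodulogram:
    phase_bin_edges: np.ndarray    # degrees, tiles [-180, 180]
    gamma_frequencies: np.ndarray  # Hz
    amplitude: np.ndarray          # (n_gamma, n_phase_bins), mean amplitude

    @property
    def phase_bin_centers(self) -> np.ndarray:
        return 0.5 * (self.phase_bin_edges[:-1] + self.phase_bin_edges[1:])


@dataclass
class PhaseStats:
    bin_edges: np.ndarray      # degrees
    probability: np.ndarray    # sums to 1
    vector_length: float       # in [0, 1]
    vector_phase: float        # degrees in [-180, 180)
    n_events: int


def _wrap_deg(ph: np.ndarray) -> np.ndarray:
    return (np.asarray(ph) + 180.0) % 360.0 - 180.0


def bandpass(trace: Trace, lo: float = 20.0, hi: float = 120.0,
             order: int = 4) -> Trace:
    """Zero-phase Butterworth band-pass (applied forward and backward)."""
    nyq = trace.fs / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band ({lo}, {hi}) Hz must lie inside (0, {nyq}) Hz")
    sos = signal.butter(order, [lo / nyq, hi / nyq], btype="band", output="sos")
    out = signal.sosfiltfilt(sos, trace.values)
    return Trace(out, trace.dt, trace.t0, trace.unit)


def downsample(trace: Trace, factor: int) -> Trace:
    """Anti-aliased decimation by an integer factor (zero-phase)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return trace
    out = signal.decimate(trace.values, factor, zero_phase=True)
    return Trace(out, trace.dt * factor, trace.t0, trace.unit)


def welch_psd(trace: Trace, band: tuple | None = None,
              segment_s: float = 1.0) -> SpectrumResult:
    """Welch PSD over Hann-tapered segments of ``segment_s`` seconds with
    50% overlap; the peak is reported within ``band`` (Hz), ties resolved
    to the lowest frequency."""
    nperseg = int(round(segment_s * trace.fs))
    if len(trace) < nperseg:
        raise ValueError("trace shorter than one Welch segment")
    f, p = signal.welch(trace.values, fs=trace.fs, window="hann",
                        nperseg=nperseg, noverlap=nperseg // 2)
    if band is None:
        sel = f > 0
    else:
        sel = (f >= band[0]) & (f <= band[1])
        if not np.any(sel):
            raise ValueError("query band contains no frequency bin")
    i = np.argmax(p[sel])
    return SpectrumResult(frequencies=f, psd=p,
                          peak_power=float(p[sel][i]),
                          peak_frequency=float(f[sel][i]))


def spectrogram(trace: Trace, window_ms: float = 100.0, step_ms: float = 1.0):
    """Short-time Fourier magnitude with the given window and step.

    Returns (times_ms, frequencies_Hz, magnitude) with magnitude shaped
    (n_freq, n_times).
    """
    nperseg = int(round(window_ms / trace.dt))
    step = max(1, int(round(step_ms / trace.dt)))
    if len(trace) <= nperseg:
        raise ValueError("trace shorter than one spectrogram window")
    f, t, z = signal.spectrogram(trace.values, fs=trace.fs, window="hann",
                                 nperseg=nperseg, noverlap=nperseg - step,
                                 mode="magnitude")
    return trace.t0 + t * 1000.0, f, z


def instantaneous_phase(trace: Trace, unwrap: bool = False) -> np.ndarray:
    """Hilbert analytic-signal phase in degrees; 0 deg at waveform peaks.

    With ``unwrap=True`` the phase increases monotonically by 360 deg per
    cycle instead of wrapping to [-180, 180)."""
    analytic = signal.hilbert(trace.values)
    ph = np.angle(analytic)
    if unwrap:
        return np.degrees(np.unwrap(ph))
    return _wrap_deg(np.degrees(ph))


def envelope(trace: Trace) -> np.ndarray:
    """Hilbert amplitude envelope of a band-limited trace."""
    return np.abs(signal.hilbert(trace.values))


def modulation_index(theta_phase: np.ndarray, gamma_amplitude: np.ndarray,
                     n_bins: int = 18) -> float:
    """Normalized Kullback-Leibler modulation index.

    The mean gamma amplitude per theta-phase bin (``n_bins`` bins tiling
    360 deg; default 18 bins of 20 deg) is normalized by the summed bin
    amplitudes, and MI = KL(P || uniform) / log(n_bins), in [0, 1]:
    0 for amplitude independent of phase, 1 when all amplitude falls in a
    single bin.
    """
    ph = np.asarray(theta_phase, dtype=float)
    amp = np.asarray(gamma_amplitude, dtype=float)
    if ph.shape != amp.shape:
        raise ValueError("phase and amplitude series must be aligned")
    if not np.any(amp > 0):
        raise ValueError("amplitude is identically zero; distribution undefined")
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    idx = np.clip(np.digitize(_wrap_deg(ph), edges) - 1, 0, n_bins - 1)
    mean_amp = np.zeros(n_bins)
    for b in range(n_bins):
        sel = idx == b
        if np.any(sel):
            mean_amp[b] = amp[sel].mean()
    p = mean_amp / mean_amp.sum()
    nz = p > 0
    kl = float(np.sum(p[nz] * np.log(p[nz] * n_bins)))
    return kl / math.log(n_bins)


def comodulogram(raw_trace: Trace, theta_band: tuple = (3.0, 8.0),
                 gamma_frequencies=None, gamma_bandwidth: float = 10.0,
                 n_phase_bins: int = 20) -> Comodulogram:
    """Gamma amplitude as a function of theta phase, per gamma frequency.

    Theta phase comes from the Hilbert transform of the theta-band
    filtered trace (zero phase at the theta peak) and is binned into
    ``n_phase_bins`` bins (default 20 bins of 18 deg). At each gamma
    frequency the trace is band-passed +/- half the bandwidth and the
    mean Hilbert amplitude per theta bin forms one row.
    """
    if gamma_frequencies is None:
        gamma_frequencies = np.arange(20.0, 121.0, 5.0)
    gamma_frequencies = np.asarray(gamma_frequencies, dtype=float)
    theta = bandpass(raw_trace, theta_band[0], theta_band[1])
    ph = instantaneous_phase(theta)
    # drop two slowest-theta periods at each end: filter and Hilbert edge
    # transients otherwise bleed into the phase bins
    trim = int(round(2000.0 / theta_band[0] / raw_trace.dt))
    keep = slice(trim, max(trim + 1, len(raw_trace) - trim))
    edges = np.linspace(-180.0, 180.0, n_phase_bins + 1)
    idx = np.clip(np.digitize(ph[keep], edges) - 1, 0, n_phase_bins - 1)
    amp = np.zeros((gamma_frequencies.size, n_phase_bins))
    half = gamma_bandwidth / 2.0
    for gi, f0 in enumerate(gamma_frequencies):
        g = bandpass(raw_trace, f0 - half, f0 + half)
        env = envelope(g)[keep]
        for b in range(n_phase_bins):
            sel = idx == b
            if np.any(sel):
                amp[gi, b] = env[sel].mean()
    return Comodulogram(phase_bin_edges=edges, gamma_frequencies=gamma_frequencies,
                        amplitude=amp)


def resultant_vector(phases_deg) -> tuple:
    """Mean resultant length (in [0, 1]) and circular mean (degrees)."""
    ph = np.asarray(phases_deg, dtype=float)
    if ph.size == 0:
        raise ValueError("resultant_vector requires at least one phase")
    z = np.exp(1j * np.radians(ph)).mean()
    return float(np.abs(z)), float(_wrap_deg(np.degrees(np.angle(z))))


def phase_histogram(event_times, phase_trace: Trace, n_bins: int = 20) -> PhaseStats:
    """Event probability per phase bin plus the resultant vector.

    Event phases are read from ``phase_trace`` (a wrapped phase series in
    degrees, e.g. from :func:`instantaneous_phase` wrapped into a Trace)
    by interpolating the unwrapped phase at the event times.
    """
    times = np.asarray(event_times, dtype=float)
    if times.size == 0:
        raise ValueError("phase_histogram requires at least one event")
    t0, t1 = phase_trace.t0, phase_trace.t0 + phase_trace.duration
    if times.min() < t0 or times.max() > t1:
        raise ValueError("events must lie within the span of the phase trace")
    unwrapped = np.degrees(np.unwrap(np.radians(phase_trace.values)))
    ph = _wrap_deg(np.interp(times, phase_trace.times, unwrapped))
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    counts, _ = np.histogram(ph, bins=edges)
    length, mean_ph = resultant_vector(ph)
    return PhaseStats(bin_edges=edges, probability=counts / counts.sum(),
                      vector_length=length, vector_phase=mean_ph,
                      n_events=times.size)


def _kappa_ml(r: float) -> float:
    # Fisher (1993) approximation to the ML concentration estimate
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r**3 - 4 * r**2 + 3 * r)


def watson_williams(*groups) -> tuple:
    """Watson-Williams multi-sample test for equal circular means.

    Accepts two or more groups of phases in degrees (or a single list of
    groups). Returns (F, p); the F statistic carries the standard
    1 + 3/(8 kappa) correction with kappa estimated from the pooled
    within-group resultant.
    """
    if len(groups) == 1 and not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("watson_williams requires at least two groups")
    k = len(groups)
    ns, Rs, zsum = [], [], 0.0
    for g in groups:
        g = np.asarray(g, dtype=float)
        if g.size < 2:
            raise ValueError("each group needs at least two phases")
        z = np.exp(1j * np.radians(g))
        ns.append(g.size)
        Rs.append(np.abs(z.sum()))
        zsum += z.sum()
    N = int(np.sum(ns))
    sumR = float(np.sum(Rs))
    R = float(np.abs(zsum))
    rw = sumR / N
    if math.isclose(sumR, N, rel_tol=0, abs_tol=1e-12):
        raise ValueError("degenerate groups: all phases identical")
    kappa = _kappa_ml(rw)
    correction = 1 + 3 / (8 * kappa)
    F = correction * ((N - k) * (sumR - R)) / ((k - 1) * (N - sumR))
    F = max(F, 0.0)
    p = float(stats.f.sf(F, k - 1, N - k))
    return float(F), p


def spikes_per_theta_cycle(spikes, cycle_boundaries) -> np.ndarray:
    """Spike counts per theta cycle given strictly increasing boundaries."""
    bounds = np.asarray(cycle_boundaries, dtype=float)
    if bounds.size < 2 or np.any(np.diff(bounds) <= 0):
        raise ValueError("cycle boundaries must be strictly increasing, length >= 2")
    times = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    counts, _ = np.histogram(times, bins=bounds)
    return counts


def relative_gamma_phase(pv_spikes, pc_spikes) -> tuple:
    """Phases of PV spikes relative to the PC spike rhythm.

    Each PC inter-spike interval is treated as one gamma period with the
    PC spikes at the trough (+/-180 deg under the zero-at-peak
    convention): phase = -180 + 360 (t_PV - t_PC,k) / (t_PC,k+1 - t_PC,k).
    PV spikes outside the PC spike span are dropped; their count is
    returned alongside the phases.
    """
    pv = pv_spikes.times if isinstance(pv_spikes, SpikeTrain) else np.asarray(pv_spikes, float)
    pc = pc_spikes.times if isinstance(pc_spikes, SpikeTrain) else np.asarray(pc_spikes, float)
    if pc.size < 2:
        raise ValueError("relative_gamma_phase requires at least two PC spikes")
    inside = (pv >= pc[0]) & (pv < pc[-1])
    dropped = int(np.count_nonzero(~inside))
    pv_in = pv[inside]
    idx = np.searchsorted(pc, pv_in, side="right") - 1
    frac = (pv_in - pc[idx]) / (pc[idx + 1] - pc[idx])
    return _wrap_deg(-180.0 + 360.0 * frac), dropped
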