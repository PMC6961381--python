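"""Spectral, phase-amplitude and circular-statistics operations."""
import math

import numpy as np
import pytest
from scipy.special import i0, i1

import nestedgamma as ng
from nestedgamma import oscillation as osc
from nestedgamma import synth


def sine_trace(freq, duration_s=2.0, fs=1000.0, amp=1.0, phase=0.0):
    t = np.arange(int(duration_s * fs)) / fs
    return ng.Trace(amp * np.sin(2 * np.pi * freq * t + phase),
                    dt=1000.0 / fs, unit="a.u.")


class TestBandpass:
    def test_in_band_amplitude_preserved(self):
        tr = osc.bandpass(sine_trace(60.0), 20.0, 120.0)
        mid = tr.values[500:-500]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_out_of_band_attenuated(self):
        tr = osc.bandpass(sine_trace(5.0, duration_s=4.0), 20.0, 120.0)
        assert np.abs(tr.values[1000:-1000]).max() < 0.1

    def test_band_must_fit_under_nyquist(self):
        with pytest.raises(ValueError):
            osc.bandpass(sine_trace(60.0, fs=200.0), 20.0, 120.0)


class TestWelch:
    def test_pure_tone_peak_frequency(self):
        tr = sine_trace(40.0, duration_s=3.0)
        spec = osc.welch_psd(tr, band=(20.0, 120.0))
        assert spec.peak_frequency == pytest.approx(40.0, abs=1.0)
        assert np.all(spec.psd >= 0.0)

    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(0)
        tr = ng.Trace(rng.normal(0, 1, 10000), dt=1.0, unit="a.u.")
        spec = osc.welch_psd(tr)
        f, p = spec.frequencies, spec.psd
        lo = p[(f >= 20) & (f < 60)].mean()
        hi = p[(f >= 60) & (f < 100)].mean()
        assert abs(lo - hi) / hi < 0.2

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            osc.welch_psd(sine_trace(40.0, duration_s=0.5))


class TestSpectrogram:
    def test_stationary_tone_gives_constant_ridge(self):
        times, freqs, z = osc.spectrogram(sine_trace(40.0))
        ridge = freqs[np.argmax(z, axis=0)]
        assert np.all(np.abs(ridge - 40.0) <= freqs[1] - freqs[0])

    def test_chirp_ridge_tracks_instantaneous_frequency(self):
        from scipy.signal import chirp
        fs = 1000.0
        t = np.arange(0, 2.0, 1 / fs)
        tr = ng.Trace(chirp(t, 20.0, 2.0, 100.0), dt=1.0, unit="a.u.")
        times, freqs, z = osc.spectrogram(tr)
        ridge = freqs[np.argmax(z, axis=0)]
        inst = 20.0 + (100.0 - 20.0) * (times / 1000.0) / 2.0
        sel = slice(10, -10)
        assert np.abs(ridge[sel] - inst[sel]).max() <= freqs[1] - freqs[0]

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            osc.spectrogram(sine_trace(40.0, duration_s=0.05))


class TestInstantaneousPhase:
    def test_zero_phase_at_cosine_peaks(self):
        fs, f = 1000.0, 10.0
        t = np.arange(int(2 * fs)) / fs
        tr = ng.Trace(np.cos(2 * np.pi * f * t), dt=1.0, unit="a.u.")
        ph = osc.instantaneous_phase(tr)
        peaks = (np.arange(1, 19) * fs / f).astype(int)
        assert np.abs(ph[peaks]).max() < 2.0

    def test_antiphase_at_minima(self):
        fs, f = 1000.0, 10.0
        t = np.arange(int(2 * fs)) / fs
        tr = ng.Trace(np.cos(2 * np.pi * f * t), dt=1.0, unit="a.u.")
        ph = osc.instantaneous_phase(tr)
        troughs = ((np.arange(1, 18) + 0.5) * fs / f).astype(int)
        assert np.min(np.abs(np.abs(ph[troughs]) - 180.0)) < 2.0

    def test_unwrapped_phase_advances_360_per_cycle(self):
        tr = sine_trace(40.0, duration_s=1.0)
        ph = osc.instantaneous_phase(tr, unwrap=True)
        assert ph[-1] - ph[0] == pytest.approx(40 * 360.0, rel=0.01)


class TestModulationIndex:
    def test_uniform_amplitude_gives_zero(self):
        rng = np.random.default_rng(1)
        ph = rng.uniform(-180.0, 180.0, 20000)
        assert osc.modulation_index(ph, np.ones(20000)) == pytest.approx(0.0, abs=1e-12)

    def test_single_occupied_bin_gives_one(self):
        ph = np.full(1000, 10.0)  # all amplitude in one 20-degree bin
        amp = np.ones(1000)
        assert osc.modulation_index(ph, amp) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        n = 100000
        ph = np.degrees(rng.vonmises(0.0, 1.0, n))
        amp = 1.0 + 0.5 * np.cos(np.radians(ph)) + rng.uniform(0, 0.1, n)
        mi = osc.modulation_index(ph, amp, n_bins=18)
        # independent brute force: 18-bin histogram, sum p log(p N)
        edges = np.linspace(-180, 180, 19)
        sums = np.zeros(18)
        counts = np.zeros(18)
        for p_i, a_i in zip(ph, amp):
            b = min(int((p_i + 180) // 20), 17)
            sums[b] += a_i
            counts[b] += 1
        means = sums / counts
        prob = means / means.sum()
        brute = float(np.sum(prob * np.log(prob * 18))) / math.log(18)
        assert mi == pytest.approx(brute, abs=1e-6)

    def test_zero_amplitude_rejected(self):
        with pytest.raises(ValueError):
            osc.modulation_index(np.zeros(10), np.zeros(10))

    def test_invariant_under_amplitude_rescaling(self):
        rng = np.random.default_rng(3)
        ph = np.degrees(rng.vonmises(0.0, 1.0, 5000))
        amp = 1.0 + 0.3 * np.cos(np.radians(ph))
        a = osc.modulation_index(ph, amp)
        b = osc.modulation_index(ph, 37.5 * amp)
        assert a == pytest.approx(b, rel=1e-12)
        assert 0.0 <= a <= 1.0

    def test_monotone_in_coupling_depth(self):
        mis = []
        for c in (0.0, 0.25, 0.5, 0.75, 1.0):
            tr, _ = synth.gen_theta_gamma(
                synth.CouplingSpec(coupling_depth=c, duration=20.0, seed=5))
            theta = osc.bandpass(tr, 3.0, 8.0)
            gamma = osc.bandpass(tr, 20.0, 120.0)
            mis.append(osc.modulation_index(osc.instantaneous_phase(theta),
                                            osc.envelope(gamma)))
        assert all(np.diff(mis) > 0)


class TestComodulogram:
    def test_bin_structure_20_by_18_degrees(self):
        tr, _ = synth.gen_theta_gamma(synth.CouplingSpec(duration=5.0))
        com = osc.comodulogram(tr, gamma_frequencies=[40.0])
        assert com.phase_bin_edges.size == 21
        assert np.allclose(np.diff(com.phase_bin_edges), 18.0)
        assert np.all(com.amplitude >= 0.0)

    def test_uncoupled_signal_has_flat_rows(self):
        tr, _ = synth.gen_theta_gamma(
            synth.CouplingSpec(coupling_depth=0.0, duration=30.0, seed=6))
        com = osc.comodulogram(tr, gamma_frequencies=[40.0])
        row = com.amplitude[0]
        assert (row.max() - row.min()) / row.mean() < 0.02

    def test_trough_coupled_signal_peaks_at_edge_bins(self):
        tr, _ = synth.gen_theta_gamma(
            synth.CouplingSpec(coupling_depth=1.0, preferred_phase=-180.0,
                               duration=20.0, seed=7))
        com = osc.comodulogram(tr, gamma_frequencies=[40.0])
        best = com.phase_bin_centers[np.argmax(com.amplitude[0])]
        assert abs(best) > 162.0  # one of the two bins touching +/-180


class TestPhaseHistogram:
    def _phase_trace(self):
        tr = sine_trace(40.0, duration_s=1.0)
        return ng.Trace(osc.instantaneous_phase(tr), tr.dt, tr.t0, "a.u.")

    def test_perfect_locking(self):
        ph_tr = self._phase_trace()
        events = 12.5 + 25.0 * np.arange(30)  # one fixed phase each cycle
        stats = osc.phase_histogram(events, ph_tr)
        assert stats.vector_length > 0.99
        assert np.count_nonzero(stats.probability > 1e-6) <= 2
        assert stats.probability.sum() == pytest.approx(1.0)

    def test_antipodal_events_cancel(self):
        ph_tr = self._phase_trace()
        stats = osc.phase_histogram([100.0, 112.5], ph_tr)
        assert stats.vector_length < 0.05

    def test_twenty_bins(self):
        stats = osc.phase_histogram([100.0], self._phase_trace())
        assert stats.probability.size == 20

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            osc.phase_histogram([], self._phase_trace())


class TestResultantVector:
    def test_identical_phases(self):
        L, mu = osc.resultant_vector([37.0] * 5)
        assert L == pytest.approx(1.0)
        assert mu == pytest.approx(37.0)

    def test_von_mises_length_matches_bessel_ratio(self):
        expected = i1(2.0) / i0(2.0)  # ~0.698
        ph = synth.gen_vonmises_phases(0.0, 2.0, 1000, seed=8)
        L, _ = osc.resultant_vector(ph)
        # 99% sampling band is ~ +/- 3 sigma, sigma ~ sqrt((1-r^2)/n) scale
        assert abs(L - expected) < 0.06

    def test_uniform_sample_is_unconcentrated(self):
        ph = synth.gen_vonmises_phases(0.0, 0.0, 1000, seed=9)
        L, _ = osc.resultant_vector(ph)
        assert L < 0.1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            osc.resultant_vector([])


class TestWatsonWilliams:
    def test_equal_concentrated_groups_not_rejected(self):
        g1 = synth.gen_vonmises_phases(20.0, 20.0, 60, seed=10)
        g2 = synth.gen_vonmises_phases(20.0, 20.0, 60, seed=11)
        F, p = osc.watson_williams(g1, g2)
        assert p > 0.05

    def test_ninety_degree_separation_detected(self):
        g1 = synth.gen_vonmises_phases(0.0, 5.0, 50, seed=12)
        g2 = synth.gen_vonmises_phases(90.0, 5.0, 50, seed=13)
        F, p = osc.watson_williams(g1, g2)
        assert p < 0.001

    def test_type_one_error_near_nominal(self):
        rejections = 0
        reps = 2000
        for k in range(reps):
            g1 = synth.gen_vonmises_phases(0.0, 2.0, 30, seed=2 * k)
            g2 = synth.gen_vonmises_phases(0.0, 2.0, 30, seed=2 * k + 1)
            _, p = osc.watson_williams(g1, g2)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            osc.watson_williams([10.0, 10.0], [10.0, 10.0])
        with pytest.raises(ValueError):
            osc.watson_williams([10.0], [0.0, 20.0])


class TestSpikesPerCycle:
    bounds = np.arange(0.0, 1001.0, 200.0)

    def test_no_spikes(self):
        assert np.all(osc.spikes_per_theta_cycle([], self.bounds) == 0)

    def test_one_spike_per_cycle(self):
        spikes = 100.0 + 200.0 * np.arange(5)
        assert np.all(osc.spikes_per_theta_cycle(spikes, self.bounds) == 1)

    def test_counts_conserve_total(self):
        rng = np.random.default_rng(14)
        spikes = np.sort(rng.uniform(0.0, 1000.0, 87))
        counts = osc.spikes_per_theta_cycle(spikes, self.bounds)
        assert counts.sum() == 87

    def test_unsorted_boundaries_rejected(self):
        with pytest.raises(ValueError):
            osc.spikes_per_theta_cycle([1.0], [0.0, 200.0, 100.0])


class TestRelativeGammaPhase:
    pc = np.array([100.0, 130.0, 160.0])

    def test_midpoint_maps_to_gamma_peak(self):
        ph, dropped = osc.relative_gamma_phase(np.array([115.0]), self.pc)
        assert ph[0] == pytest.approx(0.0)
        assert dropped == 0

    def test_coincident_spike_sits_at_trough(self):
        ph, _ = osc.relative_gamma_phase(np.array([130.0]), self.pc)
        assert ph[0] == pytest.approx(-180.0)

    def test_outside_spikes_dropped_and_counted(self):
        ph, dropped = osc.relative_gamma_phase(np.array([50.0, 115.0, 500.0]),
                                               self.pc)
        assert ph.size == 1 and dropped == 2

    def test_uniform_jitter_gives_low_resultant(self):
        rng = np.random.default_rng(15)
        pc = np.arange(0.0, 25000.0, 25.0)
        pv = np.sort(rng.uniform(0.0, 24900.0, 1000))
        ph, _ = osc.relative_gamma_phase(pv, pc)
        L, _ = osc.resultant_vector(ph)
        assert L < 0.1
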