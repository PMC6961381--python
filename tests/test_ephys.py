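"""Intracellular-recording metrics: formulas and parameter recovery."""
import numpy as np
import pytest

import nestedgamma as ng
from nestedgamma import ephys, synth
from nestedgamma.synapses import SynapseKinetics, biexp_conductance


class TestInputResistance:
    def test_printed_formula(self):
        assert ephys.input_resistance(-70.0, -71.0, 5.0) == pytest.approx(200.0)

    def test_no_deflection_gives_zero(self):
        assert ephys.input_resistance(-70.0, -70.0, 5.0) == 0.0

    def test_zero_current_rejected(self):
        with pytest.raises(ValueError):
            ephys.input_resistance(-70.0, -71.0, 0.0)

    def test_recovers_simulated_passive_cell(self, passive_cell):
        comp = passive_cell.compartments[0]
        R_true = 1.0 / comp.g_abs_uS("leak")
        tau_true = comp.capacitance_nF / comp.g_abs_uS("leak")
        traces, _ = ng.integrate(
            passive_cell,
            stimuli=[("soma", ng.StepCurrent(-5.0, t_on=200.0, t_off=500.0))],
            duration=520.0)
        seg = traces["soma"].crop(200.0, 450.0)
        fit = ephys.membrane_tau(seg, I_pA=5.0)
        assert fit.R_in == pytest.approx(R_true, rel=0.01)
        assert fit.tau == pytest.approx(tau_true, rel=0.01)


class TestMembraneTau:
    def test_exact_exponential_self_fit(self):
        t = np.arange(0.0, 100.0, 0.1)
        v = -66.0 + 1.0 * np.exp(-t / 20.0)
        fit = ephys.membrane_tau(ng.Trace(v, dt=0.1, unit="mV"))
        assert fit.tau == pytest.approx(20.0, rel=1e-3)
        assert fit.V_steady == pytest.approx(-66.0, abs=1e-6)
        assert fit.A == pytest.approx(1.0, rel=1e-6)

    def test_noisy_recovery_monte_carlo(self):
        errs = []
        for seed in range(100):
            tr, meta = synth.gen_passive_step(R_MOhm=200.0, tau_ms=20.0,
                                              I_pA=5.0, noise_sd=0.05,
                                              seed=seed)
            fit = ephys.membrane_tau(tr, I_pA=5.0)
            errs.append(abs(fit.tau - 20.0) / 20.0)
        errs = np.asarray(errs)
        assert np.median(errs) < 0.02
        assert np.quantile(errs, 0.9) < 0.05

    def test_flat_trace_rejected(self):
        with pytest.raises(ValueError):
            ephys.membrane_tau(ng.Trace(np.full(100, -70.0), dt=0.1, unit="mV"))


class TestEpspSlope:
    def test_linear_rise(self):
        # 1 mV over 10 ms, sampled densely: slope of the 20-80% window
        t = np.arange(0.0, 30.0, 0.01)
        v = np.where(t < 10.0, 0.1 * t, 1.0)
        v[t >= 20.0] = 0.0
        tr = ng.Trace(v - 70.0, dt=0.01, unit="mV")
        assert ephys.epsp_slope(tr, baseline_ms=0.02) == pytest.approx(0.1, rel=1e-3)

    def test_biexp_epsp_matches_numeric_derivative(self):
        kin = SynapseKinetics("biexp", g_max=1.0, tau_rise=3.0, tau_decay=15.0)
        t = np.arange(0.0, 60.0, 0.01)
        v = -70.0 + 4.0 * np.asarray(biexp_conductance(kin, t))
        tr = ng.Trace(v, dt=0.01, unit="mV")
        slope = ephys.epsp_slope(tr, baseline_ms=0.02)
        # dense numerical derivative averaged over the same 20-80% window
        amp = v.max() - v[0]
        rise = v[:np.argmax(v) + 1]
        t20 = np.interp(v[0] + 0.2 * amp, rise, t[:rise.size])
        t80 = np.interp(v[0] + 0.8 * amp, rise, t[:rise.size])
        sel = (t >= t20) & (t <= t80)
        numeric = np.gradient(v, 0.01)[sel].mean()
        # a least-squares line and the mean derivative agree to ~2% on
        # this curved rise (they coincide exactly for a linear rise)
        assert slope == pytest.approx(numeric, rel=0.025)

    def test_offset_invariance_and_amplitude_scaling(self):
        kin = SynapseKinetics("biexp", g_max=1.0, tau_rise=3.0, tau_decay=15.0)
        t = np.arange(0.0, 60.0, 0.01)
        wave = np.asarray(biexp_conductance(kin, t))
        s1 = ephys.epsp_slope(ng.Trace(wave - 70.0, dt=0.01, unit="mV"))
        s2 = ephys.epsp_slope(ng.Trace(wave - 55.0, dt=0.01, unit="mV"))
        s3 = ephys.epsp_slope(ng.Trace(3.0 * wave - 70.0, dt=0.01, unit="mV"))
        assert s1 == pytest.approx(s2, rel=1e-9)
        assert s3 == pytest.approx(3.0 * s1, rel=1e-9)

    def test_flat_trace_rejected(self):
        with pytest.raises(ValueError):
            ephys.epsp_slope(ng.Trace(np.full(100, -70.0), dt=0.1, unit="mV"))


class TestNormalizeTimecourse:
    times = np.arange(0.0, 41.0, 1.0)  # minutes; induction at 10

    def test_constant_slopes_stay_at_100pct(self):
        tc = ephys.normalize_timecourse(self.times, np.full(41, 0.2))
        assert np.allclose(tc.normalized_pct, 100.0)
        assert tc.summary_pct == pytest.approx(100.0)

    def test_doubled_slopes_give_200pct_summary(self):
        slopes = np.where(self.times < 10.0, 0.2, 0.4)
        tc = ephys.normalize_timecourse(self.times, slopes)
        assert tc.summary_pct == pytest.approx(200.0)

    def test_empty_summary_window_rejected(self):
        with pytest.raises(ValueError):
            ephys.normalize_timecourse(np.arange(0.0, 20.0), np.ones(20))


class TestPPRAndCharge:
    def test_ppr_values(self):
        assert ephys.ppr([100.0, 100.0]) == pytest.approx(1.0)
        assert ephys.ppr([100.0, 150.0]) == pytest.approx(1.5)
        with pytest.raises(ValueError):
            ephys.ppr([0.0, 100.0])

    def test_train_recovers_programmed_ratio(self):
        scal = np.array([1.0, 1.4, 1.2, 1.0, 0.9, 0.85, 0.8, 0.8, 0.75, 0.7])
        tr, meta = synth.gen_psc_train(per_event_scaling=scal)
        amps = ephys.train_amplitudes(tr, meta["event_times_ms"], tau_decay=15.0)
        assert ephys.ppr(amps) == pytest.approx(1.4, rel=0.02)

    def test_rectangular_pulse_charge(self):
        v = np.zeros(3000)
        v[1000:1100] = 100.0  # 100 pA for 10 ms
        tr = ng.Trace(v, dt=0.1, unit="pA")
        assert ephys.total_charge(tr, (95.0, 130.0)) == pytest.approx(1.0, rel=0.01)

    def test_zero_trace_has_zero_charge(self):
        tr = ng.Trace(np.zeros(1000), dt=0.1, unit="pA")
        assert ephys.total_charge(tr, (10.0, 90.0)) == 0.0

    def test_biexp_train_charge_matches_analytic(self):
        tr, meta = synth.gen_psc_train(post_ms=400.0)
        q = ephys.total_charge(tr, (meta["event_times_ms"][0] - 5.0,
                                    tr.t0 + tr.duration))
        assert q == pytest.approx(meta["total_charge_pC"], rel=0.005)


class TestSRCurve:
    def test_exact_midpoint(self):
        sr = ephys.sr_curve([10.0, 100.0, 300.0], [0.0, 50.0, 100.0])
        assert sr.half_max_intensity == pytest.approx(100.0, rel=0.01)

    def test_six_point_grid_accepted(self):
        grid = [10.0, 50.0, 100.0, 150.0, 200.0, 300.0]
        resp = [2.0, 15.0, 55.0, 80.0, 95.0, 100.0]
        sr = ephys.sr_curve(grid, resp)
        assert 50.0 < sr.half_max_intensity < 150.0

    def test_logistic_half_max_within_2pct(self):
        x = np.array([10.0, 50.0, 100.0, 150.0, 200.0, 300.0])
        x_half = 120.0
        y = 100.0 / (1.0 + np.exp(-(x - x_half) / 25.0))
        sr = ephys.sr_curve(x, y)
        # closed form: response = 50% of the interpolated maximum
        y_half = sr.max_response / 2.0
        expected = x_half + 25.0 * np.log(y_half / (100.0 - y_half))
        assert sr.half_max_intensity == pytest.approx(expected, rel=0.02)

    def test_non_crossing_rejected(self):
        with pytest.raises(ValueError):
            ephys.sr_curve([1.0, 2.0, 3.0], [80.0, 90.0, 100.0])


class TestDisinhibition:
    def test_additive_condition_means_none(self):
        res = ephys.disinhibition(200.0, 300.0, 100.0)
        assert res.isolated_pA == 200.0
        assert res.disinhibition_pA == 0.0

    def test_subtraction_arithmetic(self):
        res = ephys.disinhibition(200.0, 220.0, 100.0)
        assert res.isolated_pA == 120.0
        assert res.disinhibition_pA == 80.0

    def test_recovers_programmed_reduction_from_traces(self):
        # build PSC traces with a 40% reduction of the SC component during
        # pairing; amplitudes measured from the traces themselves
        kin = SynapseKinetics("biexp", g_max=1.0, tau_rise=3.0, tau_decay=40.0)
        t = np.arange(0.0, 200.0, 0.1)
        sc = 200.0 * np.asarray(biexp_conductance(kin, t))
        alveus = 100.0 * np.asarray(biexp_conductance(kin, t))
        paired = alveus + 0.6 * sc
        amp = lambda v: float(v.max())
        res = ephys.disinhibition(amp(sc), amp(paired), amp(alveus))
        reduction = res.disinhibition_pA / amp(sc)
        assert reduction == pytest.approx(0.4, abs=0.03)
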