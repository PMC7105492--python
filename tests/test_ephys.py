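"""Current decomposition: averaging, train subtraction, I_K / I_GluT
measurement, mono-exponential fitting, input resistance, EPSC charge, LTP."""

import numpy as np
import pytest

import gliaquant as gq
from gliaquant import ephys, synthgen


FS = 5000.0


class TestBaselineSubtractAverage:
    def test_constant_offset_becomes_zero(self):
        sw = ephys.SweepSet({"a": np.full((3, 1000), 17.0)}, FS,
                            {"a": np.array([0.5])}, (0.0, 0.1))
        out = ephys.baseline_subtract_average(sw)
        assert np.allclose(out.traces["a"], 0.0)

    def test_two_identical_sweeps_average_to_either(self, rng):
        trace = rng.normal(size=1000)
        sw = ephys.SweepSet({"a": np.vstack([trace, trace])}, FS,
                            {"a": np.array([0.5])}, (0.0, 0.1))
        out = ephys.baseline_subtract_average(sw)
        base = trace[:int(0.1 * FS)].mean()
        assert np.allclose(out.traces["a"][0], trace - base)

    def test_average_approaches_clean_kernel_sum(self):
        p = gq.SweepParams(noise_sd=2.0, n_sweeps=40, seed=6)
        sw = gq.gen_astro_sweeps(p)
        avg = ephys.baseline_subtract_average(sw)
        clean = np.asarray(sw.ground_truth["clean_traces"]["5"])
        resid = avg.traces["5"][0] - clean
        assert np.abs(resid).std() < 3 * 2.0 / np.sqrt(40)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            ephys.SweepSet({"a": np.zeros((1, 100)), "b": np.zeros((1, 90))},
                           FS, {}, (0.0, 0.01))


class TestIsolateFifth:
    def test_identical_traces_give_zero(self):
        t = np.sin(np.linspace(0, 5, 500))
        assert np.all(ephys.isolate_fifth_response(t, t) == 0.0)

    def test_noiseless_superposition_machine_exact(self, noiseless_sweeps):
        sw = noiseless_sweeps
        diff = ephys.isolate_fifth_response(sw.traces["5"], sw.traces["4"])
        p = gq.SweepParams()
        t = sw.time_s - sw.stim_times_s["5"][-1]
        fifth = (synthgen.biexp_kernel(t, *p.k_kernel)
                 + synthgen.biexp_kernel(t, *p.glut_kernel))
        assert np.max(np.abs(diff - fifth)) <= 1e-10 * np.max(np.abs(fifth))

    def test_facilitated_fifth_peak_scales(self):
        p = gq.SweepParams(glut_amp_factors=(1, 1, 1, 1, 1.5), noise_sd=0.0,
                           n_sweeps=1)
        sw = gq.gen_astro_sweeps(p)
        diff = ephys.isolate_fifth_response(sw.traces["5"], sw.traces["4"])
        single = np.ravel(sw.traces["1"])
        # transporter peak region: glut dominates within a few ms of the stim
        i5 = int(sw.stim_times_s["5"][-1] * FS)
        i1 = int(sw.stim_times_s["1"][0] * FS)
        w = int(0.004 * FS)
        ratio = np.min(diff[i5:i5 + w]) / np.min(single[i1:i1 + w])
        assert ratio == pytest.approx(1.5, rel=0.02)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ephys.isolate_fifth_response(np.zeros(10), np.zeros(9))


class TestFitMonoexp:
    def test_exact_exponential(self):
        t = np.arange(0, 1.0, 1 / FS)
        fit = ephys.fit_monoexp(t, -40.0 * np.exp(-t / 0.150))
        assert fit.converged
        assert fit.tau_ms == pytest.approx(150.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(-40.0, rel=1e-6)

    def test_exponential_with_offset(self):
        t = np.arange(0, 1.0, 1 / FS)
        fit = ephys.fit_monoexp(t, -40.0 * np.exp(-t / 0.150) - 12.0)
        assert fit.converged
        assert fit.tau_ms == pytest.approx(150.0, rel=1e-4)
        assert fit.offset == pytest.approx(-12.0, rel=1e-4)

    def test_white_noise_flagged(self, rng):
        t = np.arange(0, 0.2, 1 / FS)
        fit = ephys.fit_monoexp(t, rng.normal(size=t.size))
        ci_lo, ci_hi = fit.tau_ci_s
        degenerate = (not fit.converged) or not np.isfinite(ci_hi) \
            or ci_lo <= 0 or ci_hi / max(fit.tau_s, 1e-12) > 10
        assert degenerate

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            ephys.fit_monoexp(np.arange(5) / FS, np.ones(5))

    @pytest.mark.parametrize("tau_ms", [10.0, 50.0, 200.0, 800.0])
    def test_tau_bias_below_two_percent_at_snr20(self, tau_ms):
        # 50 seeds per tau, SNR 20 (amplitude/noise)
        rng = np.random.default_rng(int(tau_ms))
        dur = max(5 * tau_ms / 1000.0, 0.2)
        t = np.arange(0, dur, 1 / FS)
        taus = []
        for _ in range(50):
            y = -100.0 * np.exp(-t / (tau_ms / 1000.0)) \
                + rng.normal(0, 5.0, t.size)
            fit = ephys.fit_monoexp(t, y)
            assert fit.converged
            taus.append(fit.tau_ms)
        assert abs(np.mean(taus) - tau_ms) < 0.02 * tau_ms


class TestMeasureIK:
    def test_decaying_trace_uses_fallback_at_200ms(self):
        t = np.arange(0, 1.5, 1 / FS)
        trace = -30.0 * np.exp(-t / 0.3)  # decaying before the window opens
        m = ephys.measure_ik(trace, FS, last_stim_s=0.0)
        assert m.used_fallback
        i200 = int(0.2 * FS)
        assert m.amplitude_signed_pa == pytest.approx(trace[i200], rel=0.02)
        assert m.decay_fit.converged
        assert m.decay_fit.tau_ms == pytest.approx(300.0, rel=0.02)

    def test_late_peak_found_instead_of_fallback(self):
        # kernel peaking ~260 ms after the stimulus: the peak wins
        t = np.arange(0, 2.0, 1 / FS)
        trace = synthgen.biexp_kernel(t - 0.1, -50.0, 150.0, 500.0)
        m = ephys.measure_ik(trace, FS, last_stim_s=0.1)
        assert not m.used_fallback
        assert m.amplitude_pa == pytest.approx(50.0, rel=0.02)
        assert m.t_amplitude_s > 0.3

    def test_generator_k_tau_recovered(self, noiseless_sweeps):
        sw = noiseless_sweeps
        m = ephys.measure_ik(sw.traces["1"], FS, sw.stim_times_s["1"][0])
        assert m.decay_fit.converged
        assert m.decay_fit.tau_ms == pytest.approx(300.0, abs=1.0)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            ephys.measure_ik(np.zeros(100), FS, last_stim_s=0.5)


class TestResidualReconstruction:
    def test_noiseless_biexponential_within_two_percent_rms(self, noiseless_sweeps):
        sw = noiseless_sweeps
        avg = ephys.baseline_subtract_average(sw)
        tboa = np.ravel(avg.traces["tboa"])
        rec = ephys.reconstruct_residual_ik(tboa, FS, sw.stim_times_s["tboa"][0])
        rms = np.sqrt(np.mean((rec - tboa) ** 2))
        assert rms < 0.02 * np.max(np.abs(tboa))

    def test_zero_trace_reconstructs_to_zero(self):
        rec = ephys.reconstruct_residual_ik(np.zeros(5000), FS, 0.5)
        assert np.all(rec == 0.0)

    def test_splice_continuity_at_peak(self, noiseless_sweeps):
        sw = noiseless_sweeps
        tboa = np.ravel(sw.traces["tboa"])
        rec = ephys.reconstruct_residual_ik(tboa, FS, 0.5)
        i_peak = int(np.argmax(np.abs(rec)))
        jump = abs(rec[i_peak] - rec[i_peak - 1])
        assert jump < 0.01 * np.max(np.abs(rec))


class TestExtractIGluT:
    def test_residual_equal_to_trace_gives_flat_zero(self):
        t = np.arange(0, 1.0, 1 / FS)
        k = synthgen.biexp_kernel(t - 0.5, -20.0, 20.0, 300.0)
        pure, m = ephys.extract_iglut(k, k, FS, 0.5)
        assert np.allclose(pure, 0.0)
        assert m.amplitude_pa == pytest.approx(0.0, abs=1e-9)

    def test_generator_glut_tau_recovered(self, noiseless_sweeps):
        sw = noiseless_sweeps
        avg = ephys.baseline_subtract_average(sw)
        residual = ephys.reconstruct_residual_ik(avg.traces["tboa"], FS, 0.5)
        _, m = ephys.extract_iglut(avg.traces["1"], residual, FS, 0.5)
        assert m.decay_fit.converged
        assert m.decay_fit.tau_ms == pytest.approx(8.0, abs=0.5)


class TestInputResistance:
    def test_ideal_resistor_ohms_law(self):
        st = gq.gen_step_response(gq.StepParams(resistance_mohm=30.0,
                                                cap_amp_factor=1.0))
        r, di, settled = ephys.input_resistance(
            st.traces["step"][0], FS, tuple(st.ground_truth["step_window_s"]))
        assert r == pytest.approx(30.0, rel=1e-9)
        assert settled

    def test_doubled_current_halves_resistance(self):
        st = gq.gen_step_response(gq.StepParams(resistance_mohm=30.0,
                                                cap_amp_factor=1.0))
        trace = st.traces["step"][0] * 2.0
        r, _, _ = ephys.input_resistance(
            trace, FS, tuple(st.ground_truth["step_window_s"]))
        assert r == pytest.approx(15.0, rel=1e-9)

    def test_rc_transient_then_plateau_recovered(self):
        st = gq.gen_step_response(gq.StepParams(resistance_mohm=45.0,
                                                noise_sd=1.0, seed=2))
        r, _, settled = ephys.input_resistance(
            st.traces["step"][0], FS, tuple(st.ground_truth["step_window_s"]))
        assert r == pytest.approx(45.0, rel=0.02)
        assert settled

    def test_unsettled_plateau_flagged(self):
        t = np.arange(0, 0.5, 1 / FS)
        trace = np.where(t >= 0.1, -150.0 * np.exp(-(t - 0.1) / 0.5), 0.0)
        _, _, settled = ephys.input_resistance(trace, FS, (0.1, 0.4))
        assert not settled


class TestEpscCharge:
    def test_rectangular_pulse_analytic_area(self):
        trace = np.zeros(5000)
        trace[1000:2000] = -80.0  # 0.2 s wide, 80 pA
        res = ephys.epsc_charge(trace, FS, (0.15, 0.45), (0.5, 0.9), (0.0, 0.1))
        assert res.q_peaks_pas == pytest.approx(-80.0 * 0.2, rel=0.02)
        assert res.q_tail_pas == pytest.approx(0.0, abs=1e-9)

    def test_scaled_trace_gives_same_fraction_in_both_windows(self):
        t = np.arange(0, 1.0, 1 / FS)
        trace = synthgen.biexp_kernel(t - 0.2, -60.0, 5.0, 120.0)
        drug = 0.7 * trace
        base = ephys.epsc_charge(trace, FS, (0.18, 0.4), (0.45, 0.95), (0.0, 0.15))
        drugr = ephys.epsc_charge(drug, FS, (0.18, 0.4), (0.45, 0.95), (0.0, 0.15))
        frac = ephys.charge_fractions(drugr, base)
        assert frac["peaks_pct"] == pytest.approx(70.0)
        assert frac["tail_pct"] == pytest.approx(70.0)

    def test_tail_only_drug_effect_isolated(self):
        # drug scales only the slow (tail) component: peak fraction stays ~100%
        t = np.arange(0, 1.2, 1 / FS)
        fast = synthgen.biexp_kernel(t - 0.2, -150.0, 2.0, 12.0)
        slow = synthgen.biexp_kernel(t - 0.2, -30.0, 30.0, 300.0)
        base = fast + slow
        drug = fast + 0.69 * slow
        pw, tw, bw = (0.2, 0.25), (0.5, 1.1), (0.0, 0.15)
        fr = ephys.charge_fractions(ephys.epsc_charge(drug, FS, pw, tw, bw),
                                    ephys.epsc_charge(base, FS, pw, tw, bw))
        assert fr["tail_pct"] == pytest.approx(69.0, abs=1.5)
        assert fr["peaks_pct"] > 90.0

    def test_charge_additive_over_adjacent_windows(self):
        t = np.arange(0, 1.0, 1 / FS)
        trace = synthgen.biexp_kernel(t - 0.1, -60.0, 5.0, 100.0)
        a = ephys.epsc_charge(trace, FS, (0.1, 0.4), (0.4, 0.9), (0.0, 0.05))
        b = ephys.epsc_charge(trace, FS, (0.1, 0.9), (0.9, 0.95), (0.0, 0.05))
        assert a.q_peaks_pas + a.q_tail_pas == pytest.approx(b.q_peaks_pas,
                                                             rel=1e-6)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ephys.epsc_charge(np.zeros(5000), FS, (0.1, 0.5), (0.4, 0.9),
                              (0.0, 0.05))


class TestLTPAndIO:
    def test_flat_series_is_100_percent(self):
        t = np.arange(0, 75, 1 / 3)
        res = ephys.ltp_magnitude(t, np.full(t.size, 0.2), hfs_time_min=15.0)
        assert res.magnitude_pct == pytest.approx(100.0)

    def test_post_hfs_scaling_by_147_percent(self):
        t = np.arange(0, 75, 1 / 3)
        amps = np.where(t >= 15.0, 1.47, 1.0)
        res = ephys.ltp_magnitude(t, amps, hfs_time_min=15.0)
        assert res.magnitude_pct == pytest.approx(147.0)

    def test_window_preceding_hfs_rejected(self):
        t = np.arange(0, 75, 1 / 3)
        with pytest.raises(ValueError):
            ephys.ltp_magnitude(t, np.ones(t.size), 15.0, window_min=(-10.0, -5.0))

    def test_alternate_window_selectable(self):
        s = gq.gen_ltp_series(gq.LTPSeriesParams(potentiation_factor=1.6,
                                                 amplitude_noise_cv=0.0))
        res = ephys.ltp_magnitude(s.times_min, s.amplitudes, s.hfs_time_min,
                                  window_min=(40.0, 50.0))
        assert res.window_min == (40.0, 50.0)
        assert res.magnitude_pct == pytest.approx(160.0, abs=0.2)

    def test_input_output_single_level_and_sem(self):
        out = ephys.input_output([100, 100, 100], [0.5, 0.5, 0.5])
        assert len(out) == 1
        assert out.loc[0, "sem"] == 0.0

    def test_input_output_linear_slope_recovered(self, rng):
        stim = np.repeat([100, 200, 300, 400], 6)
        resp = 0.004 * stim + rng.normal(0, 0.02, stim.size)
        out = ephys.input_output(stim, resp)
        slope = np.polyfit(out["stim_ua"], out["mean"], 1)[0]
        assert slope == pytest.approx(0.004, rel=0.1)
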