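"""Current-clamp feature extraction: passive properties, spike detection
against a brute-force oracle, rheobase/delay semantics, I/O and jitter."""
import math
from dataclasses import replace

import numpy as np
import pytest

from gdelay import ccfeat
from gdelay.ccfeat import (DelayResult, PassiveProperties, detect_aps,
                           estimate_capacitance, find_rheobase,
                           first_spike_jitter, fit_membrane_time_constant,
                           io_curves, measure_delay, measure_rin,
                           measure_vrest, synaptic_io)
from gdelay.errors import InsufficientDataError
from gdelay.dgsim import (StepProtocol, apply_drug, naive_params,
                          resting_potential, simulate_current_clamp)
from gdelay.trace_io import Sweep


def _step_sweep(amp_pA, dv_mV, baseline=-80.0, tau_ms=30.0, dt=1e-4,
                onset=0.1, dur=0.8, total=1.0):
    """Synthetic passive charging response with known steady-state shift."""
    t = np.arange(int(total / dt)) * dt
    v = np.full(t.size, baseline)
    rise = t >= onset
    v[rise] += dv_mV * (1 - np.exp(-(t[rise] - onset) * 1e3 / tau_ms))
    return Sweep(v, dt, "voltage", StepProtocol(amp_pA, onset, dur))


class TestPassive:
    def test_vrest_of_constant_and_oscillating_traces(self):
        s = Sweep(np.full(50_000, -82.4), 1e-4, "voltage")
        assert measure_vrest(s) == pytest.approx(-82.4)
        t = np.arange(200_000) * 1e-4
        wob = Sweep(-80.0 + 2.0 * np.sin(2 * np.pi * t), 1e-4, "voltage")
        assert measure_vrest(wob) == pytest.approx(-80.0, abs=1e-6)

    def test_vrest_window_too_short_raises(self):
        s = Sweep(np.full(100, -80.0), 1e-4, "voltage")
        with pytest.raises(InsufficientDataError):
            measure_vrest(s)

    def test_vrest_of_simulated_cell_matches_model_fixed_point(self, naive_p):
        sweep = simulate_current_clamp(naive_p, StepProtocol(0.0, 0.1, 0.1),
                                       T=1.2)
        assert measure_vrest(sweep) == pytest.approx(
            resting_potential(naive_p), abs=0.5)

    def test_rin_from_symmetric_steps_is_slope(self):
        sweeps = [_step_sweep(-10.0, -5.0), _step_sweep(10.0, 5.0)]
        assert measure_rin(sweeps).r_in_MOhm == pytest.approx(500.0, rel=1e-3)

    def test_rin_excludes_spiking_and_out_of_range_sweeps(self):
        sweeps = [_step_sweep(-10.0, -5.0), _step_sweep(10.0, 5.0)]
        r0 = measure_rin(sweeps).r_in_MOhm
        spiking = _step_sweep(100.0, 30.0, baseline=-20.0)  # crosses 0 mV
        big = _step_sweep(50.0, 25.0)                        # |dV| > 10 mV
        assert measure_rin(sweeps + [spiking, big]).r_in_MOhm \
            == pytest.approx(r0)
        with pytest.raises(InsufficientDataError):
            measure_rin([spiking, big])

    def test_rin_of_passive_model_recovers_programmed_resistance(self):
        from gdelay.dgsim import SimCellParams
        p = SimCellParams(g_l_nS=1000.0 / 600.0, e_l_mV=-82.0, g_na_nS=0.0,
                          g_kdr_nS=0.0, g_kir_nS=0.0, g_d_nS=0.0)
        sweeps = [simulate_current_clamp(p, StepProtocol(a, 0.1, 0.8), T=1.0)
                  for a in (-10.0, -5.0, 5.0, 10.0)]
        assert measure_rin(sweeps).r_in_MOhm == pytest.approx(600.0, rel=0.02)

    def test_rin_invariant_under_uniform_voltage_offset(self):
        sweeps = [_step_sweep(-10.0, -5.0), _step_sweep(10.0, 5.0)]
        shifted = [Sweep(s.samples - 10.0, s.dt, s.kind, s.protocol)
                   for s in sweeps]
        assert measure_rin(shifted).r_in_MOhm \
            == pytest.approx(measure_rin(sweeps).r_in_MOhm)

    def test_tau_fit_single_exponential_reported_as_slow_component(self):
        s = _step_sweep(-5.0, -3.0, tau_ms=30.0)
        fit = fit_membrane_time_constant(s)
        assert fit.tau_m_ms == pytest.approx(30.0, rel=0.01)

    def test_tau_fit_two_components_reports_slower(self):
        t = np.arange(10_000) * 1e-4
        onset = 0.1
        rise = t >= onset
        v = np.full(t.size, -80.0)
        dt_ms = (t[rise] - onset) * 1e3
        v[rise] += -1.0 * (1 - np.exp(-dt_ms / 3.0)) \
            - 3.0 * (1 - np.exp(-dt_ms / 30.0))
        s = Sweep(v, 1e-4, "voltage", StepProtocol(-8.0, onset, 0.8))
        fit = fit_membrane_time_constant(s)
        assert fit.tau_m_ms == pytest.approx(30.0, rel=0.02)
        assert fit.tau_fast_ms == pytest.approx(3.0, rel=0.1)

    def test_capacitance_arithmetic_and_model_recovery(self):
        assert estimate_capacitance(30.0, 600.0) == pytest.approx(50.0)
        assert estimate_capacitance(60.0, 600.0) == pytest.approx(100.0)
        from gdelay.dgsim import SimCellParams
        p = SimCellParams(g_l_nS=1000.0 / 600.0, e_l_mV=-82.0, g_na_nS=0.0,
                          g_kdr_nS=0.0, g_kir_nS=0.0, g_d_nS=0.0)  # 88 pF
        s = simulate_current_clamp(p, StepProtocol(-5.0, 0.1, 0.8), T=1.0)
        fit = fit_membrane_time_constant(s)
        rin = measure_rin([s, simulate_current_clamp(
            p, StepProtocol(5.0, 0.1, 0.8), T=1.0)])
        c = estimate_capacitance(fit.tau_m_ms, rin.r_in_MOhm)
        assert c == pytest.approx(88.0, rel=0.05)

    def test_passive_properties_consistency_guard(self):
        with pytest.raises(ValueError):
            PassiveProperties(-82.0, 600.0, 30.0, 600.0, c_m_pF=80.0)


def _toy_spike(width_ms=1.1, dt=1e-5, peak=30.0, level=-5.0):
    """Triangular spike whose crossings of ``level`` are exactly width apart."""
    n = 20_000
    v = np.full(n, -80.0)
    pk = 10_000
    half = int(width_ms * 1e-3 / dt / 2)
    up = np.linspace(level, peak, half + 1)
    down = np.linspace(peak, level, half + 1)
    ramp_in = np.linspace(-80.0, level, 2000, endpoint=False)
    v[pk - half - 2000:pk - half] = ramp_in
    v[pk - half:pk + 1] = up
    v[pk:pk + half + 1] = down
    v[pk + half + 1:pk + half + 2001] = np.linspace(level, -80.0, 2000)
    return Sweep(v, dt, "voltage", StepProtocol(80.0, 0.0, 0.2))


class TestSpikeDetection:
    def test_subthreshold_trace_yields_no_events(self):
        s = _step_sweep(-10.0, -5.0)
        assert detect_aps(s) == []

    def test_width_measured_at_minus_five_mV(self):
        events = detect_aps(_toy_spike(width_ms=1.1))
        assert len(events) == 1
        assert events[0].width_ms == pytest.approx(1.1, abs=0.05)
        assert events[0].peak_V_mV == pytest.approx(30.0)

    def test_matches_brute_force_local_maximum_oracle(self, naive_p):
        """Detection agrees with an independent local-maxima scan (same
        overshoot criterion and lockout enforced by brute force) on simulated
        sweeps across stimulus strengths."""
        for i, amp in enumerate((90.0, 140.0, 200.0)):
            p = replace(naive_p, noise_sd_pA=10.0, seed=100 + i)
            s = simulate_current_clamp(p, StepProtocol(amp, 0.05, 0.7), T=0.8)
            got = [ev.peak_time_s for ev in detect_aps(s)]
            v = s.samples
            lockout = int(2e-3 / s.dt)
            oracle, last = [], -10 * lockout
            for j in range(1, v.size - 1):
                if v[j] > 0 and v[j] >= v[j - 1] and v[j] > v[j + 1] \
                        and j - last >= lockout:
                    oracle.append(j)
                    last = j
            assert len(got) == len(oracle)
            assert np.allclose(got, np.array(oracle) * s.dt, atol=s.dt)

    def test_threshold_agrees_with_oversampled_trace(self, naive_p):
        """Threshold from the default-rate trace is within 2 mV of the value
        measured on a 10x-oversampled simulation of the same cell."""
        proto = StepProtocol(90.0, 0.05, 0.7)
        coarse = simulate_current_clamp(naive_p, proto, dt=25e-6, T=0.8)
        fine = simulate_current_clamp(naive_p, proto, dt=2.5e-6, T=0.8)
        thr_c = detect_aps(coarse, slope_thresh_mV_per_s=20e3)[0].threshold_V_mV
        thr_f = detect_aps(fine, slope_thresh_mV_per_s=20e3)[0].threshold_V_mV
        assert thr_c == pytest.approx(thr_f, abs=2.0)


class TestRheobaseAndDelay:
    @staticmethod
    def _provider(threshold_pA):
        def make(amp):
            return _toy_spike() if amp >= threshold_pA \
                else _step_sweep(amp, -2.0, dur=0.2, total=0.2)
        return make

    def test_grid_semantics(self):
        prov = self._provider(63.0)
        assert find_rheobase(prov, grid=np.arange(0, 101, 1.0)).rheobase_pA == 63
        assert find_rheobase(prov, grid=np.arange(0, 101, 5.0)).rheobase_pA == 65

    def test_censored_when_grid_maximum_is_silent(self):
        res = find_rheobase(self._provider(1e6), grid=np.arange(0, 101, 5.0))
        assert res.censored and res.rheobase_pA is None

    def test_rheobase_drops_when_delay_conductance_removed(self, naive_p):
        grid = np.arange(40.0, 200.0, 10.0)

        def provider_for(p):
            return lambda amp: simulate_current_clamp(
                p, StepProtocol(amp, 0.02, 1.0), T=1.05)

        rb_ctrl = find_rheobase(provider_for(naive_p), grid=grid)
        rb_dtx = find_rheobase(provider_for(apply_drug(naive_p, "DTX", 1.0)),
                               grid=grid)
        assert not rb_ctrl.censored and not rb_dtx.censored
        assert rb_dtx.rheobase_pA <= rb_ctrl.rheobase_pA

    def test_delay_is_time_from_onset_to_first_peak(self):
        s = _toy_spike()  # peak at sample 10_000, dt 1e-5, onset 0
        assert measure_delay(s).delay_ms == pytest.approx(100.0, abs=0.1)

    def test_no_spike_is_censored_not_sentinel(self):
        res = measure_delay(_step_sweep(-10.0, -5.0))
        assert res.censored and math.isnan(res.delay_ms)

    def test_delay_invariant_under_uniform_offset(self, naive_delay_sweep):
        d0 = measure_delay(naive_delay_sweep).delay_ms
        shifted = Sweep(naive_delay_sweep.samples + 3.0,
                        naive_delay_sweep.dt, "voltage",
                        naive_delay_sweep.protocol)
        assert measure_delay(shifted, peak_min_mV=3.0).delay_ms \
            == pytest.approx(d0)


class TestIOCurvesAndJitter:
    def test_initial_frequency_from_first_interval(self):
        dt = 1e-4
        v = np.full(5000, -80.0)
        for pk in (1000, 1500):  # 50 ms apart
            v[pk] = 30.0
        s = Sweep(v, dt, "voltage", StepProtocol(100.0, 0.05, 0.4))
        table = io_curves([s])
        assert table.loc[0, "initial_freq_Hz"] == pytest.approx(20.0)
        v1 = v.copy(); v1[1500] = -80.0
        single = Sweep(v1, dt, "voltage", StepProtocol(100.0, 0.05, 0.4))
        t2 = io_curves([single])
        assert t2.loc[0, "ap_count"] == 1 and not t2.loc[0, "freq_defined"]

    def test_blocked_io_curve_lies_at_or_above_control(self, naive_p):
        amps = (90.0, 140.0, 200.0)
        proto = lambda a: StepProtocol(a, 0.02, 1.0)
        ctrl = io_curves([simulate_current_clamp(naive_p, proto(a), T=1.05)
                          for a in amps], window_s=1.0)
        dtx = io_curves([simulate_current_clamp(
            apply_drug(naive_p, "DTX", 1.0), proto(a), T=1.05)
            for a in amps], window_s=1.0)
        assert (dtx["ap_count"].to_numpy()
                >= ctrl["ap_count"].to_numpy()).all()

    def test_jitter_closed_form_cases(self):
        sd, cv = first_spike_jitter([100.0, 100.0, 100.0])
        assert sd == 0.0 and cv == 0.0
        sd, cv = first_spike_jitter([80.0, 100.0, 120.0])
        assert sd == pytest.approx(20.0)
        assert cv == pytest.approx(0.2)

    def test_jitter_needs_three_spiking_trials(self):
        with pytest.raises(InsufficientDataError):
            first_spike_jitter([DelayResult(100.0, False),
                                DelayResult(float("nan"), True)])

    def test_jitter_sd_shrinks_with_block_while_cv_moves_less(self, naive_p):
        """Under block the absolute first-spike jitter collapses with the
        delay, while the delay-relative jitter (CV) changes far less."""
        def delays(p):
            return [measure_delay(simulate_current_clamp(
                replace(p, noise_sd_pA=10.0, seed=s),
                StepProtocol(80.0, 0.05, 2.0), T=2.1)) for s in range(6)]

        sd_c, cv_c = first_spike_jitter(delays(naive_p))
        sd_d, cv_d = first_spike_jitter(delays(apply_drug(naive_p, "DTX", 1.0)))
        assert sd_d < sd_c
        sd_ratio = sd_c / sd_d
        cv_ratio = max(cv_c, cv_d) / min(cv_c, cv_d)
        assert cv_ratio < sd_ratio


class TestSynapticIO:
    def test_programmed_facilitation_recovered(self):
        from gdelay.dgsim import generate_synaptic_train
        sweep, times = generate_synaptic_train(facilitation_ratio=1.4)
        res = synaptic_io(sweep, times)
        assert res.paired_pulse_ratio == pytest.approx(1.4, rel=0.06)
        assert res.flags == ()

    def test_zero_amplitude_train_flags_ratio_undefined(self):
        s = Sweep(np.zeros(10_000), 1e-4, "voltage")
        res = synaptic_io(s, [0.1, 0.11, 0.12, 0.13, 0.14])
        assert "ratio_undefined" in res.flags
        assert math.isnan(res.paired_pulse_ratio)

    def test_ap_in_first_window_flags_contamination(self):
        dt = 1e-4
        v = np.full(10_000, -75.0)
        v[1050] = 20.0  # spike right after pulse 1
        s = Sweep(v, dt, "voltage")
        res = synaptic_io(s, [0.1, 0.11, 0.12, 0.13, 0.14])
        assert "epsp1_ap_contaminated" in res.flags
        assert res.ap_count >= 1
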