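"""Simulator correctness: passive limits, clamp identities, gating recovery,
pharmacology transforms, fixture generators, and integration convergence."""
import math
from dataclasses import replace

import numpy as np
import pytest

from gdelay import ccfeat, vcfeat
from gdelay.dgsim import (QPCRDesign, SimCellParams, StepProtocol,
                          VCStepProtocol, apply_drug, delay_current_only,
                          generate_qpcr_dataset, generate_roi_image,
                          generate_synaptic_train, naive_params,
                          resting_potential, simulate_current_clamp,
                          simulate_voltage_clamp, steady_ionic_current)
from gdelay.dgsim.model import GateParams
from gdelay.qpcr import ddct_fold


def _passive_params(r_MOhm=600.0, e_l=-82.0):
    return SimCellParams(g_l_nS=1000.0 / r_MOhm, e_l_mV=e_l, g_na_nS=0.0,
                         g_kdr_nS=0.0, g_kir_nS=0.0, g_d_nS=0.0)


class TestCurrentClamp:
    def test_passive_steady_state_matches_ohms_law(self):
        p = _passive_params()
        proto = StepProtocol(-10.0, 0.1, 0.8)
        sweep = simulate_current_clamp(p, proto, T=1.0)
        steady = sweep.samples[int(0.85 / sweep.dt):int(0.9 / sweep.dt)].mean()
        assert steady - (-82.0) == pytest.approx(-6.0, rel=0.01)  # I*R = -6 mV

    def test_identical_seed_gives_bit_identical_traces(self, naive_p):
        p = replace(naive_p, noise_sd_pA=10.0, seed=7)
        proto = StepProtocol(80.0, 0.05, 0.5)
        s1 = simulate_current_clamp(p, proto, T=0.6)
        s2 = simulate_current_clamp(p, proto, T=0.6)
        assert np.array_equal(s1.samples, s2.samples)

    def test_delay_grows_with_delay_conductance_brute_force_check(self, naive_p):
        """3x the delay conductance postpones the first spike; the ordering is
        confirmed by brute-force integration at one-tenth the step size."""
        proto = StepProtocol(300.0, 0.02, 0.12)
        d = {}
        for scale in (1.0, 3.0):
            p = replace(naive_p, g_d_nS=naive_p.g_d_nS * scale)
            d[scale] = ccfeat.measure_delay(
                simulate_current_clamp(p, proto, T=0.15)).delay_ms
            d[(scale, "fine")] = ccfeat.measure_delay(
                simulate_current_clamp(p, proto, dt=2.5e-6, T=0.15)).delay_ms
        assert d[3.0] > d[1.0]
        assert d[(3.0, "fine")] > d[(1.0, "fine")]
        assert d[1.0] == pytest.approx(d[(1.0, "fine")], rel=0.005)

    def test_halving_dt_changes_delay_and_rin_by_under_half_percent(self, naive_p):
        proto = StepProtocol(80.0, 0.05, 1.0)
        d1 = ccfeat.measure_delay(
            simulate_current_clamp(naive_p, proto, dt=25e-6, T=1.1)).delay_ms
        d2 = ccfeat.measure_delay(
            simulate_current_clamp(naive_p, proto, dt=12.5e-6, T=1.1)).delay_ms
        assert abs(d1 - d2) / d2 < 0.005
        small = StepProtocol(-10.0, 0.05, 0.5)
        v1 = simulate_current_clamp(naive_p, small, dt=25e-6, T=0.6)
        v2 = simulate_current_clamp(naive_p, small, dt=12.5e-6, T=0.6)
        ss1 = v1.samples[int(0.5 / v1.dt):int(0.55 / v1.dt)].mean()
        ss2 = v2.samples[int(0.5 / v2.dt):int(0.55 / v2.dt)].mean()
        assert ss1 == pytest.approx(ss2, abs=0.05)

    def test_preset_rests_at_calibrated_potential(self, naive_p):
        sweep = simulate_current_clamp(naive_p, StepProtocol(0.0, 0.1, 0.1),
                                       T=0.5)
        assert sweep.samples[-1] == pytest.approx(-82.4, abs=0.5)


class TestVoltageClamp:
    def test_midpoint_step_yields_half_maximal_current(self):
        """At V50_act with inactivation held open, steady a = 0.5 so the
        clamp current is half of g_D * driving force."""
        p = delay_current_only(SimCellParams(
            g_d_nS=2.0, inact=GateParams(500.0, 14.1, 250.0)))
        proto = VCStepProtocol(-100.0, (p.act.v50_mV,), step_duration_s=0.2)
        sweep = simulate_voltage_clamp(p, proto)[0]
        i0, i1 = vcfeat._step_window(proto, sweep.dt)
        steady = sweep.samples[i1 - 100:i1].mean()
        expected = 0.5 * 2.0 * (p.act.v50_mV - p.e_k_mV)
        assert steady == pytest.approx(expected, rel=0.01)

    def test_step_to_reversal_carries_no_delay_current(self):
        p = delay_current_only(SimCellParams(g_d_nS=2.0))
        proto = VCStepProtocol(-100.0, (p.e_k_mV,), step_duration_s=0.2)
        sweep = simulate_voltage_clamp(p, proto)[0]
        i0, i1 = vcfeat._step_window(proto, sweep.dt)
        assert np.max(np.abs(sweep.samples[i0:i1])) < 1e-9

    def test_current_conservation_at_steady_state(self, naive_p):
        """The reported clamp current equals the closed-form sum of the
        programmed ionic currents once gates have relaxed."""
        proto = VCStepProtocol(-100.0, (-40.0,), step_duration_s=3.0)
        sweep = simulate_voltage_clamp(naive_p, proto)[0]
        i0, i1 = vcfeat._step_window(proto, sweep.dt)
        steady = sweep.samples[i1 - 10:i1].mean()
        p_iso = replace(naive_p, g_na_nS=0.0, g_kdr_nS=0.0)  # clamp cocktail
        expected = steady_ionic_current(p_iso, -40.0)
        assert steady == pytest.approx(expected, rel=0.005)

    def test_subtraction_identity_full_minus_blocked_is_gd_only(
            self, naive_p, activation_proto, naive_activation_subs):
        only = simulate_voltage_clamp(delay_current_only(naive_p),
                                      activation_proto)
        for sub, oracle in zip(naive_activation_subs, only):
            scale = max(np.max(np.abs(oracle.samples)), 1.0)
            rms = np.sqrt(np.mean((sub.trace.samples - oracle.samples) ** 2))
            assert rms / scale < 0.005

    def test_activation_family_recovers_programmed_midpoint(
            self, naive_p, naive_activation_subs):
        pairs = [(s.step_V_mV, vcfeat.extrapolated_amplitude(s))
                 for s in naive_activation_subs]
        fit = vcfeat.fit_activation(pairs, naive_p.e_k_mV)
        assert fit.v50_mV == pytest.approx(naive_p.act.v50_mV, abs=1.0)


class TestPharmacology:
    def test_full_dtx_block_zeroes_delay_conductance(self, naive_p):
        assert apply_drug(naive_p, "DTX", 1.0).g_d_nS == 0.0

    def test_zero_fraction_is_identity(self, naive_p):
        assert apply_drug(naive_p, "4AP", 0.0) == naive_p

    def test_barium_targets_inward_rectifier_only(self, naive_p):
        blocked = apply_drug(naive_p, "barium", 0.5)
        assert blocked.g_kir_nS == pytest.approx(naive_p.g_kir_nS * 0.5)
        assert blocked.g_d_nS == naive_p.g_d_nS

    def test_dtx_shortens_simulated_delay(self, naive_p, naive_delay_sweep):
        ctrl = ccfeat.measure_delay(naive_delay_sweep).delay_ms
        blocked = simulate_current_clamp(
            apply_drug(naive_p, "DTX", 1.0), StepProtocol(80.0, 0.05, 2.0),
            T=2.1)
        assert ccfeat.measure_delay(blocked).delay_ms < ctrl

    def test_unknown_drug_rejected(self, naive_p):
        with pytest.raises(ValueError):
            apply_drug(naive_p, "TTX", 1.0)


class TestQPCRGenerator:
    def test_noise_free_group_difference_equals_programmed_log2_fold(self):
        design = QPCRDesign(n_cells=5, ct_sd=0.0,
                            log2_fold={"Kv1.1": math.log2(6.1)})
        df = generate_qpcr_dataset(design, seed=0)
        kv = df[df["gene"] == "Kv1.1"].groupby("group")["CT"].mean()
        assert kv["naive"] - kv["KA"] == pytest.approx(math.log2(6.1))
        gapdh = df[df["gene"] == "GAPDH"].groupby("group")["CT"].mean()
        assert gapdh["naive"] == pytest.approx(gapdh["KA"])

    def test_ceiling_censors_and_marks_non_detects(self):
        design = QPCRDesign(n_cells=4, ct_sd=0.0,
                            baseline_ct={g: 48.0 for g in
                                         QPCRDesign().baseline_ct},
                            log2_fold={}, detection_ceiling=45.0)
        df = generate_qpcr_dataset(design, seed=0)
        assert (~df["detected"]).all()
        assert df["CT"].isna().all()

    def test_downstream_fold_estimate_recovers_programmed_tenfold(self):
        """Monte-Carlo recovery: 200 cells/group at 1-cycle CT noise; a single
        table scatters ~10% (4 noisy group means enter the double delta), so
        the recovery check averages replicate tables."""
        base = {g: 36.0 for g in QPCRDesign().baseline_ct}
        design = QPCRDesign(n_cells=200, ct_sd=1.0, baseline_ct=base,
                            log2_fold={"Kv1.1": math.log2(10.0)})
        folds = [ddct_fold(generate_qpcr_dataset(design, seed=s),
                           "Kv1.1", case="KA", control="naive").fold
                 for s in range(10)]
        assert np.mean(folds) == pytest.approx(10.0, rel=0.10)


class TestWaveformGenerators:
    def test_synaptic_train_programmed_shape(self):
        sweep, times = generate_synaptic_train(amplitude_pA=30.0,
                                               facilitation_ratio=1.4)
        assert len(times) == 5
        assert np.diff(times) == pytest.approx(np.full(4, 0.01))  # 100 Hz
        # onset-subtracted per-pulse responses honour the facilitation ratio
        res = ccfeat.synaptic_io(sweep, times)
        assert res.paired_pulse_ratio == pytest.approx(1.4, rel=0.06)

    def test_synaptic_train_integral_linear_in_amplitude(self):
        s1, _ = generate_synaptic_train(amplitude_pA=10.0)
        s2, _ = generate_synaptic_train(amplitude_pA=30.0)
        assert s2.samples.sum() == pytest.approx(3 * s1.samples.sum())

    def test_roi_image_band_contrast_exact_without_noise(self):
        img, masks = generate_roi_image(band_gain=1.94, noise_sd=0.0)
        ratio = img[masks["band"]].mean() / img[masks["background"]].mean()
        assert ratio == pytest.approx(1.94)
        profile = np.where(masks["column"], img, 0).sum(axis=1)
        assert abs(int(np.argmax(profile)) - 40) <= 6

    def test_roi_image_gain_recovered_under_noise(self):
        ratios = []
        for seed in range(10):
            img, masks = generate_roi_image(band_gain=1.5, noise_sd=5.0,
                                            seed=seed)
            ratios.append(img[masks["band"]].mean()
                          / img[masks["background"]].mean())
        assert np.mean(ratios) == pytest.approx(1.5, abs=0.05)


def test_nonfinite_state_raises_integration_error():
    from gdelay.errors import IntegrationError
    p = SimCellParams(g_l_nS=0.0, g_na_nS=0.0, g_kdr_nS=0.0, g_kir_nS=0.0,
                      g_d_nS=0.0, c_m_pF=0.001)
    with pytest.raises(IntegrationError, match="step"):
        simulate_current_clamp(p, StepProtocol(1e5, 0.0, 0.1), T=0.1)
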