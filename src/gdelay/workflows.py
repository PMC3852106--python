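"""Canned end-to-end analyses used for validation and reporting.

Each function runs one self-contained computation on synthetic data —
gating-parameter recovery from simulated clamp families, the subtraction
identity, delay phenomenology across conductance scalings, qPCR fold
recovery, correlation detection and calibration checks — and returns plain
numbers. They are deliberately deterministic given their seed arguments.
"""
from __future__ import annotations

import math
from dataclasses import replace
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from . import ccfeat, qpcr, stats_report, vcfeat
from .dgsim import (QPCRDesign, StepProtocol, VCStepProtocol, apply_drug,
                    delay_current_only, generate_qpcr_dataset, presets,
                    simulate_current_clamp, simulate_voltage_clamp)

ACTIVATION_PROTO = VCStepProtocol(
    holding_mV=-100.0, steps_mV=tuple(range(-110, 20, 10)),
    step_duration_s=2.5)
INACTIVATION_PROTO = VCStepProtocol(
    holding_mV=-100.0, steps_mV=(10.0,), step_duration_s=0.5,
    prepulse_mV=tuple(range(-110, 20, 10)), prepulse_duration_s=2.5)
TAU_PROTO = VCStepProtocol(holding_mV=-100.0, steps_mV=(0.0,),
                           step_duration_s=2.5)


def _subtracted_family(p, proto, noise_pA, seed):
    ctrl = simulate_voltage_clamp(p, proto, measurement_noise_pA=noise_pA,
                                  seed=seed)
    drug = simulate_voltage_clamp(apply_drug(p, "DTX", 1.0), proto,
                                  measurement_noise_pA=noise_pA,
                                  seed=seed + 1)
    return vcfeat.subtract_currents(ctrl, drug)


def _family_noise_for_snr(p, snr: float) -> float:
    """Measurement noise giving the requested SNR on the largest family
    amplitude (computed on a noiseless family)."""
    subs = _subtracted_family(p, ACTIVATION_PROTO, 0.0, 0)
    amp = max(abs(vcfeat.extrapolated_amplitude(s)) for s in subs)
    return amp / snr


def gating_recovery(condition: str, n_seeds: int = 50, seed0: int = 0,
                    snr: float = 20.0) -> Dict[str, float]:
    """Recover activation/inactivation midpoints, slopes and tau_inact from
    noisy simulated clamp families; returns the across-seed mean estimates
    alongside the programmed (true) values."""
    p = presets.PRESETS[condition]()
    noise = _family_noise_for_snr(p, snr)
    v50a, ka, v50i, ki, taus = [], [], [], [], []
    for s in range(n_seeds):
        base = seed0 + 10 * s
        subs = _subtracted_family(p, ACTIVATION_PROTO, noise, base)
        pairs = [(sub.step_V_mV, vcfeat.extrapolated_amplitude(sub))
                 for sub in subs]
        # solutions are known here, so the driving force uses the K+ Nernst
        # potential; per-family reversal fits are too uncertain at this SNR
        act = vcfeat.fit_activation(pairs, vcfeat.nernst())
        v50a.append(act.v50_mV)
        ka.append(act.k_mV)

        subs_i = _subtracted_family(p, INACTIVATION_PROTO, noise, base + 2)
        pk = [(vp, vcfeat.extrapolated_amplitude(sub, skip_ms=10.0))
              for vp, sub in zip(INACTIVATION_PROTO.prepulse_mV, subs_i)]
        ina = vcfeat.fit_inactivation(pk)
        v50i.append(ina.v50_mV)
        ki.append(ina.k_mV)

        sub0 = _subtracted_family(p, TAU_PROTO, noise, base + 4)[0]
        taus.append(vcfeat.fit_tau_inact(sub0).tau_ms)
    return {
        "v50_act_mV": float(np.mean(v50a)),
        "k_act_mV": float(np.mean(ka)),
        "v50_inact_mV": float(np.mean(v50i)),
        "k_inact_mV": float(np.mean(ki)),
        "tau_inact_ms": float(np.mean(taus)),
        "true_v50_act_mV": p.act.v50_mV,
        "true_k_act_mV": p.act.k_mV,
        "true_v50_inact_mV": p.inact.v50_mV,
        "true_k_inact_mV": p.inact.k_mV,
        "true_tau_inact_ms": p.inact.tau_ms,
        "n_seeds": n_seeds,
    }


def subtraction_identity_rms(condition: str = "naive") -> float:
    """Worst-case RMS deviation (percent of per-step amplitude) between the
    control-minus-blocker subtraction and the pure delay-current family."""
    p = presets.PRESETS[condition]()
    subs = _subtracted_family(p, ACTIVATION_PROTO, 0.0, 0)
    only = simulate_voltage_clamp(delay_current_only(p), ACTIVATION_PROTO)
    worst = 0.0
    for sub, oracle in zip(subs, only):
        scale = max(float(np.max(np.abs(oracle.samples))), 1.0)
        rms = float(np.sqrt(np.mean((sub.trace.samples - oracle.samples) ** 2)))
        worst = max(worst, 100.0 * rms / scale)
    return worst


def delay_phenomenology(gd_scalings: Sequence[float] = (0.1, 0.3, 1.0, 3.0, 10.0),
                        scaling_step_pA: float = 300.0,
                        amplitudes_pA: Sequence[float] = (80.0, 130.0, 200.0, 250.0),
                        io_amplitudes_pA: Sequence[float] = (90.0, 140.0, 200.0),
                        ) -> Dict[str, object]:
    """Deterministic (noise-free) twin of the current-clamp pharmacology:
    delay vs conductance scaling, delay vs step amplitude, collapse onto the
    zero-conductance curve under full block, and blocked-vs-control I/O
    counts."""
    p = presets.naive_params()

    def delay(params, amp, window=2.0):
        sweep = simulate_current_clamp(params, StepProtocol(amp, 0.05, 2.0),
                                       T=2.1)
        return ccfeat.measure_delay(sweep, window_s=window).delay_ms

    delays_vs_gd = [delay(replace(p, g_d_nS=p.g_d_nS * s), scaling_step_pA)
                    for s in gd_scalings]
    delays_vs_amp = [delay(p, a) for a in amplitudes_pA]
    blocked = apply_drug(p, "DTX", 1.0)
    zero_gd = replace(p, g_d_nS=0.0)
    collapse = [(delay(blocked, a), delay(zero_gd, a)) for a in amplitudes_pA[:2]]

    def counts(params):
        sweeps = [simulate_current_clamp(params, StepProtocol(a, 0.02, 1.0),
                                         T=1.05) for a in io_amplitudes_pA]
        return ccfeat.io_curves(sweeps, window_s=1.0)["ap_count"].to_numpy()

    return {
        "gd_scalings": list(gd_scalings),
        "delays_vs_gd_ms": delays_vs_gd,
        "amplitudes_pA": list(amplitudes_pA),
        "delays_vs_amp_ms": delays_vs_amp,
        "blocked_vs_zero_gd_ms": collapse,
        "io_counts_control": counts(p).tolist(),
        "io_counts_blocked": counts(blocked).tolist(),
    }


def qpcr_fold_recovery(programmed_fold: float = 10.0, n_cells: int = 200,
                       ct_sd: float = 1.0, n_tables: int = 10,
                       seed0: int = 0) -> float:
    """Mean recovered fold over replicate synthetic CT tables (pearl-like
    baselines well below the detection ceiling)."""
    base = {g: 36.0 for g in QPCRDesign().baseline_ct}
    design = QPCRDesign(n_cells=n_cells, ct_sd=ct_sd, baseline_ct=base,
                        log2_fold={"Kv1.1": math.log2(programmed_fold)})
    folds = []
    for s in range(n_tables):
        df = generate_qpcr_dataset(design, seed=seed0 + s)
        kept, _ = qpcr.qc_filter(df)
        folds.append(qpcr.ddct_fold(kept, "Kv1.1", case="KA",
                                    control="naive").fold)
    return float(np.mean(folds))


def correlation_detection(seed: int = 0, n_per_group: int = 32) -> tuple:
    """Delay-vs-Kv1.1-expression correlation on a latent-factor cohort."""
    feats, cts = stats_report.build_cohort(n_per_group=n_per_group, seed=seed)
    spiking = feats[~feats["censored"]]
    return qpcr.correlate_phenotype_expression(spiking, cts, "Kv1.1")


def null_correlation_fpr(n_reps: int = 1000, n_cells: int = 20,
                         alpha: float = 0.05, seed0: int = 0) -> float:
    """False-positive rate of the phenotype-expression correlation on
    independent (null) delay and CT draws."""
    rng = np.random.default_rng(seed0)
    hits = 0
    for _ in range(n_reps):
        ids = [f"c{i}" for i in range(n_cells)]
        feats = pd.DataFrame({"cell_id": ids,
                              "delay_ms": rng.normal(400, 100, n_cells)})
        cts = pd.DataFrame({
            "sample_id": [f"{c}:Kv1.1" for c in ids],
            "gene": "Kv1.1",
            "CT": rng.normal(42, 1, n_cells),
            "detected": True, "group": "naive", "level": "single_cell",
            "melt_ok": True, "primer_dimer": False, "linked_cell_id": ids,
        })
        _, _, p = qpcr.correlate_phenotype_expression(feats, cts, "Kv1.1")
        hits += p < alpha
    return hits / n_reps


def two_group_type1_rate(n_reps: int = 2000, n: int = 10,
                         alpha: float = 0.05, seed: int = 0) -> float:
    """Empirical type-I error of the normality-gated two-group test on a
    normal null."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        res = stats_report.choose_and_run_two_group(rng.normal(0, 1, n),
                                                    rng.normal(0, 1, n))
        hits += res.p < alpha
    return hits / n_reps
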