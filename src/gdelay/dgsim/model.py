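"""Single-compartment conductance-based granule-cell model.

The membrane follows  C_m dV/dt = -(I_L + I_Na + I_Kdr + I_Kir + I_D) + I_inj + I_noise
with a slowly inactivating, subthreshold delay current

    I_D = g_D * a * b * (V - E_K)

whose activation gate a (increasing with V) and inactivation gate b
(decreasing with V) relax exponentially toward Boltzmann steady states

    a_inf(V) = 1 / (1 + exp((V50_act - V) / k_act))
    b_inf(V) = 1 / (1 + exp((V - V50_inact) / k_inact))

with fixed time constants tau_act and tau_inact (both k > 0). Spike currents
use Hodgkin-Huxley style Na/K-dr rate functions (hippocampal-interneuron
kinetics with instantaneous Na activation); the inward rectifier is modelled
as an instantaneous Boltzmann conductance. Current clamp is integrated with a
fixed-step scheme (exponential Euler for gates, explicit update for V,
dt = 25 us by default). Voltage clamp is solved exactly: with a
piecewise-constant command potential every gate ODE is a closed-form
exponential relaxation, so clamp currents carry no integration error.

Internal units: mV, pA, nS, pF, ms (1 nS * 1 mV = 1 pA; pF/nS = ms).
Public time arguments are in seconds to match the sweep containers.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from ..errors import IntegrationError
from ..trace_io import Sweep, StepProtocol, VCStepProtocol


@dataclass(frozen=True)
class GateParams:
    """Boltzmann gate: half-potential (mV), slope factor (mV, > 0), tau (ms)."""

    v50_mV: float
    k_mV: float
    tau_ms: float

    def __post_init__(self) -> None:
        if not self.k_mV > 0:
            raise ValueError(f"slope factor must be > 0, got {self.k_mV}")
        if not self.tau_ms > 0:
            raise ValueError(f"tau must be > 0, got {self.tau_ms}")


@dataclass(frozen=True)
class SimCellParams:
    """Full parameterization of the model cell.

    Conductances in nS, capacitance in pF, potentials in mV. ``noise_sd_pA``
    is the stationary standard deviation of an Ornstein-Uhlenbeck current
    noise with correlation time ``noise_tau_ms`` (dt-robust, unlike white
    noise injected per step).
    """

    c_m_pF: float = 88.0
    g_l_nS: float = 1.6
    e_l_mV: float = -80.0
    g_na_nS: float = 3000.0
    e_na_mV: float = 55.0
    g_kdr_nS: float = 800.0
    spike_v_shift_mV: float = 20.0
    g_kir_nS: float = 0.4
    kir_v50_mV: float = -90.0
    kir_k_mV: float = 10.0
    g_d_nS: float = 1.0
    act: GateParams = field(default_factory=lambda: GateParams(-32.3, 17.1, 5.0))
    inact: GateParams = field(default_factory=lambda: GateParams(-41.7, 14.1, 250.0))
    e_k_mV: float = -104.3
    noise_sd_pA: float = 0.0
    noise_tau_ms: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("c_m_pF",):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("g_l_nS", "g_na_nS", "g_kdr_nS", "g_kir_nS", "g_d_nS"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sd_pA < 0:
            raise ValueError("noise_sd_pA must be >= 0")


# ---------------------------------------------------------------------------
# Steady-state helpers
# ---------------------------------------------------------------------------

def _boltz_inc(v: float, v50: float, k: float) -> float:
    """Increasing Boltzmann, 1/(1+exp((v50-v)/k))."""
    return 1.0 / (1.0 + math.exp((v50 - v) / k))


def _boltz_dec(v: float, v50: float, k: float) -> float:
    """Decreasing Boltzmann, 1/(1+exp((v-v50)/k))."""
    return 1.0 / (1.0 + math.exp((v - v50) / k))


def _na_m_inf(v: float) -> float:
    u = v + 35.0
    am = 1.0 if abs(u) < 1e-9 else 0.1 * u / (1.0 - math.exp(-u / 10.0))
    bm = 4.0 * math.exp(-(v + 60.0) / 18.0)
    return am / (am + bm)


def _na_h(v: float) -> tuple:
    ah = 0.35 * math.exp(-(v + 58.0) / 20.0)
    bh = 5.0 / (1.0 + math.exp(-(v + 28.0) / 10.0))
    s = ah + bh
    return ah / s, 1.0 / s  # h_inf, tau_h (ms)


def _kdr_n(v: float) -> tuple:
    u = v + 34.0
    an = 0.5 if abs(u) < 1e-9 else 0.05 * u / (1.0 - math.exp(-u / 10.0))
    bn = 0.625 * math.exp(-(v + 44.0) / 80.0)
    s = an + bn
    return an / s, 1.0 / s  # n_inf, tau_n (ms)


def steady_ionic_current(p: SimCellParams, v: float,
                         include_leak: bool = True) -> float:
    """Total steady-state ionic current (pA, outward positive) at potential v."""
    vs = v - p.spike_v_shift_mV  # spike-current kinetics are shifted depolarized
    m = _na_m_inf(vs)
    h_inf, _ = _na_h(vs)
    n_inf, _ = _kdr_n(vs)
    i = p.g_na_nS * m ** 3 * h_inf * (v - p.e_na_mV)
    i += p.g_kdr_nS * n_inf ** 4 * (v - p.e_k_mV)
    i += p.g_kir_nS * _boltz_dec(v, p.kir_v50_mV, p.kir_k_mV) * (v - p.e_k_mV)
    a = _boltz_inc(v, p.act.v50_mV, p.act.k_mV)
    b = _boltz_dec(v, p.inact.v50_mV, p.inact.k_mV)
    i += p.g_d_nS * a * b * (v - p.e_k_mV)
    if include_leak:
        i += p.g_l_nS * (v - p.e_l_mV)
    return i


def resting_potential(p: SimCellParams, lo: float = -120.0, hi: float = -70.0) -> float:
    """Zero of the steady-state I-V relation in the subthreshold range.

    The upper bound stays below the persistent-Na window region so the
    bracket captures the stable resting fixed point only.
    """
    return brentq(lambda v: steady_ionic_current(p, v), lo, hi, xtol=1e-10)


def calibrate_passive(p: SimCellParams, v_rest_mV: float,
                      r_in_MOhm: float) -> SimCellParams:
    """Solve for (g_L, E_L) so the cell rests at ``v_rest_mV`` with the
    requested input resistance.

    The leak conductance absorbs whatever slope the voltage-gated currents do
    not provide at rest: g_L = 1000/R_in - dI_other/dV|_rest, and E_L then
    balances the standing current. Raises if the gated currents alone already
    exceed the target conductance.
    """
    g_target_nS = 1000.0 / r_in_MOhm
    eps = 1e-3
    other = lambda v: steady_ionic_current(p, v, include_leak=False)
    slope = (other(v_rest_mV + eps) - other(v_rest_mV - eps)) / (2 * eps)
    g_l = g_target_nS - slope
    if g_l <= 0:
        raise ValueError(
            f"gated currents supply {slope:.3f} nS at rest, above the "
            f"{g_target_nS:.3f} nS target; reduce g_D/g_Kir"
        )
    e_l = v_rest_mV + other(v_rest_mV) / g_l
    return replace(p, g_l_nS=g_l, e_l_mV=e_l)


# ---------------------------------------------------------------------------
# Current clamp
# ---------------------------------------------------------------------------

def simulate_current_clamp(p: SimCellParams, proto: StepProtocol,
                           dt: float = 25e-6, T: Optional[float] = None) -> Sweep:
    """Integrate the current-clamp response to a square step.

    dt and T in seconds; dt must be <= 50 us for gate stability. Returns a
    voltage Sweep sampled at every integration step. Deterministic given
    ``p.seed``.
    """
    if dt > 50e-6:
        raise ValueError("dt must be <= 50 us")
    if T is None:
        T = proto.onset_s + proto.duration_s + 0.1
    if T < proto.onset_s + proto.duration_s:
        raise ValueError("T must cover the stimulus")
    nsteps = int(round(T / dt))
    dtms = dt * 1e3

    v = resting_potential(p)
    shift = p.spike_v_shift_mV
    h, _ = _na_h(v - shift)
    nn, _ = _kdr_n(v - shift)
    a = _boltz_inc(v, p.act.v50_mV, p.act.k_mV)
    b = _boltz_dec(v, p.inact.v50_mV, p.inact.k_mV)

    i0, i1 = int(round(proto.onset_s / dt)), int(round((proto.onset_s + proto.duration_s) / dt))
    hold, amp = proto.holding_pA, proto.amplitude_pA

    # locals for the hot loop
    E = math.exp
    gl, el = p.g_l_nS, p.e_l_mV
    gna, ena = p.g_na_nS, p.e_na_mV
    gkdr, gkir, gd, ek = p.g_kdr_nS, p.g_kir_nS, p.g_d_nS, p.e_k_mV
    kv50, kk = p.kir_v50_mV, p.kir_k_mV
    av50, ak = p.act.v50_mV, p.act.k_mV
    bv50, bk = p.inact.v50_mV, p.inact.k_mV
    ea = E(-dtms / p.act.tau_ms)
    eb = E(-dtms / p.inact.tau_ms)
    inv_cm = dtms / p.c_m_pF

    if p.noise_sd_pA > 0:
        en = E(-dtms / p.noise_tau_ms)
        q = p.noise_sd_pA * math.sqrt(1.0 - en * en)
        normals = np.random.default_rng(p.seed).standard_normal(nsteps).tolist()
    else:
        en = q = 0.0
        normals = None
    w = 0.0

    out = np.empty(nsteps)
    for i in range(nsteps):
        out[i] = v
        vs = v - shift  # spike-current kinetics, depolarized-shifted
        # Na activation (instantaneous)
        u = vs + 35.0
        am = 1.0 if -1e-9 < u < 1e-9 else 0.1 * u / (1.0 - E(-u * 0.1))
        bm = 4.0 * E(-(vs + 60.0) / 18.0)
        m = am / (am + bm)
        # Na inactivation / Kdr activation (exponential Euler)
        ah = 0.35 * E(-(vs + 58.0) * 0.05)
        bh = 5.0 / (1.0 + E(-(vs + 28.0) * 0.1))
        s = ah + bh
        h = ah / s + (h - ah / s) * E(-dtms * s)
        u = vs + 34.0
        an = 0.5 if -1e-9 < u < 1e-9 else 0.05 * u / (1.0 - E(-u * 0.1))
        bn = 0.625 * E(-(vs + 44.0) / 80.0)
        s = an + bn
        nn = an / s + (nn - an / s) * E(-dtms * s)
        # delay-current gates (fixed tau)
        a = (ainf := 1.0 / (1.0 + E((av50 - v) / ak))) + (a - ainf) * ea
        b = (binf := 1.0 / (1.0 + E((v - bv50) / bk))) + (b - binf) * eb

        iion = gl * (v - el)
        iion += gna * m * m * m * h * (v - ena)
        vk = v - ek
        iion += (gkdr * nn * nn * nn * nn
                 + gkir / (1.0 + E((v - kv50) / kk))
                 + gd * a * b) * vk
        iinj = (hold + amp) if i0 <= i < i1 else hold
        v += inv_cm * (iinj + w - iion)
        if not -200.0 < v < 200.0:
            raise IntegrationError(
                f"non-finite or diverging V at step {i} (t={i * dt:.6f} s)"
            )
        if normals is not None:
            w = w * en + q * normals[i]
    return Sweep(out, dt, "voltage", proto)


# ---------------------------------------------------------------------------
# Voltage clamp (exact piecewise-exponential solution)
# ---------------------------------------------------------------------------

def _clamp_segment_current(p: SimCellParams, v: float, n: int, dt_ms: float,
                           a0: float, b0: float):
    """Current samples over one constant-voltage segment, plus end gate values."""
    t = np.arange(n) * dt_ms
    ainf = _boltz_inc(v, p.act.v50_mV, p.act.k_mV)
    binf = _boltz_dec(v, p.inact.v50_mV, p.inact.k_mV)
    a = ainf + (a0 - ainf) * np.exp(-t / p.act.tau_ms)
    b = binf + (b0 - binf) * np.exp(-t / p.inact.tau_ms)
    i = p.g_l_nS * (v - p.e_l_mV)
    i += p.g_kir_nS * _boltz_dec(v, p.kir_v50_mV, p.kir_k_mV) * (v - p.e_k_mV)
    i = i + p.g_d_nS * a * b * (v - p.e_k_mV)
    dur = n * dt_ms
    a_end = ainf + (a0 - ainf) * math.exp(-dur / p.act.tau_ms)
    b_end = binf + (b0 - binf) * math.exp(-dur / p.inact.tau_ms)
    return i, a_end, b_end


def simulate_voltage_clamp(p: SimCellParams, proto: VCStepProtocol,
                           dt: float = 5e-5,
                           measurement_noise_pA: float = 0.0,
                           seed: Optional[int] = None) -> list:
    """Ideal-clamp current families for a step protocol.

    Models the pharmacologically isolated configuration (spike conductances
    blocked): the recorded current is leak + Kir + I_D. Gates start from the
    holding-potential steady state; each constant-voltage segment is solved in
    closed form. Optional additive Gaussian measurement noise (seeded).
    """
    rng = np.random.default_rng(p.seed if seed is None else seed)
    dt_ms = dt * 1e3
    n_family = len(proto.prepulse_mV) if proto.prepulse_mV else len(proto.steps_mV)
    sweeps = []
    for i in range(n_family):
        vstep = proto.steps_mV[i] if len(proto.steps_mV) > 1 else proto.steps_mV[0]
        segs = [(proto.holding_mV, proto.onset_s)]
        if proto.prepulse_mV:
            segs.append((proto.prepulse_mV[i], proto.prepulse_duration_s))
        segs.append((vstep, proto.step_duration_s))
        segs.append((proto.holding_mV, 0.05))

        a = _boltz_inc(proto.holding_mV, p.act.v50_mV, p.act.k_mV)
        b = _boltz_dec(proto.holding_mV, p.inact.v50_mV, p.inact.k_mV)
        chunks = []
        for v, dur in segs:
            n = int(round(dur / dt))
            cur, a, b = _clamp_segment_current(p, v, n, dt_ms, a, b)
            chunks.append(cur)
        samples = np.concatenate(chunks)
        if measurement_noise_pA > 0:
            samples = samples + rng.normal(0.0, measurement_noise_pA, samples.size)
        sweeps.append(Sweep(samples, dt, "current", proto))
    return sweeps


# ---------------------------------------------------------------------------
# Pharmacology as parameter transforms
# ---------------------------------------------------------------------------

_DRUG_TARGETS = {"DTX": "g_d_nS", "4AP": "g_d_nS", "barium": "g_kir_nS"}


def apply_drug(p: SimCellParams, drug: str, fraction_block: float) -> SimCellParams:
    """Scale the targeted conductance by (1 - fraction_block).

    DTX and 4-AP block the delay conductance; barium blocks the inward
    rectifier. Pure parameter transform — traces are never mutated.
    """
    if drug not in _DRUG_TARGETS:
        raise ValueError(f"unknown drug {drug!r}; expected one of {sorted(_DRUG_TARGETS)}")
    if not 0.0 <= fraction_block <= 1.0:
        raise ValueError("fraction_block must be in [0, 1]")
    target = _DRUG_TARGETS[drug]
    return replace(p, **{target: getattr(p, target) * (1.0 - fraction_block)})


def delay_current_only(p: SimCellParams) -> SimCellParams:
    """Copy of ``p`` with every conductance except g_D removed.

    Voltage clamp of this cell is the exact I_D waveform — the oracle for
    subtraction pharmacology.
    """
    return replace(p, g_l_nS=0.0, g_na_nS=0.0, g_kdr_nS=0.0, g_kir_nS=0.0)
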