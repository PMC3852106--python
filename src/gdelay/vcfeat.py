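"""Voltage-clamp characterization of the dendrotoxin-sensitive delay current.

The isolated current is obtained by offline subtraction of the post-blocker
family from the control family (matched protocols). Peak currents per test
potential are converted to conductance with the fitted (or Nernst) reversal
potential and fitted with Boltzmann functions:

    activation    G/G_max = 1 / (1 + exp((V50 - V) / k))
    inactivation  I/I_max = 1 / (1 + exp((V - V50) / k))

both with k > 0 (activation rises, inactivation falls with depolarization).
Inactivation kinetics come from a mono-exponential fit to the subtracted
current during a long step to 0 mV; the reversal potential from a linear fit
to peak currents on the hyperpolarized limb; and the K+ Nernst potential from
the recording solutions as an independent reference.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, ProtocolMismatchError
from .trace_io import Sweep, VCStepProtocol

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.31446  # J/(mol K)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubtractedCurrent:
    """Blocker-sensitive current at one test potential."""

    trace: Sweep
    peak_pA: float
    step_V_mV: float
    density_pA_per_pF: Optional[float] = None

    def with_density(self, c_m_pF: float) -> "SubtractedCurrent":
        return SubtractedCurrent(self.trace, self.peak_pA, self.step_V_mV,
                                 self.peak_pA / c_m_pF)


@dataclass(frozen=True)
class BoltzmannFit:
    v50_mV: float
    k_mV: float
    scale: float          # G_max (activation) or I_max (inactivation)
    residual: float
    increasing: bool      # True for activation convention

    def __post_init__(self) -> None:
        if not self.k_mV > 0:
            raise ValueError("slope factor must be > 0")

    def __call__(self, v) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        sign = 1.0 if self.increasing else -1.0
        return self.scale / (1.0 + np.exp(sign * (self.v50_mV - v) / self.k_mV))


@dataclass(frozen=True)
class ExpFit:
    tau_ms: float
    amplitude_pA: float
    offset_pA: float
    residual: float


@dataclass(frozen=True)
class ReversalFit:
    v_rev_mV: float
    slope_nS: float
    fit_range_mV: tuple
    v_rev_se_mV: float
    wide_ci: bool


@dataclass(frozen=True)
class IonSolution:
    """Potassium concentrations (mM) and temperature (K) of a recording
    configuration. Defaults: 155 mM pipette K+, 2.5 mM bath K+, 293.15 K."""

    k_in_mM: float = 155.0
    k_out_mM: float = 2.5
    temperature_K: float = 293.15

    def __post_init__(self) -> None:
        if self.k_in_mM <= 0 or self.k_out_mM <= 0 or self.temperature_K <= 0:
            raise ValueError("concentrations and temperature must be > 0")


# ---------------------------------------------------------------------------
# Subtraction pharmacology
# ---------------------------------------------------------------------------

def _step_window(proto: VCStepProtocol, dt: float) -> tuple:
    """Sample indices of the test-step segment within a clamp sweep."""
    t0 = proto.onset_s
    if proto.prepulse_mV:
        t0 += proto.prepulse_duration_s
    i0 = int(round(t0 / dt))
    i1 = i0 + int(round(proto.step_duration_s / dt))
    return i0, i1


def subtract_currents(ctrl: Sequence[Sweep], drug: Sequence[Sweep],
                      blank_ms: float = 5.0) -> list:
    """Pointwise control-minus-blocker subtraction per matched step.

    Protocols must match exactly (same steps, dt, durations); mismatches
    raise with the offending steps listed. The peak is the signed extremum of
    the subtracted trace within the test step, excluding the first
    ``blank_ms`` after the step transition (capacitive-artifact blanking).
    """
    if len(ctrl) != len(drug):
        raise ProtocolMismatchError(
            f"family sizes differ: {len(ctrl)} control vs {len(drug)} drug sweeps"
        )
    out = []
    for i, (c, d) in enumerate(zip(ctrl, drug)):
        if c.protocol != d.protocol:
            raise ProtocolMismatchError(
                f"sweep {i}: protocols differ ({c.protocol} vs {d.protocol})"
            )
        if not math.isclose(c.dt, d.dt) or c.samples.size != d.samples.size:
            raise ProtocolMismatchError(f"sweep {i}: dt or length differs")
        proto = c.protocol
        if not isinstance(proto, VCStepProtocol):
            raise TypeError("subtraction needs voltage-clamp protocols")
        diff = c.samples - d.samples
        i0, i1 = _step_window(proto, c.dt)
        i0b = i0 + int(round(blank_ms * 1e-3 / c.dt))
        seg = diff[i0b:min(i1, diff.size)]
        if seg.size == 0:
            raise ProtocolMismatchError(f"sweep {i}: empty step window")
        peak = float(seg[np.argmax(np.abs(seg))])
        if len(proto.steps_mV) > 1:
            step_v = proto.steps_mV[i]
        else:
            step_v = proto.steps_mV[0]
        out.append(SubtractedCurrent(
            Sweep(diff, c.dt, "current", proto), peak, float(step_v)))
    return out


def current_density(sub: SubtractedCurrent, c_m_pF: float) -> float:
    """Peak current normalized by cell capacitance (pA/pF)."""
    if not c_m_pF > 0:
        raise ValueError("C_m must be > 0")
    return sub.peak_pA / c_m_pF


# ---------------------------------------------------------------------------
# Boltzmann fits
# ---------------------------------------------------------------------------

def _boltzmann_lsq(v: np.ndarray, y: np.ndarray, increasing: bool,
                   k0_mV: float = 15.0, n_restarts: int = 5,
                   sigma: Optional[np.ndarray] = None) -> tuple:
    """Multi-start (weighted) least squares of scale/(1+exp(+/-(V50-v)/k))."""
    sign = 1.0 if increasing else -1.0

    def model(v, v50, k, scale):
        return scale / (1.0 + np.exp(np.clip(sign * (v50 - v) / k, -500, 500)))

    scale0 = float(np.max(np.abs(y)))
    if scale0 == 0:
        raise FitError("all-zero observations admit no Boltzmann fit")
    half = 0.5 * scale0
    idx = int(np.argmin(np.abs(np.abs(y) - half)))
    v50_0 = float(v[idx])
    rng = np.random.default_rng(12345)
    best = None
    starts = [(v50_0, k0_mV, scale0)]
    for _ in range(n_restarts - 1):
        starts.append((v50_0 + rng.normal(0, 8), k0_mV * rng.uniform(0.5, 2),
                       scale0 * rng.uniform(0.8, 1.2)))
    w = np.ones_like(y) if sigma is None else 1.0 / sigma
    for p0 in starts:
        try:
            popt, _ = curve_fit(model, v, y, p0=p0, maxfev=20000, sigma=sigma,
                                bounds=([-150, 0.5, 0], [100, 80, np.inf]))
        except (RuntimeError, ValueError):
            continue
        ssr = float(np.sum((w * (model(v, *popt) - y)) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt)
    if best is None:
        raise FitError("Boltzmann fit did not converge from any start")
    return best[1], best[0]


def fit_activation(peaks: Sequence[tuple], v_rev_mV: float) -> BoltzmannFit:
    """Activation curve from (V, peak I) pairs.

    Currents are transformed to conductance G = I/(V - V_rev) and fitted with
    the increasing Boltzmann. Points are weighted by driving force: a fixed
    current error maps to a conductance error proportional to 1/|V - V_rev|,
    so near-reversal points carry correspondingly little weight. Requires
    >= 5 test potentials spanning the rise.
    """
    if len(peaks) < 5:
        raise FitError(f"activation fit needs >= 5 voltages, got {len(peaks)}")
    v = np.array([p[0] for p in peaks], dtype=float)
    i = np.array([p[1] for p in peaks], dtype=float)
    df = v - v_rev_mV
    keep = np.abs(df) >= 1.0   # drop points at the reversal (0/0)
    v, i, df = v[keep], i[keep], df[keep]
    g = i / df
    (v50, k, scale), ssr = _boltzmann_lsq(v, g, increasing=True,
                                          sigma=1.0 / np.abs(df))
    return BoltzmannFit(float(v50), float(k), float(scale), ssr, True)


def fit_inactivation(prepulse_peaks: Sequence[tuple]) -> BoltzmannFit:
    """Steady-state inactivation from (prepulse V, test-pulse peak I) pairs,
    normalized to the largest response and fitted with the decreasing
    Boltzmann."""
    if len(prepulse_peaks) < 5:
        raise FitError(
            f"inactivation fit needs >= 5 prepulses, got {len(prepulse_peaks)}"
        )
    v = np.array([p[0] for p in prepulse_peaks], dtype=float)
    i = np.array([p[1] for p in prepulse_peaks], dtype=float)
    imax = float(np.max(np.abs(i)))
    if imax == 0:
        raise FitError("all-zero test currents admit no inactivation fit")
    y = i / imax
    (v50, k, scale), ssr = _boltzmann_lsq(v, y, increasing=False)
    return BoltzmannFit(float(v50), float(k), float(scale), ssr, False)


def fit_tau_inact(sub: SubtractedCurrent, window_after_peak_ms: float = 5.0,
                  flat_eps_pA: float = 1e-6) -> ExpFit:
    """Mono-exponential inactivation time constant of the subtracted current
    during a long depolarizing step.

    Fits I(t) = A exp(-t/tau) + C starting ``window_after_peak_ms`` after the
    in-step peak. A flat trace admits no decay and raises.
    """
    dt = sub.trace.dt
    proto = sub.trace.protocol
    i0, i1 = _step_window(proto, dt)
    seg = sub.trace.samples[i0:min(i1, sub.trace.samples.size)]
    pk = int(np.argmax(np.abs(seg)))
    start = pk + int(round(window_after_peak_ms * 1e-3 / dt))
    y = seg[start:]
    if y.size < 10:
        raise FitError("too few samples after the peak for a decay fit")
    if float(np.ptp(y)) < flat_eps_pA:
        raise FitError("trace is flat: no measurable inactivation decay")
    t = np.arange(y.size) * dt * 1e3
    if y.size > 4000:
        stride = y.size // 4000
        t, y = t[::stride], y[::stride]

    def model(t, a, tau, c):
        return a * np.exp(np.clip(-t / tau, -500.0, 500.0)) + c

    a0 = y[0] - y[-1]
    best = None
    for tau0 in (50.0, 150.0, 400.0, 1000.0):
        try:
            popt, _ = curve_fit(model, t, y, p0=[a0, tau0, y[-1]], maxfev=20000)
        except RuntimeError:
            continue
        ssr = float(np.sum((model(t, *popt) - y) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt)
    if best is None:
        raise FitError("exponential fit did not converge")
    ssr, (a, tau, c) = best
    return ExpFit(float(abs(tau)), float(a), float(c), ssr)


def extrapolated_amplitude(sub: SubtractedCurrent,
                           skip_ms: float = 25.0) -> float:
    """Onset-extrapolated current amplitude of a subtracted step response.

    The raw in-step peak underestimates the available current at depolarized
    steps because inactivation has already begun by peak time, and by a
    voltage-dependent amount. Fitting I(t) = A exp(-t/tau) + C after the
    activation rise (first ``skip_ms`` skipped) and evaluating at step onset
    removes that bias: the extrapolate equals the fully activated,
    non-inactivated amplitude. Falls back to the raw peak when the decay fit
    is ill-conditioned (tiny currents near the reversal).
    """
    dt = sub.trace.dt
    i0, i1 = _step_window(sub.trace.protocol, dt)
    seg = sub.trace.samples[i0 + int(round(skip_ms * 1e-3 / dt)):
                            min(i1, sub.trace.samples.size)]
    if seg.size < 20 or float(np.ptp(seg)) < 1e-12:
        return sub.peak_pA
    t = np.arange(seg.size) * dt * 1e3 + skip_ms
    if seg.size > 2000:   # decimate: the fit needs resolution, not 20 kHz
        stride = seg.size // 2000
        t, seg = t[::stride], seg[::stride]

    def model(t, a, tau, c):
        return a * np.exp(np.clip(-t / tau, -500.0, 500.0)) + c

    scale = max(float(np.max(np.abs(seg))), 1e-9)
    # tau must be resolvable beyond the skipped rise, else the extrapolation
    # to t = 0 is unconstrained and can blow up on noise
    tau_lo = 2.0 * skip_ms
    try:
        popt, _ = curve_fit(
            model, t, seg, p0=[seg[0] - seg[-1], max(300.0, tau_lo), seg[-1]],
            bounds=([-10 * scale, tau_lo, -10 * scale],
                    [10 * scale, 1e4, 10 * scale]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return sub.peak_pA
    a, tau, c = popt
    if not np.isfinite([a, tau, c]).all() or abs(a + c) > 3.0 * scale:
        return sub.peak_pA
    return float(a + c)


def activation_curve(subs: Sequence[SubtractedCurrent], v_rev_mV: float,
                     amplitude: str = "extrapolated") -> BoltzmannFit:
    """Activation Boltzmann from a family of subtracted currents.

    ``amplitude`` selects the per-step current estimate: "extrapolated"
    (onset-extrapolated, inactivation-corrected; default) or "peak" (raw
    signed extremum).
    """
    if amplitude == "extrapolated":
        pairs = [(s.step_V_mV, extrapolated_amplitude(s)) for s in subs]
    elif amplitude == "peak":
        pairs = [(s.step_V_mV, s.peak_pA) for s in subs]
    else:
        raise ValueError(f"unknown amplitude estimator {amplitude!r}")
    return fit_activation(pairs, v_rev_mV)


# ---------------------------------------------------------------------------
# Reversal potential and Nernst
# ---------------------------------------------------------------------------

def estimate_reversal(peaks: Sequence[tuple],
                      fit_range_mV: tuple = (-110.0, -80.0),
                      wide_ci_mV: float = 10.0) -> ReversalFit:
    """Linear fit of peak current vs potential; V_rev is the zero crossing.

    The default range keeps to the most hyperpolarized limb, bracketing the
    crossing: further depolarized the Boltzmann growth of the activation gate
    curves the I-V upward and drags the straight-line crossing toward
    depolarized values. Pass a wider range to reproduce whole-family fits. A
    standard error of the crossing above ``wide_ci_mV`` sets the
    wide-confidence flag.
    """
    pts = [(v, i) for v, i in peaks if fit_range_mV[0] - 1e-9 <= v <= fit_range_mV[1] + 1e-9]
    if len(pts) < 2:
        raise FitError(f"reversal fit needs >= 2 points in {fit_range_mV}")
    v = np.array([p[0] for p in pts])
    i = np.array([p[1] for p in pts])
    if len(pts) > 3:
        coef, cov = np.polyfit(v, i, 1, cov=True)
    else:
        coef, cov = np.polyfit(v, i, 1), None
    slope, intercept = coef
    if slope == 0:
        raise FitError("zero slope: no reversal crossing")
    v_rev = -intercept / slope
    if cov is not None:
        # first-order error propagation of -b/a
        var = (cov[1, 1] / slope ** 2
               + intercept ** 2 * cov[0, 0] / slope ** 4
               - 2 * intercept * cov[0, 1] / slope ** 3)
        se = math.sqrt(max(var, 0.0))
    else:
        se = math.inf
    return ReversalFit(float(v_rev), float(slope), tuple(fit_range_mV),
                       float(se), bool(se > wide_ci_mV))


def driving_reference(peaks: Sequence[tuple],
                      sol: Optional[IonSolution] = None,
                      **reversal_kwargs) -> float:
    """Reversal potential to use for driving-force conversion.

    Uses the fitted reversal when it is well-determined; otherwise falls back
    to the K+ Nernst potential of the recording solutions — small
    hyperpolarized-limb currents often leave the linear fit too uncertain to
    anchor conductance transforms.
    """
    sol = sol or IonSolution()
    try:
        rev = estimate_reversal(peaks, **reversal_kwargs)
    except FitError:
        return nernst(sol)
    if rev.wide_ci or not -130.0 < rev.v_rev_mV < -70.0:
        return nernst(sol)
    return rev.v_rev_mV


def nernst(sol: IonSolution = IonSolution()) -> float:
    """K+ Nernst potential (mV): (RT/F) ln([K]_out/[K]_in)."""
    return 1e3 * (GAS_CONSTANT * sol.temperature_K / FARADAY) \
        * math.log(sol.k_out_mM / sol.k_in_mM)
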