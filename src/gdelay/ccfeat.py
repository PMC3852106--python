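"""Current-clamp feature extraction.

Implements the response-phenotype measurements used throughout the pipeline:
resting potential, input resistance from the subthreshold steady-state I-V
slope, membrane time constant by double-exponential fit (slow component),
capacitance as tau_m/R_0, AP detection with a dV/dt-based threshold, rheobase
on an ascending step grid, first-spike response delay (2 s window), I/O
curves, first-spike jitter (SD and CV), and synaptic input/output measures.

Censored measurements (no AP within the window, too few spikes for a
frequency) carry explicit flags and are never reported as sentinel numbers.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .errors import FitError, InsufficientDataError
from .trace_io import StepProtocol, Sweep


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PassiveProperties:
    """Passive summary: V_rest, R_in, tau_m, R_0 (= U_m/I_m of the tau step),
    and capacitance C_m = tau_m / R_0."""

    v_rest_mV: float
    r_in_MOhm: float
    tau_m_ms: float
    r0_MOhm: float
    c_m_pF: float

    def __post_init__(self) -> None:
        if not self.r_in_MOhm > 0 or not self.tau_m_ms > 0:
            raise ValueError("R_in and tau_m must be > 0")
        expected = 1e3 * self.tau_m_ms / self.r0_MOhm
        if not math.isclose(self.c_m_pF, expected, rel_tol=0.05):
            raise ValueError(
                f"C_m={self.c_m_pF} inconsistent with tau_m/R_0={expected:.2f} pF"
            )


@dataclass(frozen=True)
class APEvent:
    peak_time_s: float
    peak_V_mV: float
    threshold_V_mV: float
    width_ms: float

    def __post_init__(self) -> None:
        if not self.peak_V_mV > self.threshold_V_mV:
            raise ValueError("AP peak must exceed threshold")
        if not self.width_ms > 0:
            raise ValueError("AP width must be > 0")


@dataclass(frozen=True)
class DelayResult:
    """First-spike delay; ``censored`` means no AP peak inside the window."""

    delay_ms: float
    censored: bool

    @property
    def value_or_nan(self) -> float:
        return math.nan if self.censored else self.delay_ms


@dataclass(frozen=True)
class RheobaseResult:
    rheobase_pA: Optional[float]
    censored: bool


@dataclass(frozen=True)
class RinResult:
    r_in_MOhm: float
    iv_points: tuple  # ((I_pA, dV_mV), ...)
    intercept_mV: float


@dataclass(frozen=True)
class MembraneTauFit:
    tau_m_ms: float        # slow component (the membrane time constant)
    tau_fast_ms: float
    amp_slow_mV: float
    amp_fast_mV: float
    residual: float


@dataclass(frozen=True)
class ResponseFeatures:
    delay_ms: float
    rheobase_pA: Optional[float]
    ap_count: int
    initial_freq_Hz: float
    jitter_sd_ms: float
    jitter_cv: float


@dataclass(frozen=True)
class SynapticIOResult:
    epsp1_amplitude: float
    ap_count: int
    paired_pulse_ratio: float
    flags: tuple = ()


# ---------------------------------------------------------------------------
# Passive properties
# ---------------------------------------------------------------------------

def measure_vrest(s: Sweep, window_s: Optional[tuple] = None,
                  min_duration_s: float = 1.0) -> float:
    """Mean membrane potential over a stimulus-free window (defaults to the
    whole sweep). Raises if the window is shorter than ``min_duration_s``."""
    if s.kind != "voltage":
        raise TypeError("V_rest is measured on voltage sweeps")
    if window_s is None:
        seg = s.samples
        dur = s.duration
    else:
        i0, i1 = (int(round(t / s.dt)) for t in window_s)
        seg = s.samples[i0:i1]
        dur = (i1 - i0) * s.dt
    if dur < min_duration_s:
        raise InsufficientDataError(
            f"V_rest window {dur:.3f} s shorter than minimum {min_duration_s} s"
        )
    return float(np.mean(seg))


def _step_indices(s: Sweep) -> tuple:
    p = s.protocol
    if not isinstance(p, StepProtocol):
        raise TypeError("sweep lacks a current-step protocol")
    i0 = int(round(p.onset_s / s.dt))
    i1 = int(round((p.onset_s + p.duration_s) / s.dt))
    return i0, min(i1, s.samples.size)


def _baseline_and_steady(s: Sweep, steady_fraction: float) -> tuple:
    i0, i1 = _step_indices(s)
    baseline = float(np.mean(s.samples[:i0])) if i0 > 0 else float(s.samples[0])
    n_ss = max(int(round((i1 - i0) * steady_fraction)), 1)
    steady = float(np.mean(s.samples[i1 - n_ss:i1]))
    return baseline, steady


def measure_rin(sweeps: Sequence[Sweep], max_dv_mV: float = 10.0,
                steady_fraction: float = 0.2) -> RinResult:
    """Input resistance as the least-squares slope of the steady-state
    voltage-current relation, restricted to steps within +/- ``max_dv_mV`` of
    baseline. Steady state is the mean over the final ``steady_fraction`` of
    the step. Sweeps containing APs are excluded."""
    points = []
    for s in sweeps:
        if s.kind != "voltage":
            continue
        i0, i1 = _step_indices(s)
        if np.any(s.samples[i0:i1] > 0.0):   # suprathreshold: spiking sweep
            continue
        baseline, steady = _baseline_and_steady(s, steady_fraction)
        dv = steady - baseline
        if abs(dv) <= max_dv_mV + 1e-9:
            points.append((s.protocol.amplitude_pA, dv))
    if len(points) < 2:
        raise InsufficientDataError(
            f"need >= 2 subthreshold steps within +/-{max_dv_mV} mV, "
            f"got {len(points)}"
        )
    i_pA = np.array([p[0] for p in points])
    dv_mV = np.array([p[1] for p in points])
    slope, intercept = np.polyfit(i_pA, dv_mV, 1)  # GOhm
    return RinResult(float(slope * 1e3), tuple(points), float(intercept))


def fit_membrane_time_constant(avg_response: Sweep,
                               max_amplitude_mV: float = 5.0,
                               min_amp_fraction: float = 0.02) -> MembraneTauFit:
    """Double-exponential fit of a small averaged charging response; the
    slower component is the membrane time constant.

    The response amplitude must stay under ``max_amplitude_mV`` so the fit
    sees a passive membrane. If the slower component carries less than
    ``min_amp_fraction`` of the total amplitude it is treated as absent and
    the faster time constant is reported (single-exponential case).
    """
    i0, i1 = _step_indices(avg_response)
    baseline = float(np.mean(avg_response.samples[:i0])) if i0 > 0 else float(avg_response.samples[0])
    y = avg_response.samples[i0:i1] - baseline
    if np.max(np.abs(y)) > max_amplitude_mV + 0.5:
        raise ValueError(
            f"charging amplitude {np.max(np.abs(y)):.1f} mV exceeds the "
            f"{max_amplitude_mV} mV passive-response limit"
        )
    t = np.arange(y.size) * avg_response.dt * 1e3  # ms

    def model(t, a1, tau1, a2, tau2):
        return (a1 * (1 - np.exp(-t / tau1)) + a2 * (1 - np.exp(-t / tau2)))

    amp = y[-1]
    best = None
    for tau_fast in (1.0, 3.0, 10.0):
        for tau_slow in (15.0, 30.0, 80.0):
            try:
                popt, _ = curve_fit(
                    model, t, y, p0=[0.3 * amp, tau_fast, 0.7 * amp, tau_slow],
                    maxfev=20000,
                )
            except RuntimeError:
                continue
            ssr = float(np.sum((model(t, *popt) - y) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, popt)
    if best is None:
        raise FitError("double-exponential fit did not converge from any start")
    ssr, (a1, tau1, a2, tau2) = best
    (a_f, tau_f), (a_s, tau_s) = sorted(
        [(a1, abs(tau1)), (a2, abs(tau2))], key=lambda p: p[1]
    )
    total = abs(a_f) + abs(a_s)
    if total > 0 and abs(a_s) < min_amp_fraction * total:
        # degenerate second component: single-exponential response
        tau_s, a_s, tau_f, a_f = tau_f, a_f, tau_s, a_s
    return MembraneTauFit(float(tau_s), float(tau_f), float(a_s), float(a_f),
                          residual=ssr)


def estimate_capacitance(tau_m_ms: float, r0_MOhm: float) -> float:
    """C_m = tau_m / R_0, in pF (ms / MOhm = nF; scaled by 1e3)."""
    if not tau_m_ms > 0 or not r0_MOhm > 0:
        raise ValueError("tau_m and R_0 must be > 0")
    return 1e3 * tau_m_ms / r0_MOhm


# ---------------------------------------------------------------------------
# Spike detection and timing
# ---------------------------------------------------------------------------

def detect_aps(s: Sweep, slope_thresh_mV_per_s: float = 20.0,
               peak_min_mV: float = 0.0, lockout_ms: float = 2.0,
               width_at_mV: float = -5.0) -> list:
    """Detect action potentials and measure threshold and width.

    Peaks are local maxima above ``peak_min_mV`` (APs are overshooting)
    separated by at least ``lockout_ms``. The threshold is the potential at
    the last upward crossing of the dV/dt criterion before the peak (the
    conventional criterion is stated in mV/s; pass 20000 for a 20 mV/ms
    reading). Width is measured between the two crossings of ``width_at_mV``
    around the peak. Returns an empty list for subthreshold traces.
    """
    if s.kind != "voltage":
        raise TypeError("AP detection needs a voltage sweep")
    v = s.samples
    dt = s.dt
    dvdt = np.gradient(v, dt)  # mV/s, central differences
    min_dist = max(int(round(lockout_ms * 1e-3 / dt)), 1)
    peaks, _ = find_peaks(v, height=peak_min_mV, distance=min_dist)
    events = []
    prev_peak = 0
    for pk in peaks:
        # walk back into the upstroke (slope above criterion), then further
        # back to the last upward crossing of the slope criterion
        j = pk
        while j > prev_peak and dvdt[j] <= slope_thresh_mV_per_s:
            j -= 1
        while j > prev_peak and dvdt[j - 1] > slope_thresh_mV_per_s:
            j -= 1
        thr_v = float(min(v[j], v[pk] - 1e-9))
        # width: interpolated crossings of width_at_mV around the peak
        wl = _cross_time(v, dt, pk, width_at_mV, direction=-1, stop=prev_peak)
        wr = _cross_time(v, dt, pk, width_at_mV, direction=+1, stop=v.size - 1)
        if wl is None or wr is None:
            continue
        width_ms = (wr - wl) * 1e3
        events.append(APEvent(float(pk * dt), float(v[pk]), thr_v, width_ms))
        prev_peak = pk
    return events


def _cross_time(v: np.ndarray, dt: float, start: int, level: float,
                direction: int, stop: int) -> Optional[float]:
    """Interpolated time where v falls to ``level`` walking from the peak at
    ``start`` (where v > level) toward ``stop`` (inclusive index bound)."""
    i = start
    while i != stop:
        j = i + direction
        if v[j] <= level:
            frac = (v[i] - level) / (v[i] - v[j])  # in (0, 1]
            return (i + frac * direction) * dt
        i = j
    return None


def measure_delay(s: Sweep, proto: Optional[StepProtocol] = None,
                  window_s: float = 2.0, **detect_kwargs) -> DelayResult:
    """Time from current-step onset to the first AP peak within the window.

    Returns a censored result (flag, not a sentinel) when no AP occurs.
    """
    proto = proto or s.protocol
    if not isinstance(proto, StepProtocol):
        raise TypeError("measure_delay needs a current-step protocol")
    events = detect_aps(s, **detect_kwargs)
    for ev in events:
        if proto.onset_s <= ev.peak_time_s <= proto.onset_s + window_s:
            return DelayResult((ev.peak_time_s - proto.onset_s) * 1e3, False)
    return DelayResult(math.nan, True)


def find_rheobase(provider: Callable[[float], Sweep],
                  grid: Sequence[float] = tuple(np.arange(0.0, 405.0, 5.0)),
                  window_s: float = 1.0, **detect_kwargs) -> RheobaseResult:
    """Minimum grid amplitude eliciting >= 1 AP within ``window_s`` of onset.

    ``provider`` maps a step amplitude (pA) to the evoked voltage sweep.
    Censored when even the grid maximum stays silent.
    """
    for amp in grid:
        sweep = provider(float(amp))
        res = measure_delay(sweep, window_s=window_s, **detect_kwargs)
        if not res.censored:
            return RheobaseResult(float(amp), False)
    return RheobaseResult(None, True)


def io_curves(sweeps: Iterable[Sweep], window_s: float = 2.0,
              **detect_kwargs) -> pd.DataFrame:
    """AP count and initial frequency per step amplitude.

    Initial frequency is 1/(first interspike interval); with fewer than two
    APs it is undefined and flagged (NaN + ``freq_defined`` False). Multiple
    sweeps at one amplitude are averaged.
    """
    rows = []
    for s in sweeps:
        proto = s.protocol
        if not isinstance(proto, StepProtocol):
            raise TypeError("io_curves needs current-step protocols")
        events = [ev for ev in detect_aps(s, **detect_kwargs)
                  if proto.onset_s <= ev.peak_time_s <= proto.onset_s + window_s]
        if len(events) >= 2:
            freq = 1.0 / (events[1].peak_time_s - events[0].peak_time_s)
            defined = True
        else:
            freq, defined = math.nan, False
        rows.append({"amplitude_pA": proto.amplitude_pA,
                     "ap_count": len(events),
                     "initial_freq_Hz": freq,
                     "freq_defined": defined})
    df = pd.DataFrame(rows)
    out = (df.groupby("amplitude_pA", as_index=False)
             .agg(ap_count=("ap_count", "mean"),
                  initial_freq_Hz=("initial_freq_Hz", "mean"),
                  freq_defined=("freq_defined", "any"))
             .sort_values("amplitude_pA", ignore_index=True))
    return out


def first_spike_jitter(delays: Iterable[DelayResult | float]) -> tuple:
    """(SD, CV) of first-spike delays over repeated identical stimuli.

    Censored trials are dropped; at least 3 spiking trials are required.
    SD uses the n-1 (sample) convention; CV = SD / mean delay.
    """
    vals = []
    for d in delays:
        if isinstance(d, DelayResult):
            if not d.censored:
                vals.append(d.delay_ms)
        elif not math.isnan(d):
            vals.append(float(d))
    if len(vals) < 3:
        raise InsufficientDataError(
            f"jitter needs >= 3 spiking trials, got {len(vals)}"
        )
    sd = float(np.std(vals, ddof=1))
    mean = float(np.mean(vals))
    cv = sd / mean if mean > 0 else math.nan
    return sd, cv


# ---------------------------------------------------------------------------
# Synaptic input/output
# ---------------------------------------------------------------------------

def synaptic_io(trial: Sweep, pulse_times_s: Sequence[float],
                baseline_window_s: float = 0.01,
                ap_thresh_mV: float = 0.0,
                zero_eps: float = 1e-9) -> SynapticIOResult:
    """Per-trial synaptic I/O: first-response amplitude as input strength, AP
    count as output, last/first response ratio as facilitation.

    Each pulse response is its peak (within the inter-pulse window) minus the
    value at pulse onset. An AP inside the first-response window flags the
    amplitude as contaminated; a near-zero first response flags the ratio as
    undefined.
    """
    pulse_times = list(pulse_times_s)
    if len(pulse_times) < 1:
        raise ValueError("need at least one pulse time")
    v = trial.samples
    dt = trial.dt
    ipi = (pulse_times[1] - pulse_times[0]) if len(pulse_times) > 1 else 0.05
    flags = []

    def response(t0: float) -> float:
        j0 = int(round(t0 / dt))
        j1 = min(int(round((t0 + ipi) / dt)), v.size)
        return float(np.max(v[j0:j1]) - v[j0])

    b0 = int(round((pulse_times[0] - baseline_window_s) / dt))
    b1 = int(round(pulse_times[0] / dt))
    baseline = float(np.mean(v[max(b0, 0):b1])) if b1 > max(b0, 0) else float(v[0])
    j0 = int(round(pulse_times[0] / dt))
    j1 = min(int(round((pulse_times[0] + ipi) / dt)), v.size)
    first_window = v[j0:j1]
    epsp1 = float(np.max(first_window) - baseline)
    ap_count = 0
    if trial.kind == "voltage":
        events = detect_aps(trial, peak_min_mV=ap_thresh_mV)
        ap_count = sum(1 for ev in events
                       if pulse_times[0] <= ev.peak_time_s
                       <= pulse_times[-1] + ipi)
        if any(pulse_times[0] <= ev.peak_time_s < pulse_times[0] + ipi
               for ev in events):
            flags.append("epsp1_ap_contaminated")
    r_first = response(pulse_times[0])
    r_last = response(pulse_times[-1])
    if abs(r_first) < zero_eps:
        flags.append("ratio_undefined")
        ppr = math.nan
    else:
        ppr = r_last / r_first
    return SynapticIOResult(epsp1, ap_count, ppr, tuple(flags))
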