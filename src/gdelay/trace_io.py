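"""Sweep-level data model, on-disk container, and recording quality control.

Units are fixed internally: membrane potential in mV, current in pA, time in
seconds. Converters live at the I/O boundary only. A recording is a directory
per cell: ``metadata.json`` holds cell metadata, QC numbers and the protocol of
every sweep; each sweep's samples live in their own two-column CSV
(``time_s,value``) so the container stays diffable and language-neutral.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np

from .errors import FormatError, SchemaError, UnevaluableRuleError

GROUPS = ("naive", "KA", "post-NaCl", "post-KA", "recovery")
LAYERS = ("inner", "outer", "unknown")
SOLUTIONS = ("KMe", "KCl")


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepProtocol:
    """Square current step for current-clamp stimulation.

    amplitude_pA : step amplitude relative to holding.
    onset_s, duration_s : stimulus timing in seconds (onset >= 0, duration > 0).
    holding_pA : bias current outside the step.
    """

    amplitude_pA: float
    onset_s: float
    duration_s: float
    holding_pA: float = 0.0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        if self.onset_s < 0:
            raise ValueError(f"onset_s must be >= 0, got {self.onset_s}")


@dataclass(frozen=True)
class VCStepProtocol:
    """Voltage-clamp step family: a holding level, test steps, optional prepulse.

    ``prepulse_mV`` (one potential per family member, paired with
    ``prepulse_duration_s``) models inactivation protocols where conditioning
    pulses precede a fixed test pulse.
    """

    holding_mV: float
    steps_mV: tuple
    step_duration_s: float
    prepulse_mV: Optional[tuple] = None
    prepulse_duration_s: Optional[float] = None
    onset_s: float = 0.05

    def __post_init__(self) -> None:
        if not self.step_duration_s > 0:
            raise ValueError("step_duration_s must be > 0")
        object.__setattr__(self, "steps_mV", tuple(float(v) for v in self.steps_mV))
        if self.prepulse_mV is not None:
            object.__setattr__(
                self, "prepulse_mV", tuple(float(v) for v in self.prepulse_mV)
            )
            if self.prepulse_duration_s is None or not self.prepulse_duration_s > 0:
                raise ValueError("prepulse_mV requires prepulse_duration_s > 0")


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

@dataclass
class Sweep:
    """One digitized trace (voltage or current) plus its stimulus protocol.

    Time is sample-index based and 0-based: t = index * dt.
    """

    samples: np.ndarray
    dt: float
    kind: Literal["voltage", "current"]
    protocol: StepProtocol | VCStepProtocol | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("samples must be a 1-D array with >= 2 points")
        if self.kind not in ("voltage", "current"):
            raise ValueError(f"kind must be 'voltage' or 'current', got {self.kind!r}")

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt

    @property
    def duration(self) -> float:
        return self.samples.size * self.dt


@dataclass
class RecordingQC:
    """Per-recording quality numbers collected at break-in.

    Any field may be None when it was not measured; QC rules that need a
    missing field raise instead of silently passing.
    """

    r_seal_GOhm: Optional[float] = None
    r_ser_MOhm: Optional[float] = None
    v_rest_mV: Optional[float] = None
    ap_overshoot: Optional[bool] = None
    rin_over_rseal: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("r_seal_GOhm", "r_ser_MOhm"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be > 0 when present, got {v}")


@dataclass
class SweepSet:
    """All sweeps of one cell within a protocol family, plus metadata."""

    sweeps: list
    cell_id: str = "cell"
    group: str = "naive"
    layer: str = "unknown"
    solution: str = "KMe"
    qc: RecordingQC = field(default_factory=RecordingQC)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        if self.solution not in SOLUTIONS:
            raise ValueError(f"solution must be one of {SOLUTIONS}")
        if self.sweeps:
            dt0 = self.sweeps[0].dt
            kind0 = self.sweeps[0].kind
            for s in self.sweeps:
                if not math.isclose(s.dt, dt0, rel_tol=1e-12):
                    raise FormatError(
                        f"inconsistent dt within SweepSet: {s.dt} vs {dt0}"
                    )
                if s.kind != kind0:
                    raise FormatError("mixed voltage/current sweeps in one SweepSet")

    @property
    def kind(self) -> str:
        return self.sweeps[0].kind if self.sweeps else "voltage"


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCCriteria:
    """Acceptance thresholds for perforated-patch recordings.

    The defaults are the ``perforated-patch-default`` preset: series resistance
    below 40 MOhm, resting potential below -73 mV, overshooting APs, seal above
    1 GOhm, and R_in/R_seal below 0.3. Each rule can be disabled by setting its
    threshold to None.
    """

    max_r_ser_MOhm: Optional[float] = 40.0
    max_v_rest_mV: Optional[float] = -73.0
    require_overshoot: bool = True
    min_r_seal_GOhm: Optional[float] = 1.0
    max_rin_over_rseal: Optional[float] = 0.3

    def __post_init__(self) -> None:
        for name in ("max_r_ser_MOhm", "max_v_rest_mV", "min_r_seal_GOhm",
                     "max_rin_over_rseal"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")


QC_PRESETS = {"perforated-patch-default": QCCriteria()}


@dataclass(frozen=True)
class QCDecision:
    accept: bool
    violated: tuple


def qc_recording(qc: RecordingQC, criteria: QCCriteria | str = "perforated-patch-default") -> QCDecision:
    """Apply recording-acceptance rules; reject iff any enabled rule fails.

    Raises UnevaluableRuleError if an enabled rule's field is missing — a rule
    must never pass silently for lack of data.
    """
    if isinstance(criteria, str):
        criteria = QC_PRESETS[criteria]
    violated = []

    def check(rule: str, value, ok) -> None:
        if value is None:
            raise UnevaluableRuleError(
                f"rule {rule!r} is enabled but its QC field was not measured"
            )
        if not ok(value):
            violated.append(rule)

    if criteria.max_r_ser_MOhm is not None:
        check("r_ser", qc.r_ser_MOhm, lambda v: v < criteria.max_r_ser_MOhm)
    if criteria.max_v_rest_mV is not None:
        check("v_rest", qc.v_rest_mV, lambda v: v < criteria.max_v_rest_mV)
    if criteria.require_overshoot:
        check("ap_overshoot", qc.ap_overshoot, lambda v: bool(v))
    if criteria.min_r_seal_GOhm is not None:
        check("r_seal", qc.r_seal_GOhm, lambda v: v > criteria.min_r_seal_GOhm)
    if criteria.max_rin_over_rseal is not None:
        check("rin_over_rseal", qc.rin_over_rseal,
              lambda v: v < criteria.max_rin_over_rseal)
    return QCDecision(accept=not violated, violated=tuple(violated))


# ---------------------------------------------------------------------------
# Liquid junction potential
# ---------------------------------------------------------------------------

def apply_ljp_correction(s: SweepSet, ljp_mV: float = 10.0,
                         policy: str = "kcl-exempt") -> SweepSet:
    """Subtract the liquid junction potential from every voltage sweep.

    Under the default ``kcl-exempt`` policy, KCl-solution recordings are left
    untouched (their LJP is negligible); ``always`` applies the shift
    regardless of solution.
    """
    if s.sweeps and s.kind != "voltage":
        raise TypeError("LJP correction applies to voltage sweeps only")
    if policy not in ("kcl-exempt", "always"):
        raise ValueError(f"unknown LJP policy {policy!r}")
    if policy == "kcl-exempt" and s.solution == "KCl":
        return s
    new_sweeps = [
        Sweep(sw.samples - ljp_mV, sw.dt, sw.kind, sw.protocol) for sw in s.sweeps
    ]
    qc = s.qc
    if qc.v_rest_mV is not None:
        qc = replace(qc, v_rest_mV=qc.v_rest_mV - ljp_mV)
    return SweepSet(new_sweeps, s.cell_id, s.group, s.layer, s.solution, qc)


# ---------------------------------------------------------------------------
# Container round-trip
# ---------------------------------------------------------------------------

_PROTO_CLASSES = {"StepProtocol": StepProtocol, "VCStepProtocol": VCStepProtocol}


def _proto_to_json(p) -> Optional[dict]:
    if p is None:
        return None
    d = asdict(p)
    d["__class__"] = type(p).__name__
    return d


def _proto_from_json(d) -> StepProtocol | VCStepProtocol | None:
    if d is None:
        return None
    d = dict(d)
    cls = d.pop("__class__", None)
    if cls not in _PROTO_CLASSES:
        raise SchemaError(f"unknown protocol class {cls!r} in metadata")
    return _PROTO_CLASSES[cls](**d)


def save_sweeps(s: SweepSet, path: str | Path) -> Path:
    """Write a SweepSet as a cell directory (metadata.json + one CSV/sweep).

    Floats are written with 17 significant digits so the round trip is
    bit-exact for float64 samples.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "cell_id": s.cell_id,
        "group": s.group,
        "layer": s.layer,
        "solution": s.solution,
        "qc": asdict(s.qc),
        "sweeps": [],
    }
    for i, sw in enumerate(s.sweeps):
        fname = f"sweep_{i:03d}.csv"
        t = np.arange(sw.samples.size) * sw.dt
        np.savetxt(path / fname,
                   np.column_stack([t, sw.samples]),
                   delimiter=",", header="time_s,value", comments="",
                   fmt="%.17g")
        meta["sweeps"].append({
            "file": fname,
            "dt": sw.dt,
            "kind": sw.kind,
            "protocol": _proto_to_json(sw.protocol),
        })
    (path / "metadata.json").write_text(json.dumps(meta, indent=1))
    return path


def load_sweeps(path: str | Path) -> SweepSet:
    """Load a cell directory written by :func:`save_sweeps`.

    Raises SchemaError naming the missing field/column, FormatError for
    structurally inconsistent sweep tables.
    """
    path = Path(path)
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise SchemaError(f"missing metadata.json in {path}")
    meta = json.loads(meta_path.read_text())
    for required in ("cell_id", "group", "layer", "solution", "qc", "sweeps"):
        if required not in meta:
            raise SchemaError(f"metadata.json is missing field {required!r}")
    sweeps = []
    for entry in meta["sweeps"]:
        for required in ("file", "dt", "kind"):
            if required not in entry:
                raise SchemaError(f"sweep entry is missing field {required!r}")
        table = np.genfromtxt(path / entry["file"], delimiter=",", names=True)
        if table.dtype.names is None or "value" not in table.dtype.names:
            raise SchemaError(
                f"sweep table {entry['file']} is missing column 'value'"
            )
        if "time_s" not in table.dtype.names:
            raise SchemaError(
                f"sweep table {entry['file']} is missing column 'time_s'"
            )
        values = np.atleast_1d(table["value"]).astype(np.float64)
        times = np.atleast_1d(table["time_s"]).astype(np.float64)
        if times.size >= 2:
            steps = np.diff(times)
            if not np.allclose(steps, entry["dt"], rtol=1e-9, atol=1e-12):
                raise FormatError(
                    f"sweep table {entry['file']}: time column inconsistent "
                    f"with declared dt={entry['dt']}"
                )
        sweeps.append(Sweep(values, float(entry["dt"]), entry["kind"],
                            _proto_from_json(entry.get("protocol"))))
    return SweepSet(
        sweeps,
        cell_id=meta["cell_id"],
        group=meta["group"],
        layer=meta["layer"],
        solution=meta["solution"],
        qc=RecordingQC(**meta["qc"]),
    )
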