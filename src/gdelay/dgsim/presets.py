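"""Model presets for the two study conditions, plus YAML (de)serialization.

The ``naive`` and ``KA`` presets differ chiefly in delay-conductance density
and activation midpoint: the epileptic (kainate-injected, "KA") condition has
a several-fold larger g_D whose activation is shifted ~14 mV hyperpolarized,
and a larger inward-rectifier conductance. Gating midpoints, slopes and
inactivation time constants are the measured population values; the passive
leak is calibrated so each preset rests at its measured V_rest with its
measured input resistance (naive: -82.4 mV / 602 MOhm; KA: -83.8 mV /
449 MOhm). Whole-cell g_D magnitudes are free parameters chosen to place the
simulated response delays in the observed range (see docs/methods.md).
"""
from __future__ import annotations

from dataclasses import asdict, replace

import yaml

from .model import GateParams, SimCellParams, calibrate_passive

#: (v_rest mV, R_in MOhm) calibration targets per condition
PASSIVE_TARGETS = {"naive": (-82.4, 602.0), "KA": (-83.8, 449.0)}


def naive_params(seed: int = 0, noise_sd_pA: float = 0.0, **overrides) -> SimCellParams:
    """Control-condition granule cell."""
    p = SimCellParams(
        g_d_nS=2.0,
        g_kir_nS=0.4,
        act=GateParams(-32.3, 17.1, 5.0),
        inact=GateParams(-41.7, 14.1, 250.0),
        seed=seed,
        noise_sd_pA=noise_sd_pA,
    )
    p = replace(p, **overrides)
    return calibrate_passive(p, *PASSIVE_TARGETS["naive"])


def ka_params(seed: int = 0, noise_sd_pA: float = 0.0, **overrides) -> SimCellParams:
    """Epileptic-condition granule cell: larger, left-shifted delay conductance."""
    p = SimCellParams(
        g_d_nS=5.0,
        g_kir_nS=1.2,
        act=GateParams(-46.0, 17.0, 5.0),
        inact=GateParams(-43.8, 13.7, 378.0),
        seed=seed,
        noise_sd_pA=noise_sd_pA,
    )
    p = replace(p, **overrides)
    return calibrate_passive(p, *PASSIVE_TARGETS["KA"])


PRESETS = {"naive": naive_params, "KA": ka_params}


def params_to_yaml(p: SimCellParams) -> str:
    d = asdict(p)
    return yaml.safe_dump(d, sort_keys=False)


def params_from_yaml(text: str) -> SimCellParams:
    d = yaml.safe_load(text)
    d["act"] = GateParams(**d["act"])
    d["inact"] = GateParams(**d["inact"])
    return SimCellParams(**d)
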