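"""Non-electrophysiological fixture generators: CT tables, synaptic trains,
banded intensity images.

These emulate the structure of the study's molecular and imaging data so the
downstream quantification stages can be exercised and validated without any
acquired data: cycle-threshold (CT) tables with a programmed Kv1.1 fold
difference and a flat GAPDH reference, 100 Hz facilitating pulse trains, and
2-D images with a brighter middle-molecular-layer-like band.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ..trace_io import Sweep

KV1_GENES = ("Kv1.1", "Kv1.2", "Kv1.3", "Kv1.4", "Kv1.5", "Kv1.6")
REFERENCE_GENE = "GAPDH"

#: single-cell naive-condition baseline CT per gene (detection cycles; lower =
#: more abundant). GAPDH is the reference housekeeping gene.
DEFAULT_BASELINE_CT = {
    "Kv1.1": 43.6, "Kv1.2": 39.2, "Kv1.3": 39.6,
    "Kv1.4": 40.6, "Kv1.5": 43.2, "Kv1.6": 41.1,
    REFERENCE_GENE: 34.8,
}


@dataclass(frozen=True)
class QPCRDesign:
    """Programmed structure of a synthetic CT table.

    ``log2_fold`` maps gene -> programmed log2 fold elevation in the case
    group (CT drops by that many cycles); genes absent from the map, and the
    reference gene, are flat. CTs beyond ``detection_ceiling`` are censored
    (reported as non-detected).
    """

    genes: tuple = KV1_GENES + (REFERENCE_GENE,)
    n_cells: int = 30
    groups: tuple = ("naive", "KA")
    baseline_ct: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE_CT))
    log2_fold: dict = field(default_factory=lambda: {"Kv1.1": math.log2(10.4)})
    ct_sd: float = 1.0
    detection_ceiling: float = 45.0
    level: str = "single_cell"

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.ct_sd < 0:
            raise ValueError("ct_sd must be >= 0")


def generate_qpcr_dataset(design: QPCRDesign, seed: int = 0) -> pd.DataFrame:
    """Draw a tidy CT table: one row per (cell, gene).

    CT = baseline - log2_fold * [group == case] + Normal(0, ct_sd), censored
    at the detection ceiling (CT set to NaN, ``detected`` False). Columns
    match the quantification pipeline's input contract.
    """
    rng = np.random.default_rng(seed)
    case = design.groups[1]
    rows = []
    for group in design.groups:
        for i in range(design.n_cells):
            cell = f"{group}_{i:03d}"
            for gene in design.genes:
                ct = design.baseline_ct[gene]
                ct -= design.log2_fold.get(gene, 0.0) * (group == case)
                ct += rng.normal(0.0, design.ct_sd)
                detected = ct <= design.detection_ceiling
                rows.append({
                    "sample_id": f"{cell}:{gene}",
                    "gene": gene,
                    "CT": ct if detected else np.nan,
                    "detected": detected,
                    "group": group,
                    "level": design.level,
                    "melt_ok": True,
                    "primer_dimer": False,
                    "linked_cell_id": cell,
                })
    return pd.DataFrame(rows)


def generate_synaptic_train(n_pulses: int = 5, rate_hz: float = 100.0,
                            amplitude_pA: float = 30.0,
                            facilitation_ratio: float = 1.4,
                            dt: float = 2.5e-5, onset_s: float = 0.02,
                            total_s: float = 0.25,
                            tau_rise_ms: float = 0.5,
                            tau_decay_ms: float = 5.0):
    """Facilitating EPSC-like current train (5 pulses at 100 Hz by default).

    Pulse amplitudes grow geometrically so the last/first ratio equals
    ``facilitation_ratio``. Each pulse is a peak-normalized double exponential.
    Returns (current Sweep, pulse onset times in s).
    """
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    n = int(round(total_s / dt))
    t_ms = np.arange(n) * dt * 1e3
    wave = np.zeros(n)
    # peak-normalization factor of exp(-t/td) - exp(-t/tr)
    tr, td = tau_rise_ms, tau_decay_ms
    tpk = tr * td / (td - tr) * math.log(td / tr)
    norm = math.exp(-tpk / td) - math.exp(-tpk / tr)
    pulse_times = onset_s + np.arange(n_pulses) / rate_hz
    for j, t0 in enumerate(pulse_times):
        amp = amplitude_pA * facilitation_ratio ** (j / max(n_pulses - 1, 1))
        rel = t_ms - t0 * 1e3
        mask = rel > 0
        wave[mask] += amp / norm * (np.exp(-rel[mask] / td) - np.exp(-rel[mask] / tr))
    return Sweep(wave, dt, "current"), pulse_times


def generate_roi_image(shape: tuple = (128, 128), band_row: int = 40,
                       band_halfwidth: int = 6, band_gain: float = 1.94,
                       base_intensity: float = 50.0, noise_sd: float = 0.0,
                       seed: int = 0):
    """Synthetic fluorescence field with one brighter horizontal band.

    Emulates the labeled middle-molecular-layer band seen in dentate
    immunofluorescence sections. Returns (image, masks) where masks holds
    boolean arrays: ``band`` (the bright rows), ``background`` (rows well away
    from the band), and ``column`` (a full-height strip for line profiles).
    """
    rng = np.random.default_rng(seed)
    img = np.full(shape, base_intensity, dtype=float)
    rows = np.arange(shape[0])
    in_band = np.abs(rows - band_row) <= band_halfwidth
    img[in_band, :] *= band_gain
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, shape)
    band = np.zeros(shape, dtype=bool)
    band[in_band, :] = True
    background = np.zeros(shape, dtype=bool)
    background[np.abs(rows - band_row) > 3 * band_halfwidth, :] = True
    column = np.zeros(shape, dtype=bool)
    c0 = shape[1] // 2
    column[:, max(c0 - 8, 0):c0 + 8] = True
    return img, {"band": band, "background": background, "column": column}
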