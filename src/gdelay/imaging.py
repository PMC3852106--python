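"""ROI densitometry and line profiles for fluorescence quantification.

Operates on single-channel 2-D intensity arrays (RGB red-channel extraction
belongs at the I/O boundary). Signal density is the mean pixel intensity of
an ROI (total normalized to area); line profiles run along rows of a columnar
ROI and are normalized to a reference region, making the whole chain
invariant to global intensity scaling.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ROIQuant:
    roi_id: str
    area_px: int
    total_intensity: float
    mean_intensity: float
    normalized: Optional[float] = None   # vs a reference ROI

    def __post_init__(self) -> None:
        if not self.area_px > 0:
            raise ValueError("ROI area must be > 0")

    @property
    def density(self) -> float:
        """Intensity per pixel (== mean for the mean-intensity convention)."""
        return self.total_intensity / self.area_px


def _as_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {image.shape}")
    if not mask.any():
        raise ValueError("empty ROI mask")
    return mask


def roi_density(image: np.ndarray, mask: np.ndarray, roi_id: str = "roi",
                reference_mask: Optional[np.ndarray] = None) -> ROIQuant:
    """Mean-intensity densitometry of one ROI, optionally normalized to a
    reference ROI of the same image."""
    image = np.asarray(image, dtype=float)
    mask = _as_mask(image, mask)
    vals = image[mask]
    total = float(vals.sum())
    mean = float(vals.mean())
    normalized = None
    if reference_mask is not None:
        ref = image[_as_mask(image, reference_mask)]
        ref_mean = float(ref.mean())
        if ref_mean == 0:
            raise ZeroDivisionError("reference ROI has zero mean intensity")
        normalized = mean / ref_mean
    return ROIQuant(roi_id, int(vals.size), total, mean, normalized)


def line_profile(image: np.ndarray, column_mask: np.ndarray,
                 reference_mask: np.ndarray) -> np.ndarray:
    """Row-wise intensity profile of a columnar ROI, normalized to the mean
    intensity of a reference region.

    Averages across the column width per row; rows outside the columnar ROI
    are NaN. Raises if the reference has zero intensity.
    """
    image = np.asarray(image, dtype=float)
    column_mask = _as_mask(image, column_mask)
    ref = image[_as_mask(image, reference_mask)]
    ref_mean = float(ref.mean())
    if ref_mean == 0:
        raise ZeroDivisionError("reference region has zero mean intensity")
    counts = column_mask.sum(axis=1)
    sums = np.where(column_mask, image, 0.0).sum(axis=1)
    profile = np.full(image.shape[0], np.nan)
    rows = counts > 0
    profile[rows] = sums[rows] / counts[rows] / ref_mean
    return profile


def compare_roi_groups(quants_by_condition: Dict[str, Sequence[ROIQuant]],
                       reference_condition: str,
                       area_alpha: float = 0.05) -> pd.DataFrame:
    """Group-level relative densities, normalized to a named condition.

    Also checks ROI-area homogeneity across conditions (Kruskal-Wallis);
    heterogeneous areas set ``area_flag`` on every row, since density
    comparisons assume comparable ROI sizes.
    """
    if reference_condition not in quants_by_condition:
        raise KeyError(f"reference condition {reference_condition!r} absent")
    means = {c: float(np.mean([q.mean_intensity for q in qs]))
             for c, qs in quants_by_condition.items() if qs}
    if not means or reference_condition not in means:
        raise ValueError("reference condition has no ROI quantifications")
    ref = means[reference_condition]
    areas = [[q.area_px for q in qs] for qs in quants_by_condition.values()]
    flat = [a for grp in areas for a in grp]
    if len(areas) > 1 and all(len(a) > 1 for a in areas):
        if max(flat) == min(flat):
            p_area = 1.0   # identical areas everywhere: trivially homogeneous
        else:
            try:
                _, p_area = stats.kruskal(*areas)
            except ValueError:
                p_area = 1.0
    else:
        p_area = math.nan
    flag = bool(p_area < area_alpha) if not math.isnan(p_area) else False
    rows = [{"condition": c,
             "mean_density": m,
             "relative_density": m / ref,
             "n": len(quants_by_condition[c]),
             "area_p": p_area,
             "area_flag": flag}
            for c, m in means.items()]
    return pd.DataFrame(rows)
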