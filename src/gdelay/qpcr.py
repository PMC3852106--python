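"""Quantification pipeline for cycle-threshold (CT) tables.

Works on tidy tables with one row per (sample, gene): columns ``sample_id``,
``gene``, ``CT`` (NaN when not detected), ``detected``, ``group``, ``level``,
``melt_ok``, ``primer_dimer`` and ``linked_cell_id``. Stages: sample QC
(melt-curve/primer-dimer rules and the drop-cells-without-reference rule),
primer efficiency from dilution series, relative quantification by the
delta-delta-CT method, abundance ranking by mean CT, z-score co-expression
across single cells, and the join between expression and electrophysiological
phenotype.

Censored CTs (no detection) are excluded from means rather than imputed,
matching the drop rule applied to the reference gene.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, JoinError

REFERENCE_GENE = "GAPDH"

REQUIRED_COLUMNS = ("sample_id", "gene", "CT", "group", "level",
                    "melt_ok", "primer_dimer", "linked_cell_id")


@dataclass(frozen=True)
class EfficiencyResult:
    """Primer efficiency from a 10-fold dilution series.

    ``slope`` is the regression slope of CT vs log10 concentration.
    ``e_amplification`` = 10^(-1/slope) is the per-cycle amplification factor
    (2.0 for perfect doubling); ``e`` is the conventional efficiency, that
    factor minus 1 (1.0 for perfect doubling) — the quantity the 0.9-1.05
    acceptance band applies to.
    """

    slope: float
    e: float
    e_amplification: float
    in_band: bool
    band: tuple = (0.9, 1.05)


@dataclass(frozen=True)
class FoldChangeResult:
    gene: str
    dct_case: float
    dct_control: float
    ddct: float
    fold: float
    reference_gene: Optional[str]
    method: str                     # "ddct" or "dct_only"
    n_case: int
    n_control: int


def _check_columns(samples: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in samples.columns]
    if missing:
        raise KeyError(f"CT table is missing required columns: {missing}")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(samples: pd.DataFrame,
              reference_gene: str = REFERENCE_GENE) -> tuple:
    """Apply sample-level QC; returns (kept, dropped-with-reason).

    Rules: a sample fails on a bad melt curve or a primer dimer; every sample
    of a cell whose reference gene was not detected is dropped (``no
    reference``) — such cells are not analyzable at all.
    """
    _check_columns(samples)
    df = samples.copy()
    reason = pd.Series("", index=df.index, dtype=object)
    reason[~df["melt_ok"].astype(bool)] = "melt curve failed"
    dimer = df["primer_dimer"].astype(bool) & (reason == "")
    reason[dimer] = "primer dimer"

    ref = df[df["gene"] == reference_gene]
    detected_ref = set(ref.loc[ref["CT"].notna(), "linked_cell_id"])
    all_cells = set(df["linked_cell_id"])
    no_ref_cells = all_cells - detected_ref
    no_ref = df["linked_cell_id"].isin(no_ref_cells) & (reason == "")
    reason[no_ref] = f"no {reference_gene}"

    dropped = df[reason != ""].copy()
    dropped["reason"] = reason[reason != ""]
    kept = df[reason == ""].copy()
    return kept, dropped


# ---------------------------------------------------------------------------
# Efficiency
# ---------------------------------------------------------------------------

def primer_efficiency(log10_concentration: Sequence[float],
                      cts: Sequence[float],
                      band: tuple = (0.9, 1.05)) -> EfficiencyResult:
    """Efficiency from the CT-vs-log10(template) regression slope.

    Requires at least five dilution points. E = 10^(-1/slope) - 1 in the
    conventional (fraction-gained-per-cycle) reading; the raw amplification
    factor 10^(-1/slope) is reported alongside.
    """
    x = np.asarray(log10_concentration, dtype=float)
    y = np.asarray(cts, dtype=float)
    if x.size < 5 or y.size != x.size:
        raise InsufficientDataError(
            f"efficiency needs >= 5 dilution points, got {x.size}"
        )
    slope = float(np.polyfit(x, y, 1)[0])
    if slope >= 0:
        raise InsufficientDataError(
            "CT must fall with template concentration (negative slope)"
        )
    amp = 10.0 ** (-1.0 / slope)
    e = amp - 1.0
    return EfficiencyResult(slope, e, amp, bool(band[0] <= e <= band[1]),
                            tuple(band))


# ---------------------------------------------------------------------------
# Fold changes
# ---------------------------------------------------------------------------

def ddct_fold(samples: pd.DataFrame, gene: str, case: str, control: str,
              reference_gene: Optional[str] = REFERENCE_GENE,
              efficiency: float = 1.0,
              method: str = "ddct") -> FoldChangeResult:
    """Relative expression of ``gene`` in case vs control groups.

    method="ddct": dCT = mean CT_gene - mean CT_reference per group,
    ddCT = dCT_case - dCT_control, fold = (1 + E)^(-ddCT) with E defaulting
    to 1 (perfect doubling). method="dct_only" skips the reference
    normalization and uses the raw group mean CTs (the convention for
    single-cell absolute log2 comparisons). Censored CTs are excluded.
    """
    _check_columns(samples)
    if method not in ("ddct", "dct_only"):
        raise ValueError(f"unknown method {method!r}")

    def mean_ct(g: str, grp: str) -> tuple:
        sel = samples[(samples["gene"] == g) & (samples["group"] == grp)]
        vals = sel["CT"].dropna()
        if vals.empty:
            raise InsufficientDataError(f"no detected CTs for {g} in {grp!r}")
        return float(vals.mean()), int(vals.size)

    ct_case, n_case = mean_ct(gene, case)
    ct_ctrl, n_ctrl = mean_ct(gene, control)
    if method == "ddct":
        if reference_gene is None:
            raise ValueError("ddct method needs a reference gene")
        ref_case, _ = mean_ct(reference_gene, case)
        ref_ctrl, _ = mean_ct(reference_gene, control)
        dct_case = ct_case - ref_case
        dct_ctrl = ct_ctrl - ref_ctrl
    else:
        reference_gene = None
        dct_case, dct_ctrl = ct_case, ct_ctrl
    ddct = dct_case - dct_ctrl
    fold = (1.0 + efficiency) ** (-ddct)
    return FoldChangeResult(gene, dct_case, dct_ctrl, ddct, fold,
                            reference_gene, method, n_case, n_ctrl)


# ---------------------------------------------------------------------------
# Abundance and co-expression
# ---------------------------------------------------------------------------

def sc_abundance(samples: pd.DataFrame, level: Optional[str] = None,
                 group: Optional[str] = None) -> pd.DataFrame:
    """Per-gene mean CT +/- sem over detected samples, ranked by ascending
    mean CT (lower CT = higher abundance)."""
    _check_columns(samples)
    df = samples
    if level is not None:
        df = df[df["level"] == level]
    if group is not None:
        df = df[df["group"] == group]
    df = df[df["CT"].notna()]
    if df.empty:
        raise InsufficientDataError("no detected samples at the requested level")
    out = (df.groupby("gene")["CT"]
             .agg(mean_ct="mean", sem=lambda v: stats.sem(v) if len(v) > 1 else math.nan,
                  n="size")
             .reset_index()
             .sort_values("mean_ct", ignore_index=True))
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def zscore_coexpression(samples: pd.DataFrame,
                        genes: Optional[Sequence[str]] = None,
                        min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise co-expression of per-cell standardized log2-domain CTs.

    Each gene's detected CTs are z-scored across cells (CT is already a log2
    quantity, so standardization happens in the log2 domain); Pearson r is
    computed on cells where both genes are detected. Returns a symmetric
    table with r, n and p per gene pair (unit diagonal).
    """
    _check_columns(samples)
    wide = (samples[samples["CT"].notna()]
            .pivot_table(index="linked_cell_id", columns="gene", values="CT"))
    if genes is not None:
        wide = wide[[g for g in genes if g in wide.columns]]
    z = (wide - wide.mean()) / wide.std(ddof=1)
    cols = list(z.columns)
    rows = []
    for gi in cols:
        for gj in cols:
            pair = z[[gi, gj]].dropna()
            n = len(pair)
            if gi == gj:
                r, p = 1.0, 0.0
            elif n >= min_pairs:
                r, p = stats.pearsonr(pair[gi], pair[gj])
            else:
                r, p = math.nan, math.nan
            rows.append({"gene_a": gi, "gene_b": gj, "r": float(r),
                         "n": n, "p": float(p)})
    return pd.DataFrame(rows)


def correlate_phenotype_expression(features: pd.DataFrame,
                                   samples: pd.DataFrame, gene: str,
                                   feature: str = "delay_ms",
                                   expression_sign: str = "neg_ct") -> tuple:
    """Pearson correlation between a response feature and a gene's expression
    over cells present in both tables.

    Expression is -CT by default (lower CT = more transcript), so a positive
    r means the feature grows with expression; pass ``expression_sign="ct"``
    for the raw-CT convention. Returns (r, n, p). Disjoint cell ids raise.
    """
    if "cell_id" not in features.columns or feature not in features.columns:
        raise KeyError(f"features table needs columns 'cell_id' and {feature!r}")
    _check_columns(samples)
    expr = samples[(samples["gene"] == gene) & samples["CT"].notna()]
    merged = features.merge(expr[["linked_cell_id", "CT"]],
                            left_on="cell_id", right_on="linked_cell_id")
    merged = merged.dropna(subset=[feature, "CT"])
    if merged.empty:
        raise JoinError(
            f"no shared cell ids between features and {gene} expression"
        )
    if len(merged) < 3:
        raise InsufficientDataError("correlation needs >= 3 joined cells")
    x = merged[feature].to_numpy(float)
    ct = merged["CT"].to_numpy(float)
    y = -ct if expression_sign == "neg_ct" else ct
    r, p = stats.pearsonr(x, y)
    return float(r), int(len(merged)), float(p)
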