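"""Gridded marginal and average effect factors from fitted SSDs.

Effect factors (EFs) translate a change in nitrogen concentration in a water
volume into a potentially disappeared fraction of fish species, in
PDF·m³·kg⁻¹. Two perspectives are computed per 0.5-degree cell:

* marginal EF — the instantaneous effect of an extra unit of nitrogen at the
  current state: 1000 × dPDF/dC at C_current. For the logistic SSD the
  derivative is PDF(C)·(1 − PDF(C))/b.
* average EF — the long-term effect relative to a reference state (here the
  year-1900 concentration field): 1000 × (PDF(C_cur) − PDF(C_ref)) /
  (C_cur − C_ref), with the analytic limit (the marginal EF) taken when the
  two states coincide within tolerance.

The factor 1000 converts the reciprocal concentration from L/mg to m³/kg.

Cell rules: a current concentration below the zero cutoff (default 1e-4 mg/L,
the modeling-uncertainty floor) yields no EF (reason ``zero_N``). Otherwise
the ecoregion-level SSD is used when fitted and of good quality; a fit that is
missing, failed, or of poor quality falls through to the realm-major-habitat-
type SSD; if neither is usable the cell carries no EF (reason ``no_ssd``).
A missing reference concentration leaves only the average EF undefined
(reason ``undefined_ref``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposure import LEVEL_ECOREGION, LEVEL_REALM_MHT, ZERO_CUTOFF
from .ssd import SSDFit, evaluate_ssd

UNIT_COEFFICIENT = 1000.0  # L/mg -> m3/kg

REASON_OK = 0
REASON_ZERO_N = 1
REASON_NO_SSD = 2
REASON_UNDEFINED_REF = 3

REASON_NAMES = {REASON_OK: "ok", REASON_ZERO_N: "zero_N",
                REASON_NO_SSD: "no_ssd", REASON_UNDEFINED_REF: "undefined_ref"}

#: EF magnitude classes used for area summaries, PDF·m³·kg⁻¹
EF_CLASS_EDGES = (100.0, 100_000.0)


@dataclass(frozen=True)
class EFConfig:
    current_year: int = 2010
    reference_year: int = 1900
    zero_cutoff: float = ZERO_CUTOFF
    reference_tolerance: float = 1e-12  # |C_cur - C_ref| below this -> limit

    def __post_init__(self) -> None:
        if self.zero_cutoff <= 0:
            raise ValueError("zero cutoff must be positive")


@dataclass
class EFGrid:
    """Per-cell marginal and average EFs with explicit missing-value reasons.

    ``marginal`` and ``average`` are NaN where undefined; ``reason`` is 0 for
    cells where both are defined, otherwise the code of the narrower outcome
    (``undefined_ref`` marks cells where only the average EF is undefined).
    """

    marginal: np.ndarray
    average: np.ndarray
    reason: np.ndarray


def marginal_ef(fit: SSDFit, concentration: float,
                zero_cutoff: float = ZERO_CUTOFF) -> float:
    """Marginal EF: 1000 × the SSD derivative at the current concentration."""
    if fit.status != "fitted":
        raise ValueError("marginal EF requires a fitted SSD")
    c = float(concentration)
    if c < zero_cutoff:
        raise ValueError("concentration below the zero cutoff has no EF")
    p = evaluate_ssd(fit.a, fit.b, c)
    raw = p * (1.0 - p) / fit.b  # dPDF/dC, per (mg/L)
    return UNIT_COEFFICIENT * raw


def average_ef(fit: SSDFit, c_current: float, c_reference: float,
               reference_tolerance: float = 1e-12,
               zero_cutoff: float = ZERO_CUTOFF) -> float:
    """Average EF: 1000 × the PDF secant between current and reference states.

    When the two states coincide within ``reference_tolerance`` the analytic
    limit — the marginal EF at the current state — is returned.
    """
    if fit.status != "fitted":
        raise ValueError("average EF requires a fitted SSD")
    c_cur, c_ref = float(c_current), float(c_reference)
    if abs(c_cur - c_ref) < reference_tolerance:
        return marginal_ef(fit, c_cur, zero_cutoff=zero_cutoff)
    dp = evaluate_ssd(fit.a, fit.b, c_cur) - evaluate_ssd(fit.a, fit.b, c_ref)
    return UNIT_COEFFICIENT * dp / (c_cur - c_ref)


def select_fits(ecoregion_raster: np.ndarray, realm_raster: np.ndarray,
                fits: dict[tuple[str, int], SSDFit]) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell (a, b) of the usable SSD, with ecoregion-first fallback.

    Returns two float arrays; cells with no usable fit at either level hold
    NaN. A fit is usable when fitted and flagged good.
    """
    a = np.full(ecoregion_raster.shape, np.nan)
    b = np.full(ecoregion_raster.shape, np.nan)
    for level, raster in ((LEVEL_ECOREGION, ecoregion_raster),
                          (LEVEL_REALM_MHT, realm_raster)):
        for region_id in np.unique(raster):
            if region_id <= 0:
                continue
            fit = fits.get((level, int(region_id)))
            if fit is None or fit.status != "fitted" or not fit.good_fit:
                continue
            sel = (raster == region_id) & np.isnan(a)
            a[sel] = fit.a
            b[sel] = fit.b
    return a, b


def compute_ef_grid(conc_current: np.ndarray, conc_reference: np.ndarray,
                    ecoregion_raster: np.ndarray, realm_raster: np.ndarray,
                    fits: dict[tuple[str, int], SSDFit],
                    config: EFConfig = EFConfig()) -> EFGrid:
    """Vectorized per-cell EF computation with hierarchical SSD fallback."""
    shapes = {conc_current.shape, conc_reference.shape,
              ecoregion_raster.shape, realm_raster.shape}
    if len(shapes) != 1:
        raise ValueError(f"raster shapes differ: {sorted(shapes)}")

    a, b = select_fits(ecoregion_raster, realm_raster, fits)
    has_ssd = ~np.isnan(a)
    zero_n = np.isnan(conc_current) | (conc_current < config.zero_cutoff)
    defined = has_ssd & ~zero_n

    marginal = np.full(conc_current.shape, np.nan)
    average = np.full(conc_current.shape, np.nan)
    reason = np.full(conc_current.shape, REASON_OK, dtype=np.int8)
    reason[~has_ssd] = REASON_NO_SSD
    reason[zero_n] = REASON_ZERO_N  # zero-N takes precedence over no-SSD

    with np.errstate(invalid="ignore", over="ignore"):
        p_cur = 1.0 / (1.0 + np.exp(-(conc_current - a) / b))
        marginal[defined] = (UNIT_COEFFICIENT * (p_cur * (1.0 - p_cur) / b))[defined]

        ref_ok = defined & ~np.isnan(conc_reference)
        p_ref = 1.0 / (1.0 + np.exp(-(conc_reference - a) / b))
        dc = conc_current - conc_reference
        secant = UNIT_COEFFICIENT * (p_cur - p_ref) / dc
        near = np.abs(dc) < config.reference_tolerance
        average[ref_ok & ~near] = secant[ref_ok & ~near]
        average[ref_ok & near] = marginal[ref_ok & near]
        reason[defined & ~ref_ok] = REASON_UNDEFINED_REF

    return EFGrid(marginal=marginal, average=average, reason=reason)


def ef_class_areas(ef: np.ndarray, cell_area: np.ndarray | float = 1.0,
                   edges: tuple[float, ...] = EF_CLASS_EDGES) -> pd.DataFrame:
    """Area (or cell count, with unit areas) per EF magnitude class.

    Classes are (-inf, edges[0]], (edges[0], edges[1]], ..., (edges[-1], inf),
    mirroring the low/medium/high EF classes used to summarize global maps.
    """
    area = np.broadcast_to(np.asarray(cell_area, dtype=float), ef.shape)
    defined = ~np.isnan(ef)
    bounds = (-np.inf, *edges, np.inf)
    rows = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        sel = defined & (ef > lo) & (ef <= hi)
        rows.append((f"({lo}, {hi}]", int(sel.sum()), float(area[sel].sum())))
    rows.append(("undefined", int((~defined).sum()), float(area[~defined].sum())))
    return pd.DataFrame(rows, columns=["ef_class", "n_cells", "area"])
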