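"""Species sensitivity distribution construction, fitting, and diagnostics.

From the per-species tolerance thresholds of one region, the empirical
dose-response points are built by counting survivors: at each observed
threshold level C_j, the surviving richness SR_j is the number of species
whose threshold is at least C_j, and the potentially disappeared fraction is

    PDF_j = 1 - SR_j / SR_max,

with SR_max the region's total species count. The SSD is the logistic

    PDF(C) = 1 / (1 + exp(-(C - a) / b)),

where ``a`` (mg/L) is the concentration at which half the species pool has
disappeared and ``b`` (mg/L) controls the slope. (a, b) are estimated by
unweighted nonlinear least squares on the (C_j, PDF_j) pairs. Regions with
three or fewer pairs are deemed insufficient for fitting.

Fit quality is summarized by the Cox-Snell pseudo-R^2 — under a Gaussian
likelihood with maximum-likelihood residual variance this reduces exactly to
1 - RSS_fit / RSS_null, with the null the intercept-only (mean PDF) model —
and by the NRMSE, the root-mean-square residual divided by the mean observed
PDF. A fit is flagged "good" when pseudo-R^2 > 0.5 and NRMSE < 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exposure import LEVEL_ECOREGION, LEVEL_REALM_MHT

MIN_PAIRS = 4  # fewer PDF-concentration pairs than this cannot be fitted

STATUS_FITTED = "fitted"
STATUS_INSUFFICIENT = "insufficient_data"
STATUS_FAILED = "failed"

GOOD_FIT_PSEUDO_R2 = 0.5
GOOD_FIT_NRMSE = 1.0

FIT_COLUMNS = ["region_id", "level", "a", "b", "n_pairs", "sr_max",
               "pseudo_r2", "nrmse", "status", "good_fit"]


@dataclass
class PDFPoints:
    """Empirical dose-response points for one region."""

    concentration: np.ndarray  # sorted unique threshold levels, mg/L
    richness: np.ndarray       # surviving species count at each level
    pdf: np.ndarray            # disappeared fraction at each level
    sr_max: int                # total species count in the region

    def __len__(self) -> int:
        return len(self.concentration)


@dataclass
class SSDFit:
    region_id: int
    level: str
    a: float
    b: float
    n_pairs: int
    sr_max: int
    pseudo_r2: float
    nrmse: float
    status: str

    @property
    def good_fit(self) -> bool:
        return (
            self.status == STATUS_FITTED
            and np.isfinite(self.pseudo_r2) and np.isfinite(self.nrmse)
            and self.pseudo_r2 > GOOD_FIT_PSEUDO_R2
            and self.nrmse < GOOD_FIT_NRMSE
        )


def build_pdf_points(thresholds) -> PDFPoints:
    """Survivor-counting construction of the empirical PDF-concentration pairs.

    Levels are the sorted unique thresholds; SR at level C_j is the number of
    species with threshold >= C_j, so the PDF at the smallest level is 0.
    """
    t = np.sort(np.asarray(thresholds, dtype=float))
    if t.size == 0:
        raise ValueError("at least one tolerance threshold is required")
    levels, first_idx = np.unique(t, return_index=True)
    sr_max = t.size
    # species with threshold >= levels[j] are those from first_idx[j] onward
    richness = sr_max - first_idx
    pdf = 1.0 - richness / sr_max
    return PDFPoints(concentration=levels, richness=richness, pdf=pdf,
                     sr_max=sr_max)


def transform_points_log10(points: PDFPoints) -> PDFPoints:
    """Re-express the dose axis as log10(concentration).

    Provided as a sensitivity switch: fitting on the log scale yields location
    and scale coefficients in log10(mg/L). The default analysis fits on the
    untransformed concentration, where the location coefficient is directly
    the concentration at which half the species pool has disappeared.
    """
    if np.any(points.concentration <= 0):
        raise ValueError("log-scale fitting requires positive concentrations")
    return PDFPoints(concentration=np.log10(points.concentration),
                     richness=points.richness, pdf=points.pdf,
                     sr_max=points.sr_max)


def check_eligibility(points: PDFPoints) -> str:
    """A region is eligible for fitting only with at least four pairs."""
    return "eligible" if len(points) >= MIN_PAIRS else STATUS_INSUFFICIENT


def evaluate_ssd(a: float, b: float, concentration):
    """Logistic SSD: disappeared fraction at a given concentration.

    Strictly increasing in the concentration; equals 0.5 at C = a.
    """
    if b <= 0:
        raise ValueError("SSD scale coefficient b must be positive")
    c = np.asarray(concentration, dtype=float)
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-(c - a) / b))
    if out.ndim == 0:
        return float(out)
    return out


def _residuals(params, conc, pdf):
    a, b = params
    return evaluate_ssd(a, max(b, 1e-12), conc) - pdf


def _initial_guess(conc: np.ndarray, pdf: np.ndarray) -> tuple[float, float]:
    # a0: level whose observed PDF is nearest 0.5; b0: a quarter of the span
    a0 = float(conc[np.argmin(np.abs(pdf - 0.5))])
    span = float(conc.max() - conc.min())
    b0 = span / 4.0 if span > 0 else max(float(conc[0]) / 4.0, 1e-3)
    return a0, b0


def fit_ssd(points: PDFPoints, region_id: int = 0,
            level: str = LEVEL_ECOREGION) -> SSDFit:
    """Least-squares logistic fit to the empirical PDF points.

    Non-convergence is recorded as ``status='failed'``, and too few points as
    ``status='insufficient_data'``; neither raises, so batch fitting always
    completes.
    """
    nan_fit = dict(region_id=region_id, level=level, a=np.nan, b=np.nan,
                   n_pairs=len(points), sr_max=points.sr_max,
                   pseudo_r2=np.nan, nrmse=np.nan)
    if check_eligibility(points) != "eligible":
        return SSDFit(status=STATUS_INSUFFICIENT, **nan_fit)

    conc, pdf = points.concentration, points.pdf
    a0, b0 = _initial_guess(conc, pdf)
    try:
        res = least_squares(
            _residuals, x0=[a0, b0], args=(conc, pdf),
            bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except Exception:
        return SSDFit(status=STATUS_FAILED, **nan_fit)
    if not res.success or not np.all(np.isfinite(res.x)):
        return SSDFit(status=STATUS_FAILED, **nan_fit)

    a, b = float(res.x[0]), float(res.x[1])
    fit = SSDFit(region_id=region_id, level=level, a=a, b=b,
                 n_pairs=len(points), sr_max=points.sr_max,
                 pseudo_r2=np.nan, nrmse=np.nan, status=STATUS_FITTED)
    fit.pseudo_r2 = cox_snell_r2(points, fit)
    fit.nrmse = nrmse(points, fit)
    return fit


def cox_snell_r2(points: PDFPoints, fit: SSDFit) -> float:
    """Cox-Snell pseudo-R^2 of the fit against the intercept-only null.

    R^2_CS = 1 - (L0 / L1)^(2/n) with Gaussian likelihoods whose variance is
    the maximum-likelihood residual variance; this reduces algebraically to
    1 - RSS_fit / RSS_null. Undefined (NaN) when the null RSS is zero, i.e.
    all observed PDFs are identical.
    """
    pdf = points.pdf
    predicted = evaluate_ssd(fit.a, fit.b, points.concentration)
    rss1 = float(np.sum((pdf - predicted) ** 2))
    rss0 = float(np.sum((pdf - pdf.mean()) ** 2))
    if rss0 == 0.0:
        return float("nan")
    return 1.0 - rss1 / rss0


def nrmse(points: PDFPoints, fit: SSDFit) -> float:
    """Root-mean-square residual normalized by the mean observed PDF.

    Undefined (NaN) when the mean observed PDF is zero.
    """
    pdf = points.pdf
    mean = float(pdf.mean())
    if mean == 0.0:
        return float("nan")
    predicted = evaluate_ssd(fit.a, fit.b, points.concentration)
    rms = float(np.sqrt(np.mean((pdf - predicted) ** 2)))
    return rms / mean


def fit_region(thresholds, region_id: int, level: str,
               log_concentration: bool = False) -> SSDFit:
    points = build_pdf_points(thresholds)
    if log_concentration:
        points = transform_points_log10(points)
    return fit_ssd(points, region_id=region_id, level=level)


def fit_all_regions(tolerances: pd.DataFrame,
                    log_concentration: bool = False) -> pd.DataFrame:
    """Fit one SSD per (region, hierarchy level) present in the tolerance table.

    Expects columns ``accepted_name, level, region_id, threshold_mg_per_L``.
    Returns the fit table with one row per (region, level), statuses recorded,
    and the good-fit flag (pseudo-R^2 > 0.5 and NRMSE < 1).
    """
    rows = []
    if len(tolerances):
        for (level, region_id), grp in tolerances.groupby(
                ["level", "region_id"], sort=True):
            fit = fit_region(grp["threshold_mg_per_L"].to_numpy(),
                             region_id=int(region_id), level=str(level),
                             log_concentration=log_concentration)
            rows.append((fit.region_id, fit.level, fit.a, fit.b, fit.n_pairs,
                         fit.sr_max, fit.pseudo_r2, fit.nrmse, fit.status,
                         fit.good_fit))
    out = pd.DataFrame(rows, columns=FIT_COLUMNS)
    return out.sort_values(["level", "region_id"], ignore_index=True)


def fits_from_table(table: pd.DataFrame) -> dict[tuple[str, int], SSDFit]:
    """Rehydrate SSDFit objects from a fit table (inverse of fit_all_regions)."""
    out = {}
    for rec in table.itertuples(index=False):
        fit = SSDFit(region_id=int(rec.region_id), level=str(rec.level),
                     a=float(rec.a), b=float(rec.b), n_pairs=int(rec.n_pairs),
                     sr_max=int(rec.sr_max), pseudo_r2=float(rec.pseudo_r2),
                     nrmse=float(rec.nrmse), status=str(rec.status))
        out[(fit.level, fit.region_id)] = fit
    return out
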