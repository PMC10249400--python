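"""Match occurrences to pixel-year nitrogen concentrations and derive
per-species tolerance thresholds.

A species is assumed tolerant to nitrogen-induced hypoxia/toxicity up to the
highest concentration at which it has been observed within a region. The
threshold is therefore the maximum over all matched occurrence concentrations
of that species in that region, computed independently at the ecoregion level
and at the coarser realm-major-habitat-type level (the latter by re-pooling
the matched occurrences under the coarser raster, never by aggregating
ecoregion-level thresholds).

Occurrences falling on pixel-years whose concentration is missing or below
the zero cutoff (default 1e-4 mg/L) are excluded: a zero-nitrogen observation
says nothing about an upper tolerance limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ZERO_CUTOFF = 1e-4  # mg/L; concentrations below this are treated as zero

LEVEL_ECOREGION = "ecoregion"
LEVEL_REALM_MHT = "realm_mht"


@dataclass
class MatchReport:
    n_input: int
    n_matched: int
    n_below_cutoff: int
    n_missing: int


def match_concentration(records: pd.DataFrame,
                        fields: dict[int, np.ndarray],
                        zero_cutoff: float = ZERO_CUTOFF,
                        ) -> tuple[pd.DataFrame, MatchReport]:
    """Attach the concentration of each record's (cell, year).

    Parameters
    ----------
    records : DataFrame
        Prepared occurrences with ``accepted_name``, ``year``, ``row``, ``col``.
    fields : dict
        Year -> 2D concentration array (mg/L); a missing year is a hard error.
    zero_cutoff : float
        Records matched to concentrations below this, or to NaN, are excluded.
    """
    years = records["year"].to_numpy()
    missing_years = sorted(set(int(y) for y in years) - set(fields))
    if missing_years:
        raise KeyError(
            f"no concentration field for year(s) {missing_years}"
        )
    conc = np.empty(len(records))
    rows = records["row"].to_numpy()
    cols = records["col"].to_numpy()
    for y in np.unique(years):
        sel = years == y
        conc[sel] = fields[int(y)][rows[sel], cols[sel]]

    is_missing = np.isnan(conc)
    below = ~is_missing & (conc < zero_cutoff)
    keep = ~is_missing & ~below
    out = records.loc[keep].copy()
    out["concentration"] = conc[keep]
    report = MatchReport(
        n_input=len(records),
        n_matched=int(keep.sum()),
        n_below_cutoff=int(below.sum()),
        n_missing=int(is_missing.sum()),
    )
    return out, report


def derive_tolerances(matched: pd.DataFrame, region_raster: np.ndarray,
                      level: str) -> pd.DataFrame:
    """Per (species, region) tolerance threshold = max matched concentration.

    Occurrences in cells carrying no region id (value <= 0) are ignored.
    Returns columns accepted_name, level, region_id, threshold_mg_per_L,
    n_matched.
    """
    region = region_raster[matched["row"].to_numpy(), matched["col"].to_numpy()]
    df = matched.assign(region_id=region)
    df = df[df["region_id"] > 0]
    if df.empty:
        return pd.DataFrame(columns=["accepted_name", "level", "region_id",
                                     "threshold_mg_per_L", "n_matched"])
    grouped = df.groupby(["accepted_name", "region_id"], sort=True)
    out = grouped["concentration"].agg(["max", "size"]).reset_index()
    out.columns = ["accepted_name", "region_id", "threshold_mg_per_L", "n_matched"]
    out.insert(1, "level", level)
    return out


def derive_tolerances_both_levels(matched: pd.DataFrame,
                                  ecoregion_raster: np.ndarray,
                                  realm_raster: np.ndarray) -> pd.DataFrame:
    eco = derive_tolerances(matched, ecoregion_raster, LEVEL_ECOREGION)
    mht = derive_tolerances(matched, realm_raster, LEVEL_REALM_MHT)
    return pd.concat([eco, mht], ignore_index=True)
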