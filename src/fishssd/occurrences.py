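"""Occurrence-record preparation.

Point occurrence records (species name, year, longitude, latitude) arrive as
delimited text from heterogeneous sources. Before they can be matched to
gridded concentrations they are

1. harmonized — raw names replaced by accepted scientific names via a synonym
   table (unmatched names are kept as their own accepted name, not dropped);
2. filtered — records missing a year or either coordinate, with a year
   outside the analysis window, or with out-of-range coordinates are removed,
   with per-reason counts reported;
3. gridded — each record is assigned the (row, col) of the 0.5-degree cell
   containing it;
4. deduplicated — at most one record per (accepted name, year, cell), keeping
   the first in input order. Exposure matching operates at pixel-year
   resolution, so finer duplicates carry no extra information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec

logger = logging.getLogger(__name__)

OCCURRENCE_COLUMNS = ["species_name", "year", "longitude", "latitude"]


class SynonymTable:
    """Functional mapping from synonym to accepted scientific name.

    Accepted names always map to themselves; a synonym may not be assigned to
    two different accepted names.
    """

    def __init__(self, mapping: dict[str, str] | pd.DataFrame):
        if isinstance(mapping, pd.DataFrame):
            pairs = list(zip(mapping["synonym"], mapping["accepted"]))
        else:
            pairs = list(mapping.items())
        self._map: dict[str, str] = {}
        for syn, acc in pairs:
            if syn in self._map and self._map[syn] != acc:
                raise ValueError(f"synonym {syn!r} maps to two accepted names")
            self._map[syn] = acc
        for acc in set(self._map.values()):
            if self._map.setdefault(acc, acc) != acc:
                raise ValueError(f"accepted name {acc!r} is itself a synonym")

    def resolve(self, name: str) -> str:
        return self._map.get(name, name)

    def __contains__(self, name: str) -> bool:
        return name in self._map

    def __len__(self) -> int:
        return len(self._map)


def harmonize_names(records: pd.DataFrame, synonyms: SynonymTable) -> pd.DataFrame:
    """Add an ``accepted_name`` column; unmatched raw names pass through.

    The record count never changes: an unmatched name is retained as its own
    accepted name (dropping it would silently shrink regional richness).
    """
    out = records.copy()
    raw = out["species_name"].astype(str)
    out["accepted_name"] = raw.map(synonyms.resolve)
    unmatched = (~raw.isin(out["accepted_name"])) & (~raw.map(synonyms.__contains__))
    n_unmatched = int(unmatched.sum())
    if n_unmatched:
        logger.info("harmonize_names: %d records with names absent from the synonym "
                    "table kept under their raw name", n_unmatched)
    return out


@dataclass
class FilterReport:
    n_input: int
    n_no_year: int
    n_no_coordinates: int
    n_out_of_window: int
    n_bad_coordinates: int

    @property
    def n_removed(self) -> int:
        return (self.n_no_year + self.n_no_coordinates
                + self.n_out_of_window + self.n_bad_coordinates)

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_removed

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reason": ["no_year", "no_coordinates", "out_of_window",
                           "bad_coordinates", "kept"],
                "count": [self.n_no_year, self.n_no_coordinates,
                          self.n_out_of_window, self.n_bad_coordinates,
                          self.n_kept],
            }
        )


def filter_records(records: pd.DataFrame,
                   window: tuple[int, int]) -> tuple[pd.DataFrame, FilterReport]:
    """Drop records without year/coordinates, outside the year window, or with
    coordinates outside [-180, 180] x [-90, 90]. Reasons are counted in the
    order listed; each record is counted once, under the first reason that
    applies."""
    year_min, year_max = window
    year = pd.to_numeric(records["year"], errors="coerce")
    lon = pd.to_numeric(records["longitude"], errors="coerce")
    lat = pd.to_numeric(records["latitude"], errors="coerce")

    no_year = year.isna()
    no_coord = (lon.isna() | lat.isna()) & ~no_year
    out_window = ((year < year_min) | (year > year_max)) & ~no_year & ~no_coord
    bad_coord = (
        ((lon < -180) | (lon > 180) | (lat < -90) | (lat > 90))
        & ~no_year & ~no_coord & ~out_window
    )
    drop = no_year | no_coord | out_window | bad_coord

    report = FilterReport(
        n_input=len(records),
        n_no_year=int(no_year.sum()),
        n_no_coordinates=int(no_coord.sum()),
        n_out_of_window=int(out_window.sum()),
        n_bad_coordinates=int(bad_coord.sum()),
    )
    kept = records.loc[~drop].copy()
    kept["year"] = year[~drop].astype(int)
    logger.info("filter_records: kept %d of %d (removed %d)",
                report.n_kept, report.n_input, report.n_removed)
    return kept, report


def assign_cells(records: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Attach (row, col) grid indices; records outside the grid extent are
    dropped with a logged count (relevant for regional grids)."""
    out = records.copy()
    row, col = grid.cell_of(out["longitude"].to_numpy(),
                            out["latitude"].to_numpy())
    out["row"] = row
    out["col"] = col
    inside = (out["row"] >= 0) & (out["col"] >= 0) \
        & (out["row"] < grid.rows) & (out["col"] < grid.cols)
    n_outside = int((~inside).sum())
    if n_outside:
        logger.info("assign_cells: dropped %d records outside the grid extent",
                    n_outside)
    return out.loc[inside].reset_index(drop=True)


def deduplicate(records: pd.DataFrame) -> pd.DataFrame:
    """Keep the first record per (accepted_name, year, cell), in input order."""
    before = len(records)
    out = records.drop_duplicates(
        subset=["accepted_name", "year", "row", "col"], keep="first"
    ).reset_index(drop=True)
    logger.info("deduplicate: %d -> %d records", before, len(out))
    return out


def prepare_occurrences(records: pd.DataFrame, synonyms: SynonymTable,
                        window: tuple[int, int],
                        grid: GridSpec) -> tuple[pd.DataFrame, FilterReport]:
    """Full preparation: harmonize, filter, grid, deduplicate."""
    out = harmonize_names(records, synonyms)
    out, report = filter_records(out, window)
    out = assign_cells(out, grid)
    out = deduplicate(out)
    return out, report
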