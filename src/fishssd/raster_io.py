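"""Raster and table I/O.

All gridded layers are exchanged as NetCDF (classic format, written through
xarray's scipy engine) on the grid defined by a :class:`~fishssd.grid.GridSpec`,
with latitude/longitude cell-center coordinates and NaN as the missing value.
Tabular artifacts are plain CSV with a fixed, documented column order so that
reruns diff byte-for-byte.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .grid import GridSpec


def grid_coords(grid: GridSpec) -> dict:
    return {"lat": grid.lat_centers(), "lon": grid.lon_centers()}


def to_dataarray(values: np.ndarray, grid: GridSpec, name: str) -> xr.DataArray:
    if values.shape != (grid.rows, grid.cols):
        raise ValueError(
            f"array shape {values.shape} does not match grid ({grid.rows}, {grid.cols})"
        )
    return xr.DataArray(values, dims=("lat", "lon"), coords=grid_coords(grid), name=name)


def write_raster(path: Path | str, arrays: dict[str, np.ndarray], grid: GridSpec,
                 attrs: dict | None = None) -> None:
    """Write one or more co-registered layers to a classic NetCDF file."""
    ds = xr.Dataset({k: to_dataarray(v, grid, k) for k, v in arrays.items()})
    if attrs:
        ds.attrs.update(attrs)
    ds.to_netcdf(Path(path), engine="scipy")


def read_raster(path: Path | str) -> xr.Dataset:
    with xr.open_dataset(Path(path), engine="scipy") as ds:
        return ds.load()


def read_layer(path: Path | str, name: str) -> np.ndarray:
    return read_raster(path)[name].values


def grid_from_dataset(ds: xr.Dataset) -> GridSpec:
    """Recover the GridSpec from a dataset's lat/lon coordinates."""
    lat = ds["lat"].values
    lon = ds["lon"].values
    res = float(abs(lat[1] - lat[0])) if lat.size > 1 else float(abs(lon[1] - lon[0]))
    return GridSpec(
        rows=lat.size,
        cols=lon.size,
        resolution=res,
        lat0=float(lat[0] + res / 2),
        lon0=float(lon[0] - res / 2),
    )


def write_table(path: Path | str, df: pd.DataFrame, columns: list[str] | None = None) -> None:
    if columns is not None:
        df = df.loc[:, columns]
    df.to_csv(Path(path), index=False, lineterminator="\n")


def read_table(path: Path | str, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"required input table not found: {path}")
    try:
        return pd.read_csv(path, **kwargs)
    except pd.errors.ParserError as exc:  # surface the offending line number
        raise ValueError(f"malformed table {path}: {exc}") from exc
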