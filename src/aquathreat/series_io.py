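"""NetCDF round-trips for weekly series and extreme-indicator tables.

Files use the classic NetCDF3 format written through xarray's scipy
backend, with dimensions (row, col, year, week) for series and a flat
``cell`` dimension for indicator tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .synthetic_world import WeeklySeries


def series_to_netcdf(series: WeeklySeries, path: str | Path) -> None:
    ds = xr.Dataset(
        {series.variable: (("row", "col", "year", "week"), series.values)},
        attrs={
            "variable": series.variable,
            "units": "m3 s-1" if series.variable == "flow" else "degC",
        },
    )
    ds.to_netcdf(path, engine="scipy")


def series_from_netcdf(path: str | Path) -> WeeklySeries:
    with xr.open_dataset(path, engine="scipy") as ds:
        variable = str(ds.attrs["variable"])
        values = ds[variable].to_numpy()
    return WeeklySeries(
        values=values,
        variable=variable,
        n_years=values.shape[2],
        weeks_per_year=values.shape[3],
    )


def extremes_to_netcdf(extremes: pd.DataFrame, path: str | Path) -> None:
    """One NetCDF variable per indicator, indexed by flat cell id."""
    cols = [c for c in extremes.columns if c != "scenario_id"]
    ds = xr.Dataset(
        {c: (("cell",), extremes[c].to_numpy(float)) for c in cols},
        coords={"cell": extremes.index.to_numpy()},
    )
    if "scenario_id" in extremes.columns:
        ds.attrs["scenario_id"] = str(extremes["scenario_id"].iloc[0])
    ds.to_netcdf(path, engine="scipy")


def extremes_from_netcdf(path: str | Path) -> pd.DataFrame:
    with xr.open_dataset(path, engine="scipy") as ds:
        df = ds.to_dataframe()
        if "scenario_id" in ds.attrs:
            df["scenario_id"] = ds.attrs["scenario_id"]
    df.index.name = "cell"
    return df
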