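"""Readers and writers for the pipeline's delimited interchange formats.

Abundance tables are delimited text, stations as rows (first column the
station id) and features as header columns; tab is the default dialect and
comma is auto-detected.  Taxonomies are 4-column text (node_id, parent_id,
rank, name).  Distance matrices are square with station ids as both header
and first column.  Climate grids are long-form CSV (lat,lon,value) or
NetCDF when the filename ends in ``.nc``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .climate import ClimateGrid
from .errors import InputError
from .taxonomy import Taxonomy


def _sniff_sep(path: Path) -> str:
    head = path.read_text().splitlines()[0] if path.stat().st_size else ""
    return "\t" if "\t" in head else ","


def read_feature_table(path, sep: str | None = None, feature_kind: str | None = None) -> pd.DataFrame:
    """Read and validate a stations × features abundance table."""
    path = Path(path)
    sep = sep or _sniff_sep(path)
    header = path.read_text().splitlines()[0].split(sep)[1:]
    dupes = sorted({h for h in header if header.count(h) > 1})
    if dupes:
        raise InputError(f"duplicate feature column(s) in {path.name}: {dupes[:5]}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise InputError(f"duplicate station id(s) in {path.name}: {dupes[:5]}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise InputError(f"non-numeric cell in {path.name}: {exc}") from None
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise InputError(f"missing value in {path.name} at station {df.index[r]!r}, feature {df.columns[c]!r}")
    if (df.to_numpy() < 0).any():
        r, c = np.argwhere(df.to_numpy() < 0)[0]
        raise InputError(f"negative value in {path.name} at station {df.index[r]!r}, feature {df.columns[c]!r}")
    if feature_kind:
        df.attrs["feature_kind"] = feature_kind
    return df


def write_feature_table(table: pd.DataFrame, path, sep: str = "\t") -> None:
    table.to_csv(Path(path), sep=sep, index_label="station_id")


def read_taxonomy(path, sep: str | None = None) -> Taxonomy:
    path = Path(path)
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    return Taxonomy(df)


def write_taxonomy(taxonomy: Taxonomy, path, sep: str = "\t") -> None:
    taxonomy.to_frame().to_csv(Path(path), sep=sep, index=False)


def read_environment(path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    sep = sep or _sniff_sep(path)
    env = pd.read_csv(path, sep=sep, index_col=0)
    if "latitude" in env.columns and "altered_latitude" not in env.columns:
        env["altered_latitude"] = 90.0 - env["latitude"].astype(float)
    return env


def write_environment(env: pd.DataFrame, path, sep: str = "\t") -> None:
    env.to_csv(Path(path), sep=sep, index_label="station_id")


def read_distance_matrix(path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    sep = sep or _sniff_sep(path)
    d = pd.read_csv(path, sep=sep, index_col=0)
    if list(d.index) != list(d.columns):
        raise InputError(f"distance matrix in {path.name} must have matching row/column ids")
    return d.astype(float)


def write_distance_matrix(dist: pd.DataFrame, path, sep: str = "\t") -> None:
    dist.to_csv(Path(path), sep=sep, index_label="station_id")


def read_climate_grid(path, period_label: str = "") -> ClimateGrid:
    """Read a grid from long-form CSV (lat,lon,value) or NetCDF (*.nc)."""
    path = Path(path)
    if path.suffix == ".nc":
        import xarray as xr

        ds = xr.open_dataset(path, engine="scipy")
        sst = ds["sst"]
        return ClimateGrid(
            latitudes=ds["lat"].values,
            longitudes=ds["lon"].values,
            sst=sst.values,
            period_label=period_label or str(ds.attrs.get("period_label", "")),
            ice_mask=ds["ice_mask"].values.astype(bool) if "ice_mask" in ds else None,
        )
    df = pd.read_csv(path)
    for col in ("lat", "lon", "value"):
        if col not in df.columns:
            raise InputError(f"grid CSV {path.name} must have columns lat,lon,value")
    pivot = df.pivot(index="lat", columns="lon", values="value").sort_index()
    mask = None
    if "ice" in df.columns:
        mask = (
            df.pivot(index="lat", columns="lon", values="ice").sort_index().to_numpy() > 0
        )
    return ClimateGrid(
        latitudes=pivot.index.to_numpy(),
        longitudes=pivot.columns.to_numpy(dtype=float),
        sst=pivot.to_numpy(),
        period_label=period_label,
        ice_mask=mask,
    )


def write_climate_grid(grid: ClimateGrid, path) -> None:
    """Write a grid as long-form CSV, or NetCDF when the name ends in .nc."""
    path = Path(path)
    if path.suffix == ".nc":
        import xarray as xr

        ds = xr.Dataset(
            {
                "sst": (("lat", "lon"), grid.sst),
                "ice_mask": (("lat", "lon"), grid.ice_mask.astype(np.int8)),
            },
            coords={"lat": grid.latitudes, "lon": grid.longitudes},
            attrs={"period_label": grid.period_label},
        )
        ds.to_netcdf(path, engine="scipy")
        return
    lat_grid, lon_grid = np.meshgrid(grid.latitudes, grid.longitudes, indexing="ij")
    pd.DataFrame(
        {
            "lat": lat_grid.ravel(),
            "lon": lon_grid.ravel(),
            "value": grid.sst.ravel(),
            "ice": grid.ice_mask.astype(int).ravel(),
        }
    ).to_csv(path, index=False)


def write_run_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialise {type(obj)}")
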