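"""Read/write daily climate series in two dialects.

* **Long CSV** — columns ``cell_id,date,tmin,tmax,precip,radiation,
  rel_humidity,wind`` (header mandatory, ISO-8601 dates), plus optional
  ``latitude``, ``scenario_id`` and ``member_id`` provenance columns which
  the writer always emits.  Any number of cells per file; one scenario and
  member per file.
* **Gridded NetCDF** — CF-style NetCDF3 (written through xarray's scipy
  backend) with dimensions ``(time, y, x)``, one variable per field with a
  ``units`` attribute, a ``lat(y, x)`` coordinate, and scenario/member
  stored as global attributes.  Cells must form a complete regular grid
  with identifiers ``"r{row}c{col}"`` (the generator's convention).

Both writers round-trip float64 values exactly and are byte-stable for a
fixed input.
"""

from __future__ import annotations

import os
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .climate import UNITS, VARIABLES, DailyClimateSeries
from .errors import FormatError

_CSV_REQUIRED = ("cell_id", "date") + VARIABLES
_CELL_RE = re.compile(r"^r(\d+)c(\d+)$")


def _as_list(series) -> list[DailyClimateSeries]:
    if isinstance(series, DailyClimateSeries):
        return [series]
    return list(series)


def _check_overwrite(path: Path, overwrite: bool) -> None:
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".nc", ".nc3", ".cdf", ".netcdf"):
        return "netcdf"
    raise FormatError(f"cannot infer format from {path.name!r}; pass format=")


# ----------------------------------------------------------------------
# CSV dialect
# ----------------------------------------------------------------------
def _write_csv(series_list: Sequence[DailyClimateSeries], path: Path) -> None:
    frames = []
    for s in series_list:
        df = s.data.reset_index(names="date")
        df.insert(0, "cell_id", s.cell_id)
        df["latitude"] = s.latitude
        df["scenario_id"] = s.scenario_id
        df["member_id"] = s.member_id
        frames.append(df[list(_CSV_REQUIRED) + ["latitude", "scenario_id", "member_id"]])
    out = pd.concat(frames, ignore_index=True)
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    # default float formatting is the shortest repr, which round-trips exactly
    out.to_csv(path, index=False)


def _read_csv(path: Path) -> list[DailyClimateSeries]:
    df = pd.read_csv(path)
    missing = [c for c in _CSV_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing columns: {', '.join(missing)}")
    df["date"] = pd.to_datetime(df["date"], format="%Y-%m-%d")
    out = []
    for cell_id, group in df.groupby("cell_id", sort=True):
        group = group.sort_values("date")
        data = group.set_index("date")[list(VARIABLES)]
        data.index.name = None
        out.append(
            DailyClimateSeries(
                cell_id=str(cell_id),
                latitude=float(group["latitude"].iloc[0])
                if "latitude" in group
                else float("nan"),
                data=data,
                scenario_id=str(group["scenario_id"].iloc[0])
                if "scenario_id" in group
                else "unknown",
                member_id=int(group["member_id"].iloc[0])
                if "member_id" in group
                else 0,
            )
        )
    return out


# ----------------------------------------------------------------------
# Gridded NetCDF dialect
# ----------------------------------------------------------------------
def _grid_layout(series_list: Sequence[DailyClimateSeries]) -> tuple[int, int]:
    coords = {}
    for s in series_list:
        m = _CELL_RE.match(s.cell_id)
        if not m:
            raise FormatError(
                f"gridded dialect needs 'r<row>c<col>' cell ids; got {s.cell_id!r} "
                "(use the CSV dialect for irregular cell sets)"
            )
        coords[s.cell_id] = (int(m.group(1)), int(m.group(2)))
    rows = {r for r, _ in coords.values()}
    cols = {c for _, c in coords.values()}
    ny, nx = max(rows) + 1, max(cols) + 1
    if len(coords) != ny * nx or rows != set(range(ny)) or cols != set(range(nx)):
        raise FormatError("cells do not form a complete r x c grid")
    return ny, nx


def _write_netcdf(series_list: Sequence[DailyClimateSeries], path: Path) -> None:
    ny, nx = _grid_layout(series_list)
    ref = series_list[0]
    time = ref.data.index
    scenarios = {s.scenario_id for s in series_list}
    members = {s.member_id for s in series_list}
    if len(scenarios) > 1 or len(members) > 1:
        raise FormatError("one scenario and one member per gridded file")

    arrays = {v: np.full((len(time), ny, nx), np.nan) for v in VARIABLES}
    lat = np.full((ny, nx), np.nan)
    for s in series_list:
        if not s.data.index.equals(time):
            raise FormatError("all cells in a gridded file must share dates")
        r, c = map(int, _CELL_RE.match(s.cell_id).groups())
        lat[r, c] = s.latitude
        for v in VARIABLES:
            arrays[v][:, r, c] = s.data[v].to_numpy()

    ds = xr.Dataset(
        data_vars={
            v: (("time", "y", "x"), arrays[v], {"units": UNITS[v]})
            for v in VARIABLES
        },
        coords={
            "time": ("time", time),
            "y": ("y", np.arange(ny, dtype=np.int32)),
            "x": ("x", np.arange(nx, dtype=np.int32)),
            "lat": (("y", "x"), lat, {"units": "degrees_north"}),
        },
        attrs={
            "Conventions": "CF-1.8",
            "scenario_id": ref.scenario_id,
            "member_id": ref.member_id,
            "cell_id_convention": "r{y}c{x}",
        },
    )
    encoding = {
        "time": {"units": "days since 1900-01-01", "calendar": "standard",
                 "dtype": "int32"}
    }
    ds.to_netcdf(path, engine="scipy", format="NETCDF3_64BIT", encoding=encoding)


def _read_netcdf(path: Path) -> list[DailyClimateSeries]:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    missing = [v for v in VARIABLES if v not in ds.data_vars]
    if missing:
        raise FormatError(f"{path.name}: missing variables: {', '.join(missing)}")
    time = pd.DatetimeIndex(ds["time"].values)
    lat = ds["lat"].values
    scenario = str(ds.attrs.get("scenario_id", "unknown"))
    member = int(ds.attrs.get("member_id", 0))
    out = []
    for r in range(ds.sizes["y"]):
        for c in range(ds.sizes["x"]):
            data = pd.DataFrame(
                {v: ds[v].values[:, r, c] for v in VARIABLES}, index=time
            )
            out.append(
                DailyClimateSeries(
                    cell_id=f"r{r}c{c}",
                    latitude=float(lat[r, c]),
                    data=data,
                    scenario_id=scenario,
                    member_id=member,
                )
            )
    return out


def write_cell_field(
    values: "pd.Series",
    path: str | os.PathLike,
    name: str = "value",
    units: str = "1",
    overwrite: bool = False,
) -> Path:
    """Write one per-cell scalar field (index = ``r{row}c{col}`` cell ids)
    as a small (y, x) NetCDF map; NaN marks undefined cells."""
    path = Path(path)
    _check_overwrite(path, overwrite)
    coords = {}
    for cell_id in values.index:
        m = _CELL_RE.match(str(cell_id))
        if not m:
            raise FormatError(f"cell field needs 'r<row>c<col>' ids; got {cell_id!r}")
        coords[cell_id] = (int(m.group(1)), int(m.group(2)))
    ny = max(r for r, _ in coords.values()) + 1
    nx = max(c for _, c in coords.values()) + 1
    grid = np.full((ny, nx), np.nan)
    for cell_id, (r, c) in coords.items():
        grid[r, c] = float(values.loc[cell_id])
    ds = xr.Dataset(
        data_vars={name: (("y", "x"), grid, {"units": units})},
        coords={"y": np.arange(ny, dtype=np.int32),
                "x": np.arange(nx, dtype=np.int32)},
        attrs={"Conventions": "CF-1.8"},
    )
    ds.to_netcdf(path, engine="scipy", format="NETCDF3_64BIT")
    return path


# ----------------------------------------------------------------------
# public surface
# ----------------------------------------------------------------------
def write_series(
    series,
    path: str | os.PathLike,
    format: str | None = None,
    overwrite: bool = False,
) -> Path:
    """Write one series or a collection to ``path`` in the given dialect."""
    path = Path(path)
    fmt = _infer_format(path, format)
    _check_overwrite(path, overwrite)
    series_list = _as_list(series)
    if not series_list:
        raise FormatError("nothing to write: empty series collection")
    if fmt == "csv":
        _write_csv(series_list, path)
    elif fmt == "netcdf":
        _write_netcdf(series_list, path)
    else:
        raise FormatError(f"unsupported format {fmt!r}; use 'csv' or 'netcdf'")
    return path


def read_series(
    path: str | os.PathLike, format: str | None = None
) -> list[DailyClimateSeries]:
    """Read a series collection, sorted by (member_id, cell_id)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        out = _read_csv(path)
    elif fmt == "netcdf":
        out = _read_netcdf(path)
    else:
        raise FormatError(f"unsupported format {fmt!r}; use 'csv' or 'netcdf'")
    return sorted(out, key=lambda s: (s.member_id, s.cell_id))
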