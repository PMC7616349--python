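"""Gridded forecast ingestion and linkage to small areas.

Reads CF-style NetCDF sub-daily temperature forecasts (e.g. the 0.4 degree
open-data product of a global weather centre), normalises units and
coordinate order, aggregates to local-calendar-day means, and extracts a
daily series per area at its population-weighted centroid by nearest-cell or
bilinear interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AreaTable",
    "GriddedForecast",
    "DailyGrids",
    "read_forecast",
    "daily_mean",
    "link_areas",
    "read_daily_series_csv",
]

PHYSICAL_BOUNDS_C = (-90.0, 60.0)


@dataclass
class AreaTable:
    """Area metadata: one row per (area, age group).

    Columns: area_id, region, lon, lat (population-weighted centroid),
    age_group, population ``p_aj``, annual mortality rate ``m_aj``.
    """

    df: pd.DataFrame

    REQUIRED = ("area_id", "region", "lon", "lat", "age_group", "population", "annual_rate")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"area table missing columns: {missing}")
        if (self.df["population"] <= 0).any():
            raise ValueError("populations must be positive")
        r = self.df["annual_rate"]
        if ((r <= 0) | (r >= 1)).any():
            raise ValueError("annual rates must lie in (0, 1)")
        if self.df.duplicated(["area_id", "age_group"]).any():
            raise ValueError("duplicate (area_id, age_group) rows")

    @property
    def centroids(self) -> pd.DataFrame:
        """One row per area: area_id, region, lon, lat."""
        return (
            self.df[["area_id", "region", "lon", "lat"]]
            .drop_duplicates("area_id")
            .reset_index(drop=True)
        )

    def baseline_daily_deaths(self) -> pd.Series:
        """b_aj = p_aj * m_aj / 365.25, indexed by (area_id, age_group)."""
        b = self.df["population"] * self.df["annual_rate"] / 365.25
        return pd.Series(
            b.to_numpy(), index=pd.MultiIndex.from_frame(self.df[["area_id", "age_group"]])
        )

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "AreaTable":
        return cls(pd.read_csv(path))


@dataclass
class GriddedForecast:
    """Sub-daily temperature forecast on a regular lon/lat grid, in degC."""

    issue_time: np.datetime64
    valid_times: np.ndarray  # datetime64[ns]
    lat: np.ndarray
    lon: np.ndarray
    temperature: np.ndarray  # (time, lat, lon), degC

    def __post_init__(self):
        for name, coord in (("lat", self.lat), ("lon", self.lon)):
            if coord.size > 1 and not np.all(np.diff(coord) > 0):
                raise ValueError(f"{name} coordinates must be strictly increasing")
        if self.temperature.shape != (
            len(self.valid_times),
            len(self.lat),
            len(self.lon),
        ):
            raise ValueError("temperature shape does not match coordinates")
        finite = np.isfinite(self.temperature)
        if not finite.any(axis=(1, 2)).all():
            raise ValueError("forecast contains an all-missing time slice")
        vals = self.temperature[finite]
        if vals.size and (vals.min() < PHYSICAL_BOUNDS_C[0] or vals.max() > PHYSICAL_BOUNDS_C[1]):
            raise ValueError(
                f"temperatures outside physical bounds {PHYSICAL_BOUNDS_C} degC "
                "after unit normalisation — check the units attribute"
            )


_KELVIN_UNITS = {"k", "kelvin", "degk"}
_CELSIUS_UNITS = {"degc", "c", "celsius", "degrees_celsius", "deg_c"}


def read_forecast(path_or_ds, temp_var: str | None = None) -> GriddedForecast:
    """Read a CF-style NetCDF forecast into a :class:`GriddedForecast`.

    Kelvin is converted to Celsius based on the variable's ``units``
    attribute; a missing units attribute is an error (the scale is never
    guessed).  Latitudes are reordered ascending and longitudes normalised
    to [-180, 180).
    """
    import xarray as xr

    ds = path_or_ds if isinstance(path_or_ds, xr.Dataset) else xr.open_dataset(path_or_ds)
    if temp_var is None:
        if "t2m" in ds.data_vars:
            temp_var = "t2m"
        else:
            cands = [v for v in ds.data_vars if ds[v].ndim == 3]
            if len(cands) != 1:
                raise ValueError(
                    f"cannot identify the temperature variable among {list(ds.data_vars)}"
                )
            temp_var = cands[0]
    da = ds[temp_var]
    lat_name = next((n for n in ("lat", "latitude") if n in da.dims), None)
    lon_name = next((n for n in ("lon", "longitude") if n in da.dims), None)
    time_name = next((n for n in ("time", "valid_time") if n in da.dims), None)
    if lat_name is None or lon_name is None or time_name is None:
        raise ValueError(f"missing coordinate variable among dims {da.dims}")
    units = da.attrs.get("units")
    if units is None:
        raise ValueError(
            f"variable {temp_var!r} has no units attribute; refusing to guess "
            "whether values are Kelvin or Celsius"
        )
    u = str(units).strip().lower()
    if u in _KELVIN_UNITS:
        da = da - 273.15
    elif u in _CELSIUS_UNITS:
        pass
    else:
        raise ValueError(f"unrecognised temperature units {units!r}")
    # normalise longitudes to [-180, 180) then sort both axes ascending
    lon_vals = ((np.asarray(ds[lon_name].values, dtype=float) + 180.0) % 360.0) - 180.0
    da = da.assign_coords({lon_name: lon_vals}).sortby([lat_name, lon_name])
    da = da.transpose(time_name, lat_name, lon_name)
    issue = ds.attrs.get("issue_time")
    times = np.asarray(da[time_name].values)
    issue_time = np.datetime64(issue) if issue is not None else times.min()
    return GriddedForecast(
        issue_time=np.datetime64(issue_time, "ns"),
        valid_times=times.astype("datetime64[ns]"),
        lat=np.asarray(da[lat_name].values, dtype=float),
        lon=np.asarray(da[lon_name].values, dtype=float),
        temperature=np.asarray(da.values, dtype=float),
    )


@dataclass
class DailyGrids:
    """Per-date daily-mean temperature grids (dates, lat, lon)."""

    issue_time: np.datetime64
    dates: pd.DatetimeIndex
    lat: np.ndarray
    lon: np.ndarray
    temperature: np.ndarray  # (date, lat, lon)


def daily_mean(
    forecast: GriddedForecast,
    timezone_offset: float = 0.0,
    min_steps: int = 4,
) -> DailyGrids:
    """Aggregate sub-daily fields to local-calendar-day means per grid cell.

    ``timezone_offset`` (hours, UTC+offset defines the local day; fixed, no
    DST).  Days observed with fewer than ``min_steps`` sub-daily steps are
    dropped with a warning.
    """
    times = pd.DatetimeIndex(forecast.valid_times) + pd.Timedelta(
        hours=timezone_offset
    )
    days = times.floor("D")
    uniq = days.unique().sort_values()
    keep_dates, slabs = [], []
    for d in uniq:
        sel = days == d
        n = int(sel.sum())
        if n < min_steps:
            warnings.warn(
                f"dropping day {d.date()} with only {n} sub-daily steps "
                f"(minimum {min_steps})"
            )
            continue
        slabs.append(np.nanmean(forecast.temperature[sel], axis=0))
        keep_dates.append(d)
    if not keep_dates:
        raise ValueError("no calendar day retains enough sub-daily steps")
    return DailyGrids(
        issue_time=forecast.issue_time,
        dates=pd.DatetimeIndex(keep_dates),
        lat=forecast.lat,
        lon=forecast.lon,
        temperature=np.stack(slabs),
    )


def _nearest_index(coord: np.ndarray, value: float) -> int:
    return int(np.argmin(np.abs(coord - value)))


def _nearest_value(grid2d: np.ndarray, iy: int, ix: int) -> float:
    """Cell value, falling back to the nearest non-missing within one ring."""
    v = grid2d[iy, ix]
    if np.isfinite(v):
        return float(v)
    ny, nx = grid2d.shape
    best, bestd = None, np.inf
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            y, x = iy + dy, ix + dx
            if 0 <= y < ny and 0 <= x < nx and np.isfinite(grid2d[y, x]):
                d = dy * dy + dx * dx
                if d < bestd:
                    best, bestd = float(grid2d[y, x]), d
    if best is None:
        raise ValueError("no non-missing grid value within one ring of the centroid")
    return best


def _bilinear(grids: DailyGrids, lon: float, lat: float, t: int) -> float:
    ix = int(np.searchsorted(grids.lon, lon) - 1)
    iy = int(np.searchsorted(grids.lat, lat) - 1)
    if ix < 0 or iy < 0 or ix + 1 >= len(grids.lon) or iy + 1 >= len(grids.lat):
        raise ValueError("outside hull")
    x0, x1 = grids.lon[ix], grids.lon[ix + 1]
    y0, y1 = grids.lat[iy], grids.lat[iy + 1]
    fx = (lon - x0) / (x1 - x0)
    fy = (lat - y0) / (y1 - y0)
    z = grids.temperature[t]
    return float(
        z[iy, ix] * (1 - fx) * (1 - fy)
        + z[iy, ix + 1] * fx * (1 - fy)
        + z[iy + 1, ix] * (1 - fx) * fy
        + z[iy + 1, ix + 1] * fx * fy
    )


def link_areas(
    grids: DailyGrids, areas: AreaTable, method: str = "nearest"
) -> pd.DataFrame:
    """Daily forecast series per area from its centroid's grid cell.

    ``nearest`` takes the value of the closest grid node; ``bilinear`` the
    weighted mean of the four surrounding nodes (falling back to nearest,
    with a warning, for centroids outside the interior hull).  Returns a tidy
    frame (area_id, date, tmean, lead_days).
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown linkage method {method!r}")
    cents = areas.centroids
    lon_lo, lon_hi = grids.lon.min(), grids.lon.max()
    lat_lo, lat_hi = grids.lat.min(), grids.lat.max()
    bad = cents[
        (cents["lon"] < lon_lo)
        | (cents["lon"] > lon_hi)
        | (cents["lat"] < lat_lo)
        | (cents["lat"] > lat_hi)
    ]
    if len(bad):
        raise ValueError(
            f"centroids outside the forecast grid bounding box: "
            f"{bad['area_id'].tolist()}"
        )
    issue_day = pd.Timestamp(grids.issue_time).floor("D")
    rows = []
    for _, c in cents.iterrows():
        on_node = method == "nearest"
        for t, d in enumerate(grids.dates):
            if method == "bilinear":
                try:
                    val = _bilinear(grids, float(c["lon"]), float(c["lat"]), t)
                except ValueError:
                    if t == 0:
                        warnings.warn(
                            f"centroid of {c['area_id']} outside interior hull; "
                            "falling back to nearest-cell linkage"
                        )
                    val = _nearest_value(
                        grids.temperature[t],
                        _nearest_index(grids.lat, float(c["lat"])),
                        _nearest_index(grids.lon, float(c["lon"])),
                    )
            else:
                val = _nearest_value(
                    grids.temperature[t],
                    _nearest_index(grids.lat, float(c["lat"])),
                    _nearest_index(grids.lon, float(c["lon"])),
                )
            rows.append(
                {
                    "area_id": c["area_id"],
                    "date": pd.Timestamp(d),
                    "tmean": val,
                    "lead_days": int((pd.Timestamp(d) - issue_day).days),
                }
            )
    out = pd.DataFrame(rows)
    if (out["lead_days"] < 0).any():
        raise ValueError("forecast contains valid dates before the issue date")
    return out


def read_daily_series_csv(path) -> pd.DataFrame:
    """Plain-CSV ingest bypassing gridding: columns area_id, date, tmean."""
    df = pd.read_csv(path, parse_dates=["date"])
    missing = {"area_id", "date", "tmean"} - set(df.columns)
    if missing:
        raise ValueError(f"daily series CSV missing columns: {sorted(missing)}")
    if df.duplicated(["area_id", "date"]).any():
        raise ValueError("duplicate (area_id, date) rows in daily series")
    if "lead_days" not in df.columns:
        df["lead_days"] = (df["date"] - df["date"].min()).dt.days
    return df
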