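"""Synthetic calibration data, area tables and forecast grids with known truth.

The generator emulates the three data sources the forecasting pipeline
consumes — daily mortality/temperature series for risk-function calibration,
an area table with populations and baseline annual mortality rates, and a
gridded sub-daily temperature forecast — from a ground-truth exposure–response
model that is simple enough to integrate in closed form.  The truth is a
V-shaped log relative risk in temperature (vertex at the true MMT, linear
heat and cold arms) distributed over lags with normalised geometric weights,
so every downstream stage (cross-basis fit, MMT recovery, excess-death
attribution) can be checked against exact analytic values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forecast import AreaTable

__all__ = [
    "TrueCurveSpec",
    "SyntheticScenario",
    "generate_temperature_series",
    "generate_deaths",
    "generate_calibration_data",
    "generate_area_table",
    "generate_forecast_grid",
]

AGE_GROUPS = ("0-64", "65-84", "85+")
# district-scale defaults: populations and annual all-cause rates per age group
AGE_POPULATIONS = (60_000, 25_000, 8_000)
AGE_RATES = (0.003, 0.030, 0.120)
AGE_SLOPE_FACTORS = (0.5, 1.0, 1.5)  # risk steepens with age


@dataclass(frozen=True)
class TrueCurveSpec:
    """Ground-truth exposure–response curve: V-shape with geometric lags.

    ``logrr(x) = slope_heat * (x - mmt)_+ + slope_cold * (mmt - x)_+`` is
    distributed over lags 0..max_lag with weights ``decay^l`` normalised to
    sum to one, so the *cumulative* log-RR of sustained exposure at ``x``
    equals ``logrr(x)`` exactly.
    """

    mmt_true: float = 18.0
    slope_heat: float = 0.03  # log-RR per degC above the MMT
    slope_cold: float = 0.01  # log-RR per degC below the MMT
    lag_decay: float = 0.6
    max_lag: int = 21

    def __post_init__(self):
        if self.slope_heat < 0 or self.slope_cold < 0:
            raise ValueError("slopes must be non-negative")
        if not 0.0 < self.lag_decay <= 1.0:
            raise ValueError("lag_decay must be in (0, 1]")
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")

    def logrr(self, x) -> np.ndarray:
        """Cumulative log relative risk at temperature ``x`` (vector ok)."""
        x = np.asarray(x, dtype=float)
        return self.slope_heat * np.clip(x - self.mmt_true, 0.0, None) + (
            self.slope_cold * np.clip(self.mmt_true - x, 0.0, None)
        )

    def lag_weights(self) -> np.ndarray:
        w = self.lag_decay ** np.arange(self.max_lag + 1)
        return w / w.sum()

    def to_dict(self) -> dict:
        return {
            "mmt_true": self.mmt_true,
            "slope_heat": self.slope_heat,
            "slope_cold": self.slope_cold,
            "lag_decay": self.lag_decay,
            "max_lag": self.max_lag,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrueCurveSpec":
        return cls(**d)


@dataclass(frozen=True)
class SyntheticScenario:
    """Study conditions for the synthetic fixture bundle."""

    n_areas: int = 20
    n_age_groups: int = 3
    n_days: int = 3650
    seed: int = 0
    temp_mean: float = 12.0  # degC, annual mean
    temp_amplitude: float = 8.0  # degC, seasonal half-range
    temp_noise_sd: float = 3.0  # degC, day-to-day weather noise
    start_date: str = "2010-01-01"
    max_lag: int = 21
    populations: tuple[int, ...] = AGE_POPULATIONS
    annual_rates: tuple[float, ...] = AGE_RATES
    # bounding box the area centroids are scattered over (lon/lat degrees)
    lon_range: tuple[float, float] = (-2.0, 0.0)
    lat_range: tuple[float, float] = (51.0, 53.0)

    def __post_init__(self):
        if self.n_days <= 0:
            raise ValueError("n_days must be positive")
        if self.n_days <= self.max_lag:
            raise ValueError("n_days must exceed max_lag")
        if self.n_age_groups > len(self.populations):
            raise ValueError("not enough population defaults for n_age_groups")
        if any(p <= 0 for p in self.populations):
            raise ValueError("populations must be positive")
        if any(not 0.0 < r < 1.0 for r in self.annual_rates):
            raise ValueError("annual rates must lie in (0, 1)")

    @property
    def age_groups(self) -> tuple[str, ...]:
        return AGE_GROUPS[: self.n_age_groups]

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")

    def area_ids(self) -> list[str]:
        return [f"A{i:04d}" for i in range(self.n_areas)]

    def true_curves(self) -> dict[tuple[str, str], TrueCurveSpec]:
        """Per (area, age) ground-truth curves, deterministic under the seed."""
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 11]))
        out: dict[tuple[str, str], TrueCurveSpec] = {}
        for aid in self.area_ids():
            mmt = float(rng.uniform(17.0, 19.0))
            sh = float(rng.uniform(0.02, 0.04))
            sc = float(rng.uniform(0.005, 0.015))
            for g, fac in zip(self.age_groups, AGE_SLOPE_FACTORS):
                out[(aid, g)] = TrueCurveSpec(
                    mmt_true=mmt,
                    slope_heat=sh * fac,
                    slope_cold=sc * fac,
                    lag_decay=0.6,
                    max_lag=self.max_lag,
                )
        return out

    def baseline_daily_deaths(self, age_group: str) -> float:
        i = self.age_groups.index(age_group)
        return self.populations[i] * self.annual_rates[i] / 365.25


def generate_temperature_series(scenario: SyntheticScenario) -> pd.DataFrame:
    """Daily mean temperature per area: seasonal sinusoid plus Gaussian noise.

    Returns a tidy frame (area_id, date, tmean).  The seasonal cycle peaks in
    mid-July; each area carries a small fixed offset so areas differ.
    """
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 7]))
    dates = scenario.dates
    doy = dates.dayofyear.to_numpy(dtype=float)
    season = np.sin(2.0 * np.pi * (doy - 196.0 + 365.25 / 4.0) / 365.25)
    frames = []
    for aid in scenario.area_ids():
        offset = float(rng.normal(0.0, 0.5))
        noise = rng.normal(0.0, scenario.temp_noise_sd, size=len(dates))
        tmean = scenario.temp_mean + offset + scenario.temp_amplitude * season + noise
        frames.append(pd.DataFrame({"area_id": aid, "date": dates, "tmean": tmean}))
    return pd.concat(frames, ignore_index=True)


def realized_cumulative_logrr(
    temps: np.ndarray, curve: TrueCurveSpec
) -> np.ndarray:
    """Lag-weighted cumulative log-RR realised on each day with full history.

    Day ``t`` (for ``t >= max_lag``) accrues ``sum_l w_l * logrr(x_{t-l})``.
    Returns a vector of length ``len(temps) - max_lag``.
    """
    temps = np.asarray(temps, dtype=float)
    L = curve.max_lag
    if temps.shape[0] <= L:
        raise ValueError(
            f"series of length {temps.shape[0]} too short for max_lag={L}"
        )
    r = curve.logrr(temps)
    w = curve.lag_weights()
    n = temps.shape[0]
    out = np.zeros(n - L)
    for l in range(L + 1):
        out += w[l] * r[L - l : n - l]
    return out


def generate_deaths(
    temps: np.ndarray,
    curve: TrueCurveSpec,
    baseline_daily_deaths: float,
    seed: int,
) -> np.ndarray:
    """Poisson daily death counts under the ground-truth lagged risk.

    Counts are drawn for days with a complete lag history only (length
    ``len(temps) - max_lag``), with mean
    ``baseline * exp(sum_l w_l logrr(x_{t-l}))``.
    """
    if baseline_daily_deaths <= 0:
        raise ValueError("baseline_daily_deaths must be positive")
    beta = realized_cumulative_logrr(temps, curve)
    rng = np.random.default_rng(seed)
    return rng.poisson(baseline_daily_deaths * np.exp(beta))


def generate_calibration_data(
    scenario: SyntheticScenario,
) -> tuple[pd.DataFrame, dict[tuple[str, str], TrueCurveSpec]]:
    """Full calibration bundle: (area_id, age_group, date, tmean, deaths).

    Death counts cover only days with a complete lag history (the first
    ``max_lag`` days carry deaths = NA), matching what the fitting stage can
    use.  Returns the tidy frame and the ground-truth curve per (area, age).
    """
    temps = generate_temperature_series(scenario)
    truths = scenario.true_curves()
    seeds = np.random.SeedSequence([scenario.seed, 23]).generate_state(
        scenario.n_areas * scenario.n_age_groups
    )
    frames = []
    k = 0
    for aid in scenario.area_ids():
        t = temps.loc[temps["area_id"] == aid]
        for g in scenario.age_groups:
            curve = truths[(aid, g)]
            deaths = generate_deaths(
                t["tmean"].to_numpy(),
                curve,
                scenario.baseline_daily_deaths(g),
                int(seeds[k] % (2**31)),
            )
            k += 1
            df = t.copy()
            df["age_group"] = g
            col = np.full(len(df), np.nan)
            col[scenario.max_lag :] = deaths
            df["deaths"] = col
            frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[["area_id", "age_group", "date", "tmean", "deaths"]], truths


def generate_area_table(scenario: SyntheticScenario) -> AreaTable:
    """Area table with population-weighted centroids and per-age baselines."""
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 31]))
    rows = []
    for i, aid in enumerate(scenario.area_ids()):
        lon = float(rng.uniform(*scenario.lon_range))
        lat = float(rng.uniform(*scenario.lat_range))
        region = f"R{i % 4}"
        for g, p, m in zip(
            scenario.age_groups, scenario.populations, scenario.annual_rates
        ):
            rows.append(
                {
                    "area_id": aid,
                    "region": region,
                    "lon": lon,
                    "lat": lat,
                    "age_group": g,
                    "population": p,
                    "annual_rate": m,
                }
            )
    return AreaTable(pd.DataFrame(rows))


def generate_forecast_grid(
    scenario: SyntheticScenario,
    dates,
    grid_resolution: float = 0.4,
    path=None,
    daily_anomaly: float = 0.0,
    steps_per_day: int = 8,
    units: str = "K",
    noise_sd: float = 0.0,
    diurnal_amplitude: float = 3.0,
    meridional_gradient: float = 0.5,
    bounds: tuple[float, float, float, float] | None = None,
):
    """Write a CF-style NetCDF gridded sub-daily temperature forecast.

    The field follows the scenario's seasonal cycle plus ``daily_anomaly``
    (e.g. a heatwave excursion), a gentle meridional gradient, a diurnal
    cycle, and optional Gaussian noise.  ``bounds`` (lon_min, lon_max,
    lat_min, lat_max) defaults to the scenario's centroid box padded by one
    grid step; an explicit box that fails to cover the centroid range is a
    coverage error.

    Returns the ``xarray.Dataset``; writes NetCDF3 to ``path`` if given.
    """
    import xarray as xr

    dates = pd.DatetimeIndex(dates)
    if bounds is None:
        pad = grid_resolution
        bounds = (
            scenario.lon_range[0] - pad,
            scenario.lon_range[1] + pad,
            scenario.lat_range[0] - pad,
            scenario.lat_range[1] + pad,
        )
    lon_min, lon_max, lat_min, lat_max = bounds
    if lon_min > scenario.lon_range[0] or lon_max < scenario.lon_range[1] or (
        lat_min > scenario.lat_range[0] or lat_max < scenario.lat_range[1]
    ):
        raise ValueError("forecast grid bounds do not cover the area centroids")
    lons = np.arange(lon_min, lon_max + grid_resolution / 2.0, grid_resolution)
    lats = np.arange(lat_min, lat_max + grid_resolution / 2.0, grid_resolution)
    step_h = 24.0 / steps_per_day
    times = np.concatenate(
        [
            d.to_datetime64() + (np.arange(steps_per_day) * step_h * 3600 * 1e9).astype("timedelta64[ns]")
            for d in dates
        ]
    )
    doy = pd.DatetimeIndex(times).dayofyear.to_numpy(dtype=float)
    hod = pd.DatetimeIndex(times).hour.to_numpy(dtype=float)
    season = np.sin(2.0 * np.pi * (doy - 196.0 + 365.25 / 4.0) / 365.25)
    base = scenario.temp_mean + scenario.temp_amplitude * season + daily_anomaly
    diurnal = diurnal_amplitude * np.sin(2.0 * np.pi * (hod - 9.0) / 24.0)
    # meridional gradient: cooler to the north
    grad = -meridional_gradient * (lats - lats.mean())
    field = (
        base[:, None, None]
        + diurnal[:, None, None]
        + grad[None, :, None]
        + np.zeros((1, 1, len(lons)))
    )
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 43]))
        field = field + rng.normal(0.0, noise_sd, size=field.shape)
    if units == "K":
        data = field + 273.15
    elif units in ("degC", "C"):
        data = field
    else:
        raise ValueError(f"unsupported units {units!r}")
    ds = xr.Dataset(
        {
            "t2m": (
                ("time", "lat", "lon"),
                data,
                {"units": units, "long_name": "2 metre temperature"},
            )
        },
        coords={
            "time": ("time", times),
            "lat": ("lat", lats, {"units": "degrees_north"}),
            "lon": ("lon", lons, {"units": "degrees_east"}),
        },
        attrs={
            "Conventions": "CF-1.8",
            "issue_time": str((dates[0] - pd.Timedelta(days=6)).date()),
        },
    )
    if path is not None:
        ds.to_netcdf(path, engine="scipy")
    return ds
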