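"""Expected excess deaths from forecast temperatures and risk functions.

For each day ``t``, age group ``a`` and area ``j`` the expected excess
deaths are

    d_taj = (p_aj * m_aj / 365.25) * (1 - exp(-beta_taj))

where ``p_aj`` and ``m_aj`` are the group's population and baseline annual
mortality rate (so ``b_aj = p_aj * m_aj / 365.25`` is the constant daily
baseline) and ``beta_taj`` is the cumulative log relative risk of the
forecast temperature on day ``t``, evaluated on the area/age-specific
exposure–response curve referenced at its minimum mortality temperature.
``1 - exp(-beta)`` is the attributable fraction (RR-1)/RR with
``RR = exp(beta)``.  Attribution follows the forward perspective: all lagged
risk from the exposure on day ``t`` is booked to day ``t``.

Uncertainty is propagated by Monte Carlo: coefficient vectors are drawn from
the multivariate normal sampling distribution of each risk function, the
excess is recomputed per draw, and empirical confidence intervals (eCIs) of
any aggregate are quantiles of the per-draw aggregate sums (draws are
matched across the cells of an aggregate, so within-area correlation is
preserved; areas are sampled independently).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forecast import AreaTable
from .risk import RiskFunction, RiskStore

__all__ = [
    "ExcessTable",
    "cumulative_logrr_at",
    "expected_excess",
    "forecast_impacts",
    "monte_carlo_eci",
    "aggregate",
]


def cumulative_logrr_at(risk: RiskFunction, tmean) -> np.ndarray | float:
    """beta_taj: cumulative log-RR at forecast temperature, zero at the MMT."""
    out = risk.logrr_at(tmean)
    return float(out[0]) if np.isscalar(tmean) else out


def expected_excess(b_aj, beta_taj):
    """d_taj = b * (1 - exp(-beta)) = b * (RR - 1)/RR, signed.

    Negative beta (protective side of the curve) yields a negative excess;
    the magnitude is always strictly below the baseline for finite beta.
    """
    b = np.asarray(b_aj, dtype=float)
    beta = np.asarray(beta_taj, dtype=float)
    if np.any(b < 0):
        raise ValueError("baseline daily deaths must be non-negative")
    if np.any(~np.isfinite(beta)):
        bad = np.nonzero(~np.isfinite(beta))[0][:5]
        raise ValueError(f"non-finite log relative risk at positions {bad.tolist()}")
    out = b * (1.0 - np.exp(-beta))
    return float(out) if out.ndim == 0 else out


@dataclass
class ExcessTable:
    """Per-cell expected excess deaths with optional simulation draws.

    ``cells`` has one row per (area, age group, date); ``sims`` (if set) is
    an (n_cells, n_sim) array of per-draw excess deaths aligned with the
    rows of ``cells``, from which eCIs of any aggregate are derived.
    """

    cells: pd.DataFrame
    sims: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def total(self) -> float:
        return float(self.cells["excess"].sum())


_MODES = ("heat", "cold", "net")


def _mode_mask(cells: pd.DataFrame, mode: str) -> np.ndarray:
    """Cells kept (not zeroed) under an attribution mode."""
    if mode == "net":
        return np.ones(len(cells), dtype=bool)
    side = cells["attribution_side"].to_numpy()
    return side == mode


def forecast_impacts(
    series: pd.DataFrame,
    store: RiskStore,
    areas: AreaTable,
    mode: str = "heat",
    clamp: bool = True,
) -> ExcessTable:
    """Point-estimate excess deaths per (area, age group, forecast day).

    ``series`` is the per-area daily forecast frame (area_id, date, tmean
    [, lead_days]).  Forecast temperatures outside a risk function's
    calibration range are clamped to the boundary (flagged per cell).
    ``mode`` keeps heat cells (tmean > MMT), cold cells (tmean < MMT) or the
    signed net; zeroed cells remain in the table with excess 0.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    region_of = dict(
        zip(areas.centroids["area_id"], areas.centroids["region"])
    )
    missing = []
    for aid in series["area_id"].unique():
        for g in areas.df.loc[areas.df["area_id"] == aid, "age_group"].unique():
            try:
                store.get(aid, g, region=region_of.get(aid))
            except KeyError:
                missing.append((aid, g))
    if missing:
        raise KeyError(
            f"missing risk functions (no fallback) for: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    baselines = areas.baseline_daily_deaths()
    rows = []
    for (aid, g), b in baselines.items():
        sub = series.loc[series["area_id"] == aid]
        if sub.empty:
            continue
        rf, used_fallback = store.get(aid, g, region=region_of.get(aid))
        t = sub["tmean"].to_numpy(dtype=float)
        lo, hi = rf.temp_range
        t_clamped = np.clip(t, lo, hi) if clamp else t
        clamped = t_clamped != t
        beta = rf.logrr_at(t_clamped)
        side = np.where(
            t_clamped > rf.mmt, "heat", np.where(t_clamped < rf.mmt, "cold", "none")
        )
        d = expected_excess(b, beta)
        for i in range(len(sub)):
            rows.append(
                {
                    "area_id": aid,
                    "region": region_of.get(aid),
                    "age_group": g,
                    "date": pd.Timestamp(sub["date"].iloc[i]),
                    "tmean": float(t_clamped[i]),
                    "logrr": float(beta[i]),
                    "baseline": float(b),
                    "excess": float(d[i]),
                    "attribution_side": str(side[i]),
                    "clamped": bool(clamped[i]),
                    "fallback_used": bool(used_fallback),
                }
            )
    cells = pd.DataFrame(rows)
    if len(cells):
        keep = _mode_mask(cells, mode)
        cells.loc[~keep, "excess"] = 0.0
        n_clamped = int(cells["clamped"].sum())
        if n_clamped:
            warnings.warn(
                f"{n_clamped} forecast temperatures clamped to calibration range"
            )
    return ExcessTable(cells=cells, meta={"mode": mode, "clamp": clamp})


def _sym_sqrt(vcov: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Symmetric matrix square root via eigendecomposition.

    Eigenvalues within -tol*max of zero are clipped to zero; anything more
    negative is a numerical error, not repairable noise.
    """
    v = (np.asarray(vcov, dtype=float) + np.asarray(vcov, dtype=float).T) / 2.0
    w, q = np.linalg.eigh(v)
    floor = -tol * max(1.0, float(w.max(initial=0.0)))
    if w.min(initial=0.0) < floor:
        raise ValueError(
            f"vcov not PSD beyond tolerance (min eigenvalue {w.min():.3e})"
        )
    return q @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ q.T


def monte_carlo_eci(
    table: ExcessTable,
    store: RiskStore,
    n_sim: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> ExcessTable:
    """Attach Monte Carlo simulation draws and per-cell eCIs to a table.

    For each (area, age group), ``n_sim`` coefficient vectors are drawn from
    N(coef, vcov) via the symmetric matrix square root; beta and the excess
    are recomputed per cell per draw (with the same clamped temperatures and
    mode zeroing as the point estimate).  eCI bounds are empirical quantiles
    (linear interpolation) of the draws; for aggregates, of the per-draw
    sums over the aggregate's cells.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    if not 0.5 < level < 1.0:
        raise ValueError("level must lie in (0.5, 1)")
    cells = table.cells.reset_index(drop=True)
    mode = table.meta.get("mode", "net")
    keep = _mode_mask(cells, mode)
    sims = np.zeros((len(cells), n_sim))
    groups = sorted(
        cells.groupby(["area_id", "age_group"], sort=True).groups.items()
    )
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(groups))
    region_of = dict(zip(cells["area_id"], cells["region"]))
    for ((aid, g), idx), ss in zip(groups, children):
        idx = np.asarray(idx)
        rf, _ = store.get(aid, g, region=region_of.get(aid))
        A = _sym_sqrt(rf.vcov)
        rng = np.random.default_rng(ss)
        z = rng.standard_normal((n_sim, len(rf.coef)))
        draws = rf.coef[None, :] + z @ A.T  # (n_sim, k)
        B = rf._basis_rel_mmt(cells.loc[idx, "tmean"].to_numpy())  # (m, k)
        beta_sims = B @ draws.T  # (m, n_sim)
        b = cells.loc[idx, "baseline"].to_numpy()[:, None]
        sims[idx] = b * (1.0 - np.exp(-beta_sims))
    sims[~keep] = 0.0
    alpha = 1.0 - level
    lo = np.quantile(sims, alpha / 2.0, axis=1)
    hi = np.quantile(sims, 1.0 - alpha / 2.0, axis=1)
    out_cells = cells.copy()
    out_cells["eci_lo"] = lo
    out_cells["eci_hi"] = hi
    meta = dict(table.meta)
    meta.update({"n_sim": n_sim, "seed": seed, "level": level})
    return ExcessTable(cells=out_cells, sims=sims, meta=meta)


def aggregate(
    table: ExcessTable,
    by: list[str] | tuple[str, ...] = (),
    areas: AreaTable | None = None,
) -> pd.DataFrame:
    """Aggregate excess deaths by any subset of {region, age_group, date}.

    Sums point estimates over the group; the excess rate per million uses
    the group's population (each distinct (area, age group) counted once,
    however many dates the group spans).  When simulation draws are present
    the group's eCI is re-derived from the per-draw sums over its cells.
    """
    by = list(by)
    allowed = {"region", "age_group", "date"}
    if not set(by) <= allowed:
        raise ValueError(f"grouping keys must be a subset of {sorted(allowed)}")
    cells = table.cells.reset_index(drop=True)
    if not len(cells):
        return pd.DataFrame(columns=by + ["excess", "population", "rate_per_million"])
    if areas is not None:
        pop = areas.df.set_index(["area_id", "age_group"])["population"]
        cells = cells.assign(
            _pop=pop.reindex(
                pd.MultiIndex.from_frame(cells[["area_id", "age_group"]])
            ).to_numpy()
        )
    else:
        # baseline = p*m/365.25 does not recover p alone: require the table
        raise ValueError("an AreaTable is required to compute population rates")
    rows = []
    level = table.meta.get("level", 0.95)
    alpha = 1.0 - level
    if by:
        iterator = ((k, idx) for k, idx in cells.groupby(by, sort=True).groups.items())
    else:
        iterator = [((), cells.index)]
    for key, idx in iterator:
        idx = np.asarray(idx)
        sub = cells.loc[idx]
        if sub.empty:
            warnings.warn(f"empty aggregation group {key}; omitted")
            continue
        pop = float(
            sub.drop_duplicates(["area_id", "age_group"])["_pop"].sum()
        )
        excess = float(sub["excess"].sum())
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row["excess"] = excess
        row["population"] = pop
        row["rate_per_million"] = 1e6 * excess / pop if pop > 0 else np.nan
        if table.sims is not None:
            agg_sims = table.sims[idx].sum(axis=0)
            row["eci_lo"] = float(np.quantile(agg_sims, alpha / 2.0))
            row["eci_hi"] = float(np.quantile(agg_sims, 1.0 - alpha / 2.0))
            row["rate_eci_lo"] = 1e6 * row["eci_lo"] / pop if pop > 0 else np.nan
            row["rate_eci_hi"] = 1e6 * row["eci_hi"] / pop if pop > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
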