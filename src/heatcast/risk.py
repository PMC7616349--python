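"""Area/age-specific temperature–mortality risk functions.

The fitting engine is a quasi-Poisson time-series regression of daily death
counts on the DLNM cross-basis (plus optional confounder columns), exposed
as a scikit-learn style estimator.  Fitted models reduce to a cumulative
exposure–response curve referenced at the minimum mortality temperature and
are stored, per (area, age group), in a :class:`RiskStore` that the impact
engine consumes.  Overdispersion is estimated from Pearson residuals and
inflates the coefficient variance–covariance matrix (never deflates: the
dispersion has a floor of 1).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .crossbasis import (
    CrossBasisSpec,
    CumulativeCurve,
    _check_psd,
    build_crossbasis,
    find_mmt,
    reduce_to_cumulative,
)

__all__ = [
    "RiskFunction",
    "RiskStore",
    "DLNMRiskModel",
    "fit_dlnm",
    "linear_trend",
    "save_risk_store",
    "load_risk_store",
    "ConvergenceError",
    "RankError",
]

MIN_EVENTS_STABLE = 10


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the last deviance reached."""

    def __init__(self, message: str, deviance: float):
        super().__init__(message)
        self.deviance = deviance


class RankError(np.linalg.LinAlgError):
    """Design matrix is rank deficient (collinear columns)."""


@dataclass
class RiskFunction:
    """Reduced cumulative risk curve for one (area, age group).

    ``coef``/``vcov`` parametrise the overall cumulative log-RR in the
    exposure basis of ``spec``; ``mmt`` is the reference temperature at
    which the curve (and its uncertainty) is zero; ``temp_range`` the
    calibration support beyond which evaluation should be clamped.
    """

    area_id: str
    age_group: str
    coef: np.ndarray
    vcov: np.ndarray
    mmt: float
    spec: CrossBasisSpec
    temp_range: tuple[float, float]
    stable: bool = True

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float).ravel()
        self.vcov = np.asarray(self.vcov, dtype=float)
        if self.coef.shape[0] != self.spec.n_var:
            raise ValueError(
                f"coef length {self.coef.shape[0]} does not match reduced "
                f"dimension {self.spec.n_var}"
            )
        _check_psd(self.vcov)
        lo, hi = self.temp_range
        if not lo <= self.mmt <= hi:
            raise ValueError(f"MMT {self.mmt} outside calibration range {self.temp_range}")

    def _basis_rel_mmt(self, temps) -> np.ndarray:
        temps = np.atleast_1d(np.asarray(temps, dtype=float))
        return self.spec.var_basis(temps) - self.spec.var_basis(np.array([self.mmt]))

    def logrr_at(self, temps) -> np.ndarray:
        """Cumulative log relative risk at ``temps``, zero at the MMT."""
        return self._basis_rel_mmt(temps) @ self.coef

    def curve(self, temp_grid=None) -> CumulativeCurve:
        if temp_grid is None:
            temp_grid = np.linspace(*self.temp_range, 101)
        c = CumulativeCurve(
            temp_grid=np.asarray(temp_grid, dtype=float),
            logrr=np.zeros(0),
            se=np.zeros(0),
            reference=self.mmt,
            reduced_coef=self.coef,
            reduced_vcov=self.vcov,
            spec=self.spec,
        )
        c.logrr = c.predict(c.temp_grid)
        c.se = c.predict_se(c.temp_grid)
        return c

    def to_record(self) -> dict:
        return {
            "area_id": self.area_id,
            "age_group": self.age_group,
            "coef": self.coef.tolist(),
            "vcov": self.vcov.ravel().tolist(),  # row-major
            "mmt": self.mmt,
            "spec": self.spec.to_dict(),
            "temp_range": list(self.temp_range),
            "stable": self.stable,
        }

    @classmethod
    def from_record(cls, d: dict) -> "RiskFunction":
        k = len(d["coef"])
        return cls(
            area_id=str(d["area_id"]),
            age_group=str(d["age_group"]),
            coef=np.asarray(d["coef"], dtype=float),
            vcov=np.asarray(d["vcov"], dtype=float).reshape(k, k),
            mmt=float(d["mmt"]),
            spec=CrossBasisSpec.from_dict(d["spec"]),
            temp_range=tuple(d["temp_range"]),
            stable=bool(d.get("stable", True)),
        )


class RiskStore:
    """Collection of risk functions keyed by (area_id, age_group).

    Region-level pooled functions can be registered as fallbacks for areas
    without a stable fit of their own; lookups report whether the fallback
    was used so downstream outputs can flag it.
    """

    def __init__(self):
        self._functions: dict[tuple[str, str], RiskFunction] = {}
        self._fallbacks: dict[tuple[str, str], RiskFunction] = {}

    def add(self, rf: RiskFunction) -> None:
        key = (rf.area_id, rf.age_group)
        if key in self._functions:
            raise ValueError(f"duplicate risk function for {key}")
        self._functions[key] = rf

    def add_fallback(self, region: str, rf: RiskFunction) -> None:
        self._fallbacks[(region, rf.age_group)] = rf

    def get(
        self, area_id: str, age_group: str, region: str | None = None
    ) -> tuple[RiskFunction, bool]:
        """Risk function for (area, age); returns (function, used_fallback)."""
        rf = self._functions.get((area_id, age_group))
        if rf is not None:
            return rf, False
        if region is not None:
            fb = self._fallbacks.get((region, age_group))
            if fb is not None:
                return fb, True
        raise KeyError(
            f"no risk function for area {area_id!r}, age group {age_group!r}"
            + ("" if region is None else f" (region {region!r} has no fallback)")
        )

    def __len__(self) -> int:
        return len(self._functions)

    def __contains__(self, key) -> bool:
        return tuple(key) in self._functions

    def keys(self):
        return self._functions.keys()

    def values(self):
        return self._functions.values()

    def items(self):
        return self._functions.items()

    def __eq__(self, other) -> bool:
        if not isinstance(other, RiskStore):
            return NotImplemented
        if self._functions.keys() != other._functions.keys():
            return False
        if self._fallbacks.keys() != other._fallbacks.keys():
            return False
        for k, a in self._functions.items():
            b = other._functions[k]
            if a.to_record() != b.to_record():
                return False
        for k, a in self._fallbacks.items():
            if a.to_record() != other._fallbacks[k].to_record():
                return False
        return True


def linear_trend(n: int) -> np.ndarray:
    """Long-term linear trend column, scaled to [0, 1] over the series."""
    if n < 2:
        return np.zeros((n, 1))
    return (np.arange(n, dtype=float) / (n - 1))[:, None]


class DLNMRiskModel(BaseEstimator):
    """Quasi-Poisson DLNM of daily deaths on lagged non-linear temperature.

    scikit-learn style estimator: ``fit(temps, deaths)`` regresses daily
    death counts on an intercept plus the temperature cross-basis (plus any
    supplied confounder columns) with a log link, estimates overdispersion
    from the Pearson chi-square, reduces the fit to the overall cumulative
    exposure–response curve and locates the minimum mortality temperature.

    Parameters
    ----------
    spec : optional explicit :class:`CrossBasisSpec`; if None, one is built
        from the calibration temperatures (natural cubic exposure spline
        with interior knots at the ``var_percentiles`` of the series,
        lag spline with ``n_lag_knots`` knots on the log-lag scale).
    max_lag : lag window in days (default 21).
    var_percentiles : exposure knot placement percentiles.
    n_lag_knots : interior knots of the lag spline.
    var_basis_type : "ns" or "linear_threshold".
    mmt_search : percentile window of the MMT search (default (1, 99)).
    max_iter, tol : IRLS iteration cap and relative deviance tolerance.

    Attributes (after fit)
    ----------------------
    spec_ : the cross-basis specification used.
    coef_, vcov_ : full cross-basis coefficients and (dispersion-inflated)
        variance–covariance.
    intercept_ : fitted log baseline.
    dispersion_ : Pearson dispersion, floored at 1.
    curve_ : reduced :class:`CumulativeCurve` centred at the MMT.
    mmt_ : minimum mortality temperature (degC).
    temp_range_ : calibration temperature support.
    stable_ : False when the series has fewer than 10 events.
    """

    def __init__(
        self,
        spec: CrossBasisSpec | None = None,
        max_lag: int = 21,
        var_percentiles: tuple[float, ...] = (10.0, 75.0, 90.0),
        n_lag_knots: int = 3,
        var_basis_type: str = "ns",
        mmt_search: tuple[float, float] = (1.0, 99.0),
        max_iter: int = 50,
        tol: float = 1e-8,
    ):
        self.spec = spec
        self.max_lag = max_lag
        self.var_percentiles = var_percentiles
        self.n_lag_knots = n_lag_knots
        self.var_basis_type = var_basis_type
        self.mmt_search = mmt_search
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, temps, deaths, confounders=None):
        temps = np.asarray(temps, dtype=float).ravel()
        deaths = np.asarray(deaths, dtype=float).ravel()
        if temps.shape[0] != deaths.shape[0]:
            raise ValueError("temps and deaths must be aligned series of equal length")
        if np.any(deaths < 0) or np.any(~np.isfinite(deaths)):
            raise ValueError("deaths must be finite non-negative counts")
        spec = self.spec or CrossBasisSpec.from_temperatures(
            temps,
            max_lag=self.max_lag,
            var_percentiles=self.var_percentiles,
            n_lag_knots=self.n_lag_knots,
            var_basis_type=self.var_basis_type,
        )
        cb, complete = build_crossbasis(temps, spec)
        y = deaths[complete]
        X = np.column_stack([np.ones(complete.sum()), cb[complete]])
        if confounders is not None:
            conf = np.asarray(confounders, dtype=float)
            if conf.ndim == 1:
                conf = conf[:, None]
            X = np.column_stack([X, conf[complete]])
        self.n_events_ = float(y.sum())
        self.stable_ = self.n_events_ >= MIN_EVENTS_STABLE
        if not self.stable_:
            warnings.warn(
                f"only {self.n_events_:.0f} events in the series; fit flagged unstable"
            )
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise RankError(
                f"design matrix rank-deficient ({X.shape[1]} columns)"
            )
        model = sm.GLM(y, X, family=sm.families.Poisson())
        res = model.fit(maxiter=self.max_iter, tol=self.tol)
        if not getattr(res, "converged", True):
            raise ConvergenceError(
                f"IRLS did not converge in {self.max_iter} iterations",
                deviance=float(res.deviance),
            )
        df_resid = max(1.0, float(res.df_resid))
        pearson = float(res.pearson_chi2) / df_resid
        self.dispersion_ = max(1.0, pearson)
        full_vcov = self.dispersion_ * np.asarray(res.cov_params())
        params = np.asarray(res.params)
        ncb = spec.n_coef
        self.intercept_ = float(params[0])
        self.coef_ = params[1 : 1 + ncb]
        self.vcov_ = full_vcov[1 : 1 + ncb, 1 : 1 + ncb]
        self.deviance_ = float(res.deviance)
        self.spec_ = spec
        self.temp_range_ = (float(temps.min()), float(temps.max()))
        grid = np.arange(self.temp_range_[0], self.temp_range_[1] + 0.05, 0.1)
        curve = reduce_to_cumulative(
            self.coef_, self.vcov_, spec, grid, reference=float(np.median(temps))
        )
        self.mmt_, self.curve_ = find_mmt(
            curve, temps, self.mmt_search[0], self.mmt_search[1]
        )
        self._calibration_temps_ = temps
        return self

    def predict(self, temps) -> np.ndarray:
        """Cumulative log relative risk at ``temps`` relative to the MMT."""
        if not hasattr(self, "curve_"):
            raise RuntimeError("model is not fitted")
        return self.curve_.predict(temps)

    def to_risk_function(self, area_id: str, age_group: str) -> RiskFunction:
        if not hasattr(self, "curve_"):
            raise RuntimeError("model is not fitted")
        return RiskFunction(
            area_id=area_id,
            age_group=age_group,
            coef=self.curve_.reduced_coef,
            vcov=self.curve_.reduced_vcov,
            mmt=self.mmt_,
            spec=self.spec_,
            temp_range=self.temp_range_,
            stable=self.stable_,
        )


def fit_dlnm(
    deaths,
    temps,
    spec: CrossBasisSpec | None = None,
    confounders=None,
    area_id: str = "area",
    age_group: str = "all",
    **kwargs,
) -> RiskFunction:
    """Fit one series and return its :class:`RiskFunction` (thin wrapper)."""
    model = DLNMRiskModel(spec=spec, **kwargs)
    model.fit(temps, deaths, confounders=confounders)
    return model.to_risk_function(area_id, age_group)


def save_risk_store(store: RiskStore, path) -> None:
    """Serialise a store to JSON lines (one record per line, lossless)."""
    with open(path, "w") as fh:
        for _, rf in sorted(store.items()):
            rec = rf.to_record()
            rec["kind"] = "risk"
            fh.write(json.dumps(rec) + "\n")
        for (region, _), rf in sorted(store._fallbacks.items()):
            rec = rf.to_record()
            rec["kind"] = "fallback"
            rec["region"] = region
            fh.write(json.dumps(rec) + "\n")


def load_risk_store(path) -> RiskStore:
    """Load and validate a JSON-lines store; invariants checked per record."""
    store = RiskStore()
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            try:
                rf = RiskFunction.from_record(d)
            except ValueError as e:
                raise ValueError(f"corrupt risk store at line {i + 1}: {e}") from e
            if d.get("kind") == "fallback":
                store.add_fallback(str(d["region"]), rf)
            else:
                store.add(rf)
    return store
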