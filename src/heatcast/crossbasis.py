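"""Bidimensional exposure–lag basis for distributed lag non-linear models.

A DLNM represents the temperature–mortality association with a *cross-basis*:
the tensor product of a basis in the exposure dimension (temperature) and a
basis in the lag dimension (days since exposure), summed over the lag window
for each observation day.  Fitted cross-basis coefficients are reduced to an
overall *cumulative* exposure–response curve — the log relative risk of a
sustained exposure at temperature ``x`` relative to a reference temperature —
whose minimum over the observed temperature range defines the minimum
mortality temperature (MMT), the natural reference for attribution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CrossBasisSpec",
    "CumulativeCurve",
    "natural_cubic_basis",
    "linear_threshold_basis",
    "build_crossbasis",
    "reduce_to_cumulative",
    "find_mmt",
    "DegenerateCurveWarning",
]


class DegenerateCurveWarning(UserWarning):
    """Raised when an MMT is requested for an (almost) flat risk curve."""


def natural_cubic_basis(
    x: np.ndarray,
    knots: np.ndarray,
    boundary: tuple[float, float],
    intercept: bool = False,
) -> np.ndarray:
    """Natural cubic spline basis, linear beyond the boundary knots.

    Uses the closed-form truncated-power construction: with knots
    ``xi_1 < ... < xi_M`` (boundary knots included),

        d_k(x) = [ (x - xi_k)_+^3 - (x - xi_M)_+^3 ] / (xi_M - xi_k)

    and basis functions ``1, x, d_1 - d_{M-1}, ..., d_{M-2} - d_{M-1}``.
    Without intercept the constant column is dropped, giving ``K + 1``
    functions for ``K`` interior knots — the same span as R's ``ns()``
    (the coefficients differ by the linear reparametrisation, the fitted
    curve does not).
    """
    x = np.asarray(x, dtype=float)
    lo, hi = float(boundary[0]), float(boundary[1])
    if not lo < hi:
        raise ValueError(f"boundary knots must satisfy lo < hi, got ({lo}, {hi})")
    xi = np.concatenate([[lo], np.asarray(knots, dtype=float), [hi]])
    if np.any(np.diff(xi) <= 0):
        raise ValueError("knots must be strictly increasing and inside the boundary")
    m = len(xi)
    if m == 2:
        # no interior knots: natural spline degenerates to a straight line
        cols = [x]
    else:
        def d(k: int) -> np.ndarray:
            return (
                np.clip(x - xi[k], 0.0, None) ** 3
                - np.clip(x - xi[m - 1], 0.0, None) ** 3
            ) / (xi[m - 1] - xi[k])

        d_last = d(m - 2)
        cols = [x] + [d(k) - d_last for k in range(m - 2)]
    if intercept:
        cols = [np.ones_like(x)] + cols
    return np.column_stack(cols)


def linear_threshold_basis(
    x: np.ndarray, knots: np.ndarray, boundary=None, intercept: bool = False
) -> np.ndarray:
    """Piecewise-linear (hockey-stick) exposure basis.

    No knots gives the plain linear column.  With knots ``k_1 < ... < k_K``
    the columns are the descending arm below the first knot, ``(k_1 - x)_+``,
    and one ascending arm ``(x - k_i)_+`` per knot — a V at a single knot.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if knots.size == 0:
        cols = [x]
    else:
        if np.any(np.diff(knots) <= 0):
            raise ValueError("threshold knots must be strictly increasing")
        cols = [np.clip(knots[0] - x, 0.0, None)]
        cols += [np.clip(x - k, 0.0, None) for k in knots]
    if intercept:
        cols = [np.ones_like(x)] + cols
    return np.column_stack(cols)


def default_lag_knots(max_lag: int, n_knots: int = 3) -> np.ndarray:
    """Interior lag knots equally spaced on the log(1 + lag) scale."""
    if max_lag < 2 or n_knots < 1:
        return np.array([])
    pts = np.linspace(np.log1p(0), np.log1p(max_lag), n_knots + 2)[1:-1]
    return np.expm1(pts)


@dataclass(frozen=True)
class CrossBasisSpec:
    """Specification of the exposure and lag bases of a cross-basis.

    Parameters
    ----------
    var_knots : interior knots of the exposure spline, in degrees Celsius.
    var_boundary : boundary knots (temperatures) of the exposure spline.
    lag_knots : interior knots of the lag spline, in days.
    max_lag : lag window length in days (default 21).
    var_basis_type : ``"ns"`` (natural cubic spline, no intercept) or
        ``"linear_threshold"``.
    lag_basis_type : ``"ns_intercept"`` — natural cubic spline with
        intercept over lags 0..max_lag.
    """

    var_knots: tuple[float, ...]
    var_boundary: tuple[float, float]
    lag_knots: tuple[float, ...] = ()
    max_lag: int = 21
    var_basis_type: str = "ns"
    lag_basis_type: str = "ns_intercept"

    def __post_init__(self):
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")
        vk = np.asarray(self.var_knots, dtype=float)
        lo, hi = self.var_boundary
        if vk.size and (np.any(np.diff(vk) <= 0) or vk[0] <= lo or vk[-1] >= hi):
            raise ValueError("var_knots must be strictly increasing and strictly inside var_boundary")
        lk = np.asarray(self.lag_knots, dtype=float)
        if lk.size and (np.any(np.diff(lk) <= 0) or lk[0] < 0 or lk[-1] > self.max_lag):
            raise ValueError("lag_knots must be strictly increasing within [0, max_lag]")
        if self.var_basis_type not in ("ns", "linear_threshold"):
            raise ValueError(f"unknown var_basis_type {self.var_basis_type!r}")
        if self.lag_basis_type != "ns_intercept":
            raise ValueError(f"unknown lag_basis_type {self.lag_basis_type!r}")

    # -- basis evaluation ------------------------------------------------

    def var_basis(self, x: np.ndarray) -> np.ndarray:
        """Exposure basis matrix evaluated at temperatures ``x``."""
        if self.var_basis_type == "ns":
            return natural_cubic_basis(x, np.asarray(self.var_knots), self.var_boundary)
        return linear_threshold_basis(x, np.asarray(self.var_knots))

    def lag_basis(self) -> np.ndarray:
        """Lag basis matrix evaluated at lags 0..max_lag (with intercept)."""
        lags = np.arange(self.max_lag + 1, dtype=float)
        if self.max_lag == 0:
            return np.ones((1, 1))
        lk = np.asarray(self.lag_knots, dtype=float)
        # max_lag == 1 leaves no room for curvature: intercept + linear term
        if self.max_lag == 1:
            return np.column_stack([np.ones(2), lags])
        return natural_cubic_basis(lags, lk, (0.0, float(self.max_lag)), intercept=True)

    @property
    def n_var(self) -> int:
        return self.var_basis(np.array([0.0])).shape[1]

    @property
    def n_lag(self) -> int:
        return self.lag_basis().shape[1]

    @property
    def n_coef(self) -> int:
        """Dimension of the full cross-basis coefficient vector."""
        return self.n_var * self.n_lag

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "var_knots": list(self.var_knots),
            "var_boundary": list(self.var_boundary),
            "lag_knots": list(self.lag_knots),
            "max_lag": self.max_lag,
            "var_basis_type": self.var_basis_type,
            "lag_basis_type": self.lag_basis_type,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CrossBasisSpec":
        return cls(
            var_knots=tuple(d["var_knots"]),
            var_boundary=tuple(d["var_boundary"]),
            lag_knots=tuple(d.get("lag_knots", ())),
            max_lag=int(d.get("max_lag", 21)),
            var_basis_type=d.get("var_basis_type", "ns"),
            lag_basis_type=d.get("lag_basis_type", "ns_intercept"),
        )

    @classmethod
    def from_temperatures(
        cls,
        temps: np.ndarray,
        max_lag: int = 21,
        var_percentiles: tuple[float, ...] = (10.0, 75.0, 90.0),
        n_lag_knots: int = 3,
        var_basis_type: str = "ns",
    ) -> "CrossBasisSpec":
        """Data-driven spec: exposure knots at percentiles of the series."""
        temps = np.asarray(temps, dtype=float)
        knots = tuple(np.percentile(temps, var_percentiles))
        boundary = (float(temps.min()), float(temps.max()))
        if var_basis_type == "linear_threshold":
            knots = (float(np.percentile(temps, 50.0)),)
            return cls(knots, boundary, (), max_lag, var_basis_type)
        return cls(
            knots,
            boundary,
            tuple(default_lag_knots(max_lag, n_lag_knots)),
            max_lag,
            var_basis_type,
        )


def build_crossbasis(
    temps: np.ndarray, spec: CrossBasisSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-basis design matrix for a daily temperature series.

    Row ``t`` holds, for each exposure-basis function ``v_j`` and lag-basis
    function ``w_k``, the lag-summed product

        CB[t, (j, k)] = sum_{l=0}^{L} v_j(x_{t-l}) * w_k(l).

    Returns ``(matrix, complete)`` where ``complete`` flags rows with a full
    lag history; the first ``max_lag`` rows are NaN and flagged False.
    Column order is exposure-major: ``(j, k)`` flattens with ``k`` fastest.
    """
    temps = np.asarray(temps, dtype=float)
    n = temps.shape[0]
    L = spec.max_lag
    if n <= L:
        raise ValueError(
            f"series of length {n} is too short for max_lag={L}; "
            "need at least max_lag + 1 days"
        )
    V = spec.var_basis(temps)  # (n, kv)
    W = spec.lag_basis()  # (L+1, kl)
    kv, kl = V.shape[1], W.shape[1]
    cb = np.zeros((n, kv, kl))
    for l in range(L + 1):
        # exposure l days before day t contributes through lag-basis row l
        cb[l:, :, :] += V[: n - l, :, None] * W[l, None, :]
    cb = cb.reshape(n, kv * kl)
    complete = np.ones(n, dtype=bool)
    complete[:L] = False
    cb[~complete] = np.nan
    if complete.sum() < kv * kl:
        raise ValueError(
            f"only {int(complete.sum())} complete-history rows for "
            f"{kv * kl} cross-basis columns: design is rank deficient"
        )
    return cb, complete


@dataclass
class CumulativeCurve:
    """Overall cumulative exposure–response curve with sampling uncertainty.

    ``logrr[i]`` is the cumulative log relative risk of sustained exposure at
    ``temp_grid[i]`` relative to ``reference``; ``se`` the pointwise standard
    error.  ``reduced_coef``/``reduced_vcov`` parametrise the curve in the
    (uncentred) exposure basis of ``spec``.
    """

    temp_grid: np.ndarray
    logrr: np.ndarray
    se: np.ndarray
    reference: float
    reduced_coef: np.ndarray
    reduced_vcov: np.ndarray
    spec: CrossBasisSpec

    def predict(self, temps) -> np.ndarray:
        """Cumulative log-RR at arbitrary temperatures, centred at reference."""
        temps = np.atleast_1d(np.asarray(temps, dtype=float))
        B = self.spec.var_basis(temps) - self.spec.var_basis(
            np.array([self.reference])
        )
        return B @ self.reduced_coef

    def predict_se(self, temps) -> np.ndarray:
        temps = np.atleast_1d(np.asarray(temps, dtype=float))
        B = self.spec.var_basis(temps) - self.spec.var_basis(
            np.array([self.reference])
        )
        var = np.einsum("ij,jk,ik->i", B, self.reduced_vcov, B)
        return np.sqrt(np.clip(var, 0.0, None))

    def recentre(self, reference: float) -> "CumulativeCurve":
        """Same curve expressed relative to a new reference temperature."""
        new = replace(self, reference=float(reference))
        new.logrr = new.predict(self.temp_grid)
        new.se = new.predict_se(self.temp_grid)
        return new

    def to_json(self) -> str:
        return json.dumps(
            {
                "spec": self.spec.to_dict(),
                "reference": self.reference,
                "reduced_coef": self.reduced_coef.tolist(),
                "reduced_vcov": self.reduced_vcov.tolist(),
                "temp_grid": self.temp_grid.tolist(),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "CumulativeCurve":
        d = json.loads(s)
        spec = CrossBasisSpec.from_dict(d["spec"])
        grid = np.asarray(d["temp_grid"], dtype=float)
        coef = np.asarray(d["reduced_coef"], dtype=float)
        vcov = np.asarray(d["reduced_vcov"], dtype=float)
        curve = cls(
            temp_grid=grid,
            logrr=np.zeros_like(grid),
            se=np.zeros_like(grid),
            reference=float(d["reference"]),
            reduced_coef=coef,
            reduced_vcov=vcov,
            spec=spec,
        )
        curve.logrr = curve.predict(grid)
        curve.se = curve.predict_se(grid)
        return curve


def _check_psd(vcov: np.ndarray, tol: float = 1e-8) -> None:
    vcov = np.asarray(vcov, dtype=float)
    if vcov.ndim != 2 or vcov.shape[0] != vcov.shape[1]:
        raise ValueError("vcov must be a square matrix")
    if not np.allclose(vcov, vcov.T, atol=tol * max(1.0, np.abs(vcov).max())):
        raise ValueError("vcov is not symmetric within tolerance")
    eig = np.linalg.eigvalsh((vcov + vcov.T) / 2.0)
    floor = -tol * max(1.0, float(eig.max(initial=0.0)))
    if eig.min(initial=0.0) < floor:
        raise ValueError(
            f"vcov is not positive semi-definite (min eigenvalue {eig.min():.3e})"
        )


def reduce_to_cumulative(
    coef: np.ndarray,
    vcov: np.ndarray,
    spec: CrossBasisSpec,
    temp_grid: np.ndarray,
    reference: float,
) -> CumulativeCurve:
    """Collapse fitted cross-basis coefficients to the cumulative curve.

    The cumulative log-RR of sustained exposure at ``x`` is
    ``sum_{j,k} coef_{jk} v_j(x) s_k`` with ``s_k = sum_l w_k(l)`` the lag
    column sums, i.e. a linear map ``M = I_kv (x) s^T`` of the full
    coefficients; the reduced vcov is ``M V M^T``.
    """
    coef = np.asarray(coef, dtype=float).ravel()
    if coef.shape[0] != spec.n_coef:
        raise ValueError(
            f"coef has length {coef.shape[0]}, spec dimension is {spec.n_coef}"
        )
    _check_psd(vcov)
    W = spec.lag_basis()
    s = W.sum(axis=0)  # (kl,)
    kv = spec.n_var
    M = np.kron(np.eye(kv), s[None, :])  # (kv, kv*kl)
    theta = M @ coef
    vr = M @ np.asarray(vcov, dtype=float) @ M.T
    vr = (vr + vr.T) / 2.0
    grid = np.asarray(temp_grid, dtype=float)
    curve = CumulativeCurve(
        temp_grid=grid,
        logrr=np.zeros_like(grid),
        se=np.zeros_like(grid),
        reference=float(reference),
        reduced_coef=theta,
        reduced_vcov=vr,
        spec=spec,
    )
    curve.logrr = curve.predict(grid)
    curve.se = curve.predict_se(grid)
    return curve


def find_mmt(
    curve: CumulativeCurve,
    temps: np.ndarray,
    search_lo: float = 1.0,
    search_hi: float = 99.0,
    step: float = 0.1,
) -> tuple[float, CumulativeCurve]:
    """Minimum mortality temperature of a cumulative curve.

    Scans a 0.1 degC grid between the ``search_lo`` and ``search_hi``
    percentiles of the calibration temperatures, returns the minimising
    temperature (ties broken toward the lower temperature) and the curve
    recentred there.  A flat curve yields the window midpoint with a
    :class:`DegenerateCurveWarning`.
    """
    if not (0.0 < search_lo < search_hi < 100.0):
        raise ValueError("search percentiles must satisfy 0 < lo < hi < 100")
    temps = np.asarray(temps, dtype=float)
    lo = float(np.percentile(temps, search_lo))
    hi = float(np.percentile(temps, search_hi))
    grid = np.arange(lo, hi + step / 2.0, step)
    vals = curve.predict(grid)
    if np.ptp(vals) < 1e-12:
        warnings.warn(
            "risk curve is flat over the search window; MMT set to midpoint",
            DegenerateCurveWarning,
        )
        mmt = (lo + hi) / 2.0
    else:
        mmt = float(grid[int(np.argmin(vals))])  # argmin -> first = lowest temp
    return mmt, curve.recentre(mmt)
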