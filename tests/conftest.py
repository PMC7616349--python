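import warnings

import numpy as np
import pandas as pd
import pytest

import heatcast as hc


@pytest.fixture
def toy_spec():
    """Small cross-basis: 2 exposure knots, 2 lag knots, 5-day lag window."""
    return hc.CrossBasisSpec(
        var_knots=(12.0, 20.0),
        var_boundary=(0.0, 30.0),
        lag_knots=(1.0, 3.0),
        max_lag=5,
    )


@pytest.fixture(scope="session")
def pipeline_bundle():
    """Fitted small synthetic pipeline shared across integration tests.

    6 areas x 3 age groups, 10 years of calibration data, risk store fitted
    per (area, age), plus a 6-day summer heatwave forecast series linked to
    the areas.
    """
    scenario = hc.SyntheticScenario(n_areas=6, n_days=3650, seed=42)
    calib, truths = hc.generate_calibration_data(scenario)
    areas = hc.generate_area_table(scenario)
    store = hc.RiskStore()
    models = {}
    for (aid, g), sub in calib.groupby(["area_id", "age_group"], sort=True):
        sub = sub.sort_values("date")
        m = hc.DLNMRiskModel()
        m.fit(sub["tmean"].to_numpy(), sub["deaths"].fillna(0.0).to_numpy())
        store.add(m.to_risk_function(str(aid), str(g)))
        models[(aid, g)] = m
    # held-out heatwave: six July days the summer after calibration ends
    fc_dates = pd.date_range("2020-07-17", periods=6, freq="D")
    ds = hc.generate_forecast_grid(scenario, fc_dates, daily_anomaly=6.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        grids = hc.daily_mean(hc.read_forecast(ds))
        series = hc.link_areas(grids, areas)
    return {
        "scenario": scenario,
        "calibration": calib,
        "truths": truths,
        "areas": areas,
        "store": store,
        "models": models,
        "series": series,
    }


@pytest.fixture
def tiny_store():
    """Two-area, one-age risk store with simple linear-threshold curves."""
    spec = hc.CrossBasisSpec(
        var_knots=(18.0,), var_boundary=(0.0, 35.0), max_lag=0,
        var_basis_type="linear_threshold",
    )
    store = hc.RiskStore()
    rows = []
    for i, (aid, slope) in enumerate([("X1", 0.02), ("X2", 0.04)]):
        rf = hc.RiskFunction(
            area_id=aid,
            age_group="all",
            coef=np.array([0.01, slope]),  # cold arm, heat arm
            vcov=np.diag([1e-5, 2e-5]),
            mmt=18.0,
            spec=spec,
            temp_range=(0.0, 35.0),
        )
        store.add(rf)
        rows.append(
            {
                "area_id": aid, "region": "R0", "lon": -1.0 - i, "lat": 52.0,
                "age_group": "all", "population": 10_000, "annual_rate": 0.01,
            }
        )
    areas = hc.AreaTable(pd.DataFrame(rows))
    return store, areas
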