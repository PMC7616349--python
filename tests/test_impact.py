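"""Excess-death computation, Monte Carlo eCIs and aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import heatcast as hc


class TestExpectedExcess:
    def test_attributable_fraction_identities(self):
        assert hc.expected_excess(10.0, np.log(2.0)) == pytest.approx(5.0, rel=1e-12)
        assert hc.expected_excess(7.3, 0.0) == 0.0

    def test_baseline_from_population_and_rate(self):
        b = 1500 * 0.01 / 365.25
        assert b == pytest.approx(0.041068, abs=5e-7)
        d = hc.expected_excess(b, 0.1)
        assert d == pytest.approx(b * (1 - np.exp(-0.1)), rel=1e-12)

    def test_excess_strictly_below_baseline(self):
        rng = np.random.default_rng(0)
        beta = rng.normal(0, 2, 1000)
        d = hc.expected_excess(3.0, beta)
        assert (d < 3.0).all()

    def test_protective_side_is_signed_negative(self):
        assert hc.expected_excess(10.0, -0.5) < 0

    def test_non_finite_beta_raises(self):
        with pytest.raises(ValueError, match="non-finite"):
            hc.expected_excess(1.0, np.array([0.1, np.nan]))


class TestCumulativeLogRR:
    def test_reference_identity_and_zero_coef(self, tiny_store):
        store, _ = tiny_store
        rf, _ = store.get("X1", "all")
        assert hc.cumulative_logrr_at(rf, rf.mmt) == pytest.approx(0.0, abs=1e-12)
        rf0 = hc.RiskFunction(
            area_id="Z", age_group="all", coef=np.zeros(2),
            vcov=np.zeros((2, 2)), mmt=18.0, spec=rf.spec, temp_range=rf.temp_range,
        )
        assert hc.cumulative_logrr_at(rf0, 30.0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_explicit_basis_loop(self, tiny_store):
        store, _ = tiny_store
        rf, _ = store.get("X2", "all")
        for x in (5.0, 18.0, 25.0, 33.0):
            v = rf.spec.var_basis(np.array([x]))[0]
            vref = rf.spec.var_basis(np.array([rf.mmt]))[0]
            expect = sum(rf.coef[j] * (v[j] - vref[j]) for j in range(len(rf.coef)))
            assert hc.cumulative_logrr_at(rf, x) == pytest.approx(
                expect, rel=1e-12, abs=1e-15
            )


def _series(store_areas, temps_by_area, dates=None):
    _, areas = store_areas
    dates = dates or pd.date_range("2022-07-17", periods=len(next(iter(temps_by_area.values()))))
    rows = []
    for aid, temps in temps_by_area.items():
        for d, t in zip(dates, temps):
            rows.append({"area_id": aid, "date": d, "tmean": t, "lead_days": 0})
    return pd.DataFrame(rows)


class TestForecastImpacts:
    def test_all_days_at_mmt_zero_table(self, tiny_store):
        store, areas = tiny_store
        series = _series(tiny_store, {"X1": [18.0] * 3, "X2": [18.0] * 3})
        table = hc.forecast_impacts(series, store, areas, mode="net")
        assert table.total() == 0.0
        assert (table.cells["attribution_side"] == "none").all()

    def test_single_cell_composes_expected_excess(self, tiny_store):
        store, areas = tiny_store
        series = _series(tiny_store, {"X1": [28.0], "X2": [18.0]})
        table = hc.forecast_impacts(series, store, areas, mode="heat")
        rf, _ = store.get("X1", "all")
        b = 10_000 * 0.01 / 365.25
        expect = hc.expected_excess(b, hc.cumulative_logrr_at(rf, 28.0))
        hot = table.cells[table.cells["area_id"] == "X1"]
        assert hot["excess"].iloc[0] == pytest.approx(expect, rel=1e-12)
        assert table.total() == pytest.approx(expect, rel=1e-12)

    def test_net_equals_heat_plus_cold(self, pipeline_bundle):
        series = pipeline_bundle["series"]
        store, areas = pipeline_bundle["store"], pipeline_bundle["areas"]
        totals = {}
        for mode in ("heat", "cold", "net"):
            totals[mode] = hc.forecast_impacts(series, store, areas, mode=mode).total()
        assert totals["net"] == pytest.approx(
            totals["heat"] + totals["cold"], rel=1e-9, abs=1e-12
        )

    def test_out_of_range_temperatures_clamped_and_flagged(self, tiny_store):
        store, areas = tiny_store
        series = _series(tiny_store, {"X1": [50.0], "X2": [18.0]})
        with pytest.warns(UserWarning, match="clamped"):
            table = hc.forecast_impacts(series, store, areas, mode="heat")
        hot = table.cells[table.cells["area_id"] == "X1"]
        assert hot["clamped"].iloc[0]
        assert hot["tmean"].iloc[0] == 35.0  # calibration upper bound

    def test_missing_risk_function_lists_key(self, tiny_store):
        store, areas = tiny_store
        extra = areas.df.iloc[[0]].assign(area_id="X9")
        areas2 = hc.AreaTable(pd.concat([areas.df, extra], ignore_index=True))
        series = _series(tiny_store, {"X1": [20.0], "X2": [20.0], "X9": [20.0]})
        with pytest.raises(KeyError, match="X9"):
            hc.forecast_impacts(series, store, areas2)

    def test_heat_excess_monotone_in_temperature(self, tiny_store):
        """Above the MMT a rising forecast cannot lower the excess."""
        store, areas = tiny_store
        rf, _ = store.get("X1", "all")
        temps = np.linspace(rf.mmt, 35.0, 40)
        d = hc.expected_excess(1.0, rf.logrr_at(temps))
        assert (np.diff(d) >= -1e-15).all()


def _brute_force_eci(cells, store, n_sim, seed, level, mode):
    """Straight-line reimplementation of the Monte Carlo eCI definition."""
    groups = sorted(
        cells.groupby(["area_id", "age_group"], sort=True).groups.items()
    )
    children = np.random.SeedSequence(seed).spawn(len(groups))
    sims = np.zeros((len(cells), n_sim))
    for ((aid, g), idx), ss in zip(groups, children):
        rf, _ = store.get(aid, g)
        # symmetric square root by eigendecomposition, scalar loops below
        w, q = np.linalg.eigh((rf.vcov + rf.vcov.T) / 2.0)
        A = q @ np.diag(np.sqrt(np.clip(w, 0, None))) @ q.T
        rng = np.random.default_rng(ss)
        z = rng.standard_normal((n_sim, len(rf.coef)))
        for s in range(n_sim):
            theta = rf.coef + A @ z[s]
            for i in idx:
                x = cells.loc[i, "tmean"]
                v = rf.spec.var_basis(np.array([float(x)]))[0]
                vr = rf.spec.var_basis(np.array([rf.mmt]))[0]
                beta = float(np.dot(theta, v - vr))
                b = cells.loc[i, "baseline"]
                side = cells.loc[i, "attribution_side"]
                keep = mode == "net" or side == mode
                sims[i, s] = b * (1 - np.exp(-beta)) if keep else 0.0
    alpha = 1 - level
    return (
        np.quantile(sims, alpha / 2, axis=1),
        np.quantile(sims, 1 - alpha / 2, axis=1),
        sims,
    )


class TestMonteCarloECI:
    def test_zero_vcov_collapses_to_point_estimate(self, tiny_store):
        store, areas = tiny_store
        store0 = hc.RiskStore()
        for rf in store.values():
            store0.add(
                hc.RiskFunction(
                    area_id=rf.area_id, age_group=rf.age_group, coef=rf.coef,
                    vcov=np.zeros_like(rf.vcov), mmt=rf.mmt, spec=rf.spec,
                    temp_range=rf.temp_range,
                )
            )
        series = _series(tiny_store, {"X1": [25.0, 30.0], "X2": [12.0, 28.0]})
        table = hc.forecast_impacts(series, store0, areas, mode="net")
        out = hc.monte_carlo_eci(table, store0, n_sim=200, seed=1)
        np.testing.assert_array_equal(out.cells["eci_lo"], out.cells["excess"])
        np.testing.assert_array_equal(out.cells["eci_hi"], out.cells["excess"])

    def test_matches_brute_force_oracle_on_small_instance(self, tiny_store):
        store, areas = tiny_store
        series = _series(tiny_store, {"X1": [25.0, 30.0], "X2": [12.0]})
        table = hc.forecast_impacts(series, store, areas, mode="net")
        out = hc.monte_carlo_eci(table, store, n_sim=300, seed=7)
        lo, hi, sims = _brute_force_eci(
            out.cells.drop(columns=["eci_lo", "eci_hi"]).reset_index(drop=True),
            store, n_sim=300, seed=7, level=0.95, mode="net",
        )
        np.testing.assert_allclose(out.cells["eci_lo"], lo, rtol=1e-10)
        np.testing.assert_allclose(out.cells["eci_hi"], hi, rtol=1e-10)
        np.testing.assert_allclose(out.sims, sims, rtol=1e-10)

    def test_simulated_beta_distribution_is_normal(self, tiny_store):
        """Single cell, scalar variance: draws must pass a KS normality test."""
        spec = hc.CrossBasisSpec(
            var_knots=(), var_boundary=(0.0, 35.0), max_lag=0,
            var_basis_type="linear_threshold",
        )
        sigma2 = 4e-4
        rf = hc.RiskFunction(
            area_id="K", age_group="all", coef=np.array([0.02]),
            vcov=np.array([[sigma2]]), mmt=18.0, spec=spec, temp_range=(0.0, 35.0),
        )
        store = hc.RiskStore(); store.add(rf)
        areas = hc.AreaTable(pd.DataFrame([{
            "area_id": "K", "region": "R", "lon": 0.0, "lat": 50.0,
            "age_group": "all", "population": 1000, "annual_rate": 0.01,
        }]))
        series = pd.DataFrame([{  # one cell, 10 degC above the MMT
            "area_id": "K", "date": pd.Timestamp("2022-07-19"), "tmean": 28.0,
            "lead_days": 0,
        }])
        table = hc.forecast_impacts(series, store, areas, mode="net")
        out = hc.monte_carlo_eci(table, store, n_sim=10_000, seed=3)
        b = table.cells["baseline"].iloc[0]
        # invert d = b(1 - e^{-beta}) to recover the simulated beta draws
        beta_sims = -np.log(1.0 - out.sims[0] / b)
        dx = 28.0 - 18.0
        ks = stats.kstest(
            beta_sims, "norm", args=(0.02 * dx, np.sqrt(sigma2) * dx)
        )
        assert ks.pvalue > 0.01

    def test_aggregate_eci_equals_eci_of_cell_sums(self, tiny_store):
        store, areas = tiny_store
        series = _series(tiny_store, {"X1": [25.0, 30.0], "X2": [26.0, 31.0]})
        table = hc.forecast_impacts(series, store, areas, mode="net")
        out = hc.monte_carlo_eci(table, store, n_sim=400, seed=5)
        agg = hc.aggregate(out, by=[], areas=areas)
        sums = out.sims.sum(axis=0)
        assert agg["eci_lo"].iloc[0] == pytest.approx(np.quantile(sums, 0.025), rel=1e-12)
        assert agg["eci_hi"].iloc[0] == pytest.approx(np.quantile(sums, 0.975), rel=1e-12)

    def test_eci_width_shrinks_with_vcov_scale(self, tiny_store):
        store, areas = tiny_store
        series = _series(tiny_store, {"X1": [30.0], "X2": [30.0]})

        def width(scale):
            st = hc.RiskStore()
            for rf in store.values():
                st.add(hc.RiskFunction(
                    area_id=rf.area_id, age_group=rf.age_group, coef=rf.coef,
                    vcov=scale * rf.vcov, mmt=rf.mmt, spec=rf.spec,
                    temp_range=rf.temp_range,
                ))
            t = hc.forecast_impacts(series, st, areas, mode="net")
            out = hc.monte_carlo_eci(t, st, n_sim=500, seed=9)
            agg = hc.aggregate(out, by=[], areas=areas)
            return float(agg["eci_hi"].iloc[0] - agg["eci_lo"].iloc[0])

        assert width(1.0) > width(0.25) > width(0.0) == 0.0

    def test_n_sim_floor_enforced(self, tiny_store):
        store, areas = tiny_store
        series = _series(tiny_store, {"X1": [25.0], "X2": [25.0]})
        table = hc.forecast_impacts(series, store, areas)
        with pytest.raises(ValueError, match="at least 100"):
            hc.monte_carlo_eci(table, store, n_sim=10)


class TestAggregate:
    def test_grand_total_and_partitions(self, pipeline_bundle):
        series = pipeline_bundle["series"]
        store, areas = pipeline_bundle["store"], pipeline_bundle["areas"]
        table = hc.forecast_impacts(series, store, areas, mode="heat")
        table = hc.monte_carlo_eci(table, store, n_sim=200, seed=2)
        total = hc.aggregate(table, by=[], areas=areas)["excess"].iloc[0]
        assert total == pytest.approx(table.total(), rel=1e-12)
        for keys in (["region"], ["age_group"], ["date"], ["region", "age_group", "date"]):
            agg = hc.aggregate(table, by=keys, areas=areas)
            assert agg["excess"].sum() == pytest.approx(total, rel=1e-9)

    def test_rate_hand_check_single_area(self, tiny_store):
        store, areas = tiny_store
        series = _series(tiny_store, {"X1": [30.0], "X2": [18.0]})
        table = hc.forecast_impacts(series, store, areas, mode="heat")
        agg = hc.aggregate(table, by=["region"], areas=areas)
        d = table.total()
        # both areas share region R0: population 2 x 10,000
        assert agg["rate_per_million"].iloc[0] == pytest.approx(
            1e6 * d / 20_000, rel=1e-12
        )

    def test_population_counted_once_across_dates(self, tiny_store):
        store, areas = tiny_store
        series = _series(tiny_store, {"X1": [30.0, 30.0, 30.0], "X2": [18.0] * 3})
        agg = hc.aggregate(
            hc.forecast_impacts(series, store, areas, mode="heat"),
            by=["region"], areas=areas,
        )
        assert agg["population"].iloc[0] == 20_000

    def test_bad_grouping_key_rejected(self, tiny_store):
        store, areas = tiny_store
        series = _series(tiny_store, {"X1": [30.0], "X2": [18.0]})
        table = hc.forecast_impacts(series, store, areas)
        with pytest.raises(ValueError, match="subset"):
            hc.aggregate(table, by=["banana"], areas=areas)
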