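"""Tests for the fixed-effects panel model and its derived response surface."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.stattools import durbin_watson as sm_dw

from speiyield import (
    EstimationError,
    PanelFit,
    TruePanelParams,
    decade_summary,
    durbin_watson,
    fit_panel,
    generate_yields,
    loss_thresholds,
    optimum_spei,
    response,
    response_table,
)

TABLE_FIT = PanelFit.from_coefficients(alpha1=-0.1592, alpha2=-0.1297)


def make_panel(intercepts, alpha1, alpha2, alpha3, rho=0.0, error_sd=0.0, seed=0,
               n_years=20):
    rng = np.random.default_rng(seed)
    sites = list(intercepts)
    years = list(range(1990, 1990 + n_years))
    cov = pd.DataFrame(
        [(s, y, rng.normal(0, 0.8)) for s in sites for y in years],
        columns=["site", "year", "spei"],
    )
    params = TruePanelParams(
        site_intercepts=intercepts, alpha1=alpha1, alpha2=alpha2, alpha3=alpha3,
        rho=rho, error_sd=error_sd,
    )
    yields = generate_yields(cov, params, seed=seed + 1)
    return yields, cov


class TestFitPanel:
    def test_noise_free_exact_recovery(self):
        intercepts = {"a": 3.0, "b": 3.5, "c": 2.8}
        yields, cov = make_panel(intercepts, -0.1592, -0.1297, 0.0626)
        fit = fit_panel(yields, cov, ar1="off")
        assert fit.alpha1 == pytest.approx(-0.1592, rel=1e-7)
        assert fit.alpha2 == pytest.approx(-0.1297, rel=1e-7)
        assert fit.alpha3 == pytest.approx(0.0626, rel=1e-7)
        for s, b in intercepts.items():
            assert fit.site_intercepts[s] == pytest.approx(b, rel=1e-7)
        assert fit.mean_intercept == pytest.approx(np.mean(list(intercepts.values())), rel=1e-7)

    def test_matches_normal_equations_oracle(self):
        # Independent solve of the LSDV normal equations on a two-site toy.
        yields, cov = make_panel({"a": 3.0, "b": 4.0}, -0.2, -0.1, 0.05,
                                 error_sd=0.1, seed=3, n_years=8)
        fit = fit_panel(yields, cov, ar1="off")
        df = yields.merge(cov, on=["site", "year"]).sort_values(["site", "year"])
        t = df.groupby("site").cumcount().to_numpy() + 1
        s = df.spei.to_numpy()
        X = np.column_stack([
            (df.site == "a").astype(float),
            (df.site == "b").astype(float),
            s, s**2, t,
        ])
        beta = np.linalg.solve(X.T @ X, X.T @ df.yield_t_ha.to_numpy())
        assert fit.site_intercepts["a"] == pytest.approx(beta[0], rel=1e-9)
        assert fit.alpha1 == pytest.approx(beta[2], rel=1e-9)
        assert fit.alpha2 == pytest.approx(beta[3], rel=1e-9)
        assert fit.alpha3 == pytest.approx(beta[4], rel=1e-9)

    def test_intercept_shift_invariance(self):
        yields, cov = make_panel({"a": 3.0, "b": 4.0}, -0.2, -0.1, 0.05,
                                 error_sd=0.15, seed=4)
        fit = fit_panel(yields, cov, ar1="off")
        shifted = yields.assign(yield_t_ha=yields.yield_t_ha + 2.5)
        fit2 = fit_panel(shifted, cov, ar1="off")
        assert fit2.alpha1 == pytest.approx(fit.alpha1, rel=1e-9)
        assert fit2.alpha2 == pytest.approx(fit.alpha2, rel=1e-9)
        for s in fit.site_intercepts:
            assert fit2.site_intercepts[s] == pytest.approx(fit.site_intercepts[s] + 2.5, rel=1e-9)

    def test_ar1_detected_and_rho_recovered(self):
        yields, cov = make_panel({"a": 3.0, "b": 3.5, "c": 4.0, "d": 2.9}, -0.16,
                                 -0.13, 0.06, rho=0.6, error_sd=0.3, seed=5,
                                 n_years=35)
        fit = fit_panel(yields, cov, ar1="auto")
        assert fit.ar1_applied
        assert fit.dw < 1.5
        assert 0.3 < fit.rho < 0.8

    def test_constant_covariate_rejected(self):
        yields, cov = make_panel({"a": 3.0, "b": 4.0}, -0.2, -0.1, 0.05)
        cov["spei"] = 0.5
        with pytest.raises(EstimationError):
            fit_panel(yields, cov)

    def test_unmatched_cells_dropped_with_count(self):
        yields, cov = make_panel({"a": 3.0, "b": 4.0}, -0.2, -0.1, 0.05, n_years=10)
        fit = fit_panel(yields, cov.drop(cov.index[:2]), ar1="off")
        assert fit.n_dropped == 2
        assert fit.n_obs == len(yields) - 2

    def test_minimum_panel_size_enforced(self):
        yields, cov = make_panel({"a": 3.0, "b": 4.0}, -0.2, -0.1, 0.05, n_years=4)
        with pytest.raises(ValueError):
            fit_panel(yields, cov)


class TestDurbinWatson:
    def test_alternating_residuals_approach_four(self):
        n = 200
        e = np.tile([1.0, -1.0], n // 2)
        assert durbin_watson({"s": e}) == pytest.approx(4.0 * (n - 1) / n)

    def test_iid_residuals_near_two(self):
        rng = np.random.default_rng(6)
        e = rng.normal(size=5000)
        assert durbin_watson({"s": e}) == pytest.approx(2.0, abs=0.1)

    def test_persistent_residuals_below_one(self):
        rng = np.random.default_rng(7)
        e = np.zeros(2000)
        for i in range(1, 2000):
            e[i] = 0.9 * e[i - 1] + rng.normal()
        assert durbin_watson({"s": e}) < 1.0

    def test_single_site_matches_statsmodels(self):
        rng = np.random.default_rng(8)
        e = rng.normal(size=100)
        assert durbin_watson({"s": e}) == pytest.approx(sm_dw(e), abs=1e-12)

    def test_differences_do_not_cross_sites(self):
        # concatenating two sites must not create a spurious difference
        a = np.array([1.0, 1.1, 0.9])
        b = np.array([5.0, 5.1, 4.9])
        within = durbin_watson({"a": a, "b": b})
        pooled = durbin_watson({"ab": np.concatenate([a, b])})
        assert within != pytest.approx(pooled)

    def test_too_short_everywhere_rejected(self):
        with pytest.raises(ValueError):
            durbin_watson({"a": [1.0], "b": [2.0]})


class TestResponseSurface:
    @pytest.mark.parametrize(
        "s, expected",
        [(2.0, -837.2), (1.0, -288.9), (0.5, -112.0), (-0.5, 47.2), (-1.0, 29.5), (-2.0, -200.4)],
    )
    def test_reported_level_responses(self, s, expected):
        assert round(response(s, TABLE_FIT), 1) == expected

    def test_baseline_zero(self):
        assert response(0.0, TABLE_FIT) == 0.0

    def test_optimum(self):
        assert round(optimum_spei(TABLE_FIT), 2) == -0.61
        sym = PanelFit.from_coefficients(alpha1=0.0, alpha2=-1.0)
        assert optimum_spei(sym) == 0.0

    def test_optimum_is_argmax_on_grid(self):
        v = optimum_spei(TABLE_FIT)
        grid = np.linspace(-3, 3, 1201)
        assert response(v, TABLE_FIT) >= response(grid, TABLE_FIT).max() - 1e-9

    def test_convex_response_rejected(self):
        with pytest.raises(EstimationError):
            optimum_spei(PanelFit.from_coefficients(alpha1=0.1, alpha2=0.2))

    def test_loss_thresholds(self):
        lo, hi = loss_thresholds(TABLE_FIT)
        assert round(lo, 2) == -1.23 and hi == 0.0
        for t in (lo, hi):
            assert abs(response(t, TABLE_FIT)) < 1e-9
        v = optimum_spei(TABLE_FIT)
        assert lo < v < hi
        grid = np.linspace(lo + 1e-6, hi - 1e-6, 101)
        assert np.all(response(grid, TABLE_FIT) > 0)
        outside = np.array([lo - 0.5, hi + 0.5])
        assert np.all(response(outside, TABLE_FIT) < 0)

    def test_wet_losses_exceed_equal_drought(self):
        L = np.linspace(0.01, 4.0, 400)
        assert np.all(np.abs(response(L, TABLE_FIT)) > np.abs(response(-L, TABLE_FIT)))


class TestResponseTable:
    def test_reported_rows(self):
        tbl = response_table(TABLE_FIT).set_index("level")
        slight_wet = tbl.loc["slight wetting"]
        assert round(slight_wet.response_lo_kg_ha, 1) == -288.9
        assert round(slight_wet.response_hi_kg_ha, 1) == -112.0
        normal = tbl.loc["normal"]
        assert round(normal.response_lo_kg_ha, 1) == -112.0
        assert round(normal.response_hi_kg_ha, 1) == 47.2
        extreme_dry = tbl.loc["extreme drought"]
        assert round(extreme_dry.response_hi_kg_ha, 1) == -200.4
        assert np.isneginf(extreme_dry.response_lo_kg_ha)
        moderate_wet = tbl.loc["moderate wetting"]
        assert round(moderate_wet.response_lo_kg_ha, 1) == -837.2
        assert round(moderate_wet.response_hi_kg_ha, 1) == -288.9

    def test_vertex_aware_upper_bound_in_slight_drought(self):
        tbl = response_table(TABLE_FIT).set_index("level")
        v = optimum_spei(TABLE_FIT)
        assert tbl.loc["slight drought"].response_hi_kg_ha == pytest.approx(
            response(v, TABLE_FIT)
        )

    def test_levels_tile_the_axis(self):
        tbl = response_table(TABLE_FIT)
        bounds = tbl.sort_values("spei_lo")[["spei_lo", "spei_hi"]].to_numpy()
        for (lo1, hi1), (lo2, _) in zip(bounds, bounds[1:]):
            assert hi1 == lo2


class TestDecadeSummary:
    def test_reported_decade_responses(self):
        values = pd.DataFrame(
            {
                "site": "all",
                "year": [1985, 1995, 2005],
                "spei": [0.0422, 0.3225, -0.3772],
            }
        )
        out = decade_summary(
            values, [(1980, 1989), (1990, 1999), (2000, 2014)], fit=TABLE_FIT
        )
        assert [round(r, 2) for r in out.response_kg_ha] == [-6.95, -64.83, 41.60]

    def test_constant_series(self):
        values = pd.DataFrame({"site": "a", "year": range(1980, 2000), "spei": 0.3})
        out = decade_summary(values, [(1980, 1989), (1990, 1999)])
        np.testing.assert_allclose(out["mean"], 0.3)

    def test_empty_period_rejected(self):
        values = pd.DataFrame({"site": "a", "year": [1985], "spei": [0.1]})
        with pytest.raises(ValueError):
            decade_summary(values, [(1990, 1999)])

    def test_overlapping_periods_rejected(self):
        values = pd.DataFrame({"site": "a", "year": range(1980, 2000), "spei": 0.0})
        with pytest.raises(ValueError):
            decade_summary(values, [(1980, 1990), (1990, 1999)])
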