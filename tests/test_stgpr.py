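"""Three-stage smoother: lag covariate, prior, residual smoothing, GP, gap-fill.

Stage 2 and stage 3 are each checked against an independent brute-force
oracle (explicit double loops / the closed-form Gaussian conditional).
"""

import numpy as np
import pandas as pd
import pytest

from nutledger.errors import ConfigurationError, SchemaError
from nutledger.stgpr import (
    STGPRParams,
    default_lag_weights,
    fill_time_series,
    lag_distributed_income,
    matern32,
    stage1_prior,
    stage2_residual_smooth,
    stage3_gp,
)


def _income_df(values, location="a", start=2000):
    return pd.DataFrame(
        {
            "location_id": location,
            "year": np.arange(start, start + len(values)),
            "income_per_capita": values,
        }
    )


class TestLagDistributedIncome:
    def test_constant_income_maps_to_itself(self):
        out = lag_distributed_income(_income_df([500.0] * 15))
        np.testing.assert_allclose(out["ldi"], 500.0)

    def test_single_year_renormalises_to_itself(self):
        out = lag_distributed_income(_income_df([123.0]))
        assert out["ldi"].iloc[0] == pytest.approx(123.0)

    def test_linear_ramp_matches_direct_summation(self):
        x = np.arange(100.0, 120.0)
        out = lag_distributed_income(_income_df(x), window=10)
        w = default_lag_weights(10)
        # brute-force oracle: explicit weighted sum over available lags
        for i in range(len(x)):
            lags = [x[i - k] for k in range(10) if i - k >= 0]
            weights = w[: len(lags)]
            expected = float(np.dot(weights, lags) / weights.sum())
            assert out["ldi"].iloc[i] == pytest.approx(expected, abs=1e-12)

    def test_empty_series_raises(self):
        with pytest.raises(SchemaError):
            lag_distributed_income(_income_df([]))

    def test_custom_weights_validated(self):
        with pytest.raises(ConfigurationError):
            lag_distributed_income(_income_df([1.0] * 5), window=3, weights=[1.0, -1.0, 1.0])


def _grid_covariates(n_loc=6, years=range(2000, 2010), n_regions=2, slope=100.0):
    rows = []
    for i in range(n_loc):
        for year in years:
            income = 1000.0 * np.exp(0.5 * i)
            rows.append(
                {
                    "location_id": f"l{i}",
                    "year": year,
                    "income_per_capita": income,
                    "super_region": f"r{i % n_regions}",
                }
            )
    return pd.DataFrame(rows)


class TestStage1Prior:
    def test_exact_linear_model_has_zero_residuals(self):
        cov = _grid_covariates()
        from nutledger.stgpr import _prepare_covariates

        full = _prepare_covariates(cov)
        intercepts = {"r0": 5.0, "r1": -3.0}
        full["value"] = full["super_region"].map(intercepts) + 2.0 * np.log(full["ldi"])
        prior, coef = stage1_prior(full[["location_id", "year", "value"]], cov)
        merged = full.merge(prior, on=["location_id", "year"])
        np.testing.assert_allclose(merged["value"], merged["prior"], atol=1e-8)
        assert coef["slope"] == pytest.approx(2.0, abs=1e-8)

    def test_unobserved_location_gets_super_region_line(self):
        cov = _grid_covariates()
        from nutledger.stgpr import _prepare_covariates

        full = _prepare_covariates(cov)
        full["value"] = 1.0 + 3.0 * np.log(full["ldi"])
        observed = full[full["location_id"] != "l0"]
        prior, coef = stage1_prior(observed[["location_id", "year", "value"]], cov)
        l0 = prior[prior["location_id"] == "l0"].merge(
            full[["location_id", "year", "ldi"]], on=["location_id", "year"]
        )
        expected = coef["intercepts"]["r0"] + coef["slope"] * np.log(l0["ldi"])
        np.testing.assert_allclose(l0["prior"], expected, atol=1e-10)

    def test_all_missing_nutrient_error_names_it(self):
        cov = _grid_covariates()
        with pytest.raises(SchemaError, match="iron_mg"):
            stage1_prior(pd.DataFrame(columns=["location_id", "year", "value"]),
                         cov, nutrient="iron_mg")

    def test_coefficient_recovery_on_noisy_panel(self):
        rng = np.random.default_rng(0)
        cov = _grid_covariates(n_loc=40, years=range(1990, 2010), n_regions=4)
        from nutledger.stgpr import _prepare_covariates

        full = _prepare_covariates(cov)
        true_slope = 150.0
        full["value"] = 10.0 + true_slope * np.log(full["ldi"]) + rng.normal(0, 20, len(full))
        observed = full.sample(frac=0.8, random_state=1)
        _, coef = stage1_prior(observed[["location_id", "year", "value"]], cov)
        n = len(observed)
        se_rough = 20.0 / np.sqrt(n) / np.std(np.log(full["ldi"]))
        assert abs(coef["slope"] - true_slope) < 4 * se_rough


def _oracle_stage2(residuals, super_regions, targets, lambda_time, zeta):
    """Explicit double-loop weighted average (independent of the implementation)."""
    obs = list(residuals.itertuples(index=False))
    max_dt = max(
        abs(t_year - o.year) for (_, t_year) in targets for o in obs
    )
    out = {}
    for t_loc, t_year in targets:
        num = den = 0.0
        for o in obs:
            w_t = (1 - (abs(t_year - o.year) / (1 + max_dt)) ** lambda_time) ** 3
            if o.location_id == t_loc:
                w_s = zeta
            elif super_regions[o.location_id] == super_regions[t_loc]:
                w_s = zeta * (1 - zeta)
            else:
                w_s = (1 - zeta) ** 2
            num += w_t * w_s * o.resid
            den += w_t * w_s
        out[(t_loc, t_year)] = num / den if den > 0 else 0.0
    return out


class TestStage2ResidualSmooth:
    def _regions(self):
        return pd.Series(
            {"l0": "r0", "l1": "r0", "l2": "r1", "l3": "r1", "l4": "r2"}
        )

    def test_single_residual_fills_everything(self):
        residuals = pd.DataFrame(
            {"location_id": ["l0"], "year": [2002], "resid": [3.5]}
        )
        out = stage2_residual_smooth(
            residuals, self._regions(), ["l0", "l1", "l2"], range(2000, 2005),
            lambda_time=0.5, zeta_space=0.9,
        )
        np.testing.assert_allclose(out["smooth"], 3.5, atol=1e-12)

    def test_zeta_one_uses_only_own_location(self):
        residuals = pd.DataFrame(
            {
                "location_id": ["l0"] * 5 + ["l1"] * 5,
                "year": list(range(2000, 2005)) * 2,
                "resid": [1.0] * 5 + [100.0] * 5,
            }
        )
        out = stage2_residual_smooth(
            residuals, self._regions(), ["l0"], range(2000, 2005),
            lambda_time=0.5, zeta_space=1.0,
        )
        np.testing.assert_allclose(out["smooth"], 1.0, atol=1e-12)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(12)
        locs = ["l0", "l1", "l2", "l3", "l4"]
        years = list(range(2000, 2005))
        cells = [(l, y) for l in locs for y in years]
        observed = [cells[i] for i in rng.choice(len(cells), size=15, replace=False)]
        residuals = pd.DataFrame(
            {
                "location_id": [c[0] for c in observed],
                "year": [c[1] for c in observed],
                "resid": rng.normal(size=len(observed)),
            }
        )
        out = stage2_residual_smooth(
            residuals, self._regions(), locs, years, lambda_time=0.7, zeta_space=0.8
        )
        oracle = _oracle_stage2(residuals, self._regions(), cells, 0.7, 0.8)
        for _, row in out.iterrows():
            assert row["smooth"] == pytest.approx(
                oracle[(row["location_id"], row["year"])], abs=1e-12
            )

    def test_no_residuals_raises(self):
        with pytest.raises(SchemaError):
            stage2_residual_smooth(
                pd.DataFrame(columns=["location_id", "year", "resid"]),
                self._regions(), ["l0"], [2000],
            )


def _oracle_gp_conditional(years, mu, yo, vo, mo, amplitude, ls, nugget):
    """Closed-form Gaussian conditional, assembled independently."""
    def k(a, b):
        d = np.abs(np.subtract.outer(a, b)) * np.sqrt(3.0) / ls
        return amplitude**2 * (1 + d) * np.exp(-d)

    K_oo = k(yo, yo) + nugget * np.eye(len(yo))
    K_go = k(years, yo)
    inv = np.linalg.inv(K_oo)
    mean = mu + K_go @ inv @ (vo - mo)
    cov = k(years, years) - K_go @ inv @ K_go.T
    return mean, cov


class TestStage3GP:
    def _params(self, **kw):
        defaults = dict(gp_amplitude=50.0, gp_nugget=4.0, gp_length_scale_years=8.0,
                        n_draws=200, seed=3)
        defaults.update(kw)
        return STGPRParams(**defaults)

    def _prior(self, years, mu, loc="l0"):
        return pd.DataFrame({"location_id": loc, "year": years, "prior": mu})

    def test_interpolates_observations_as_nugget_vanishes(self):
        years = np.arange(2000, 2010)
        prior = self._prior(years, np.zeros(10))
        observed = pd.DataFrame(
            {"location_id": "l0", "year": years, "value": np.sin(years - 2000.0) * 10}
        )
        out = stage3_gp(prior, observed, self._params(gp_nugget=1e-9))
        np.testing.assert_allclose(out["mean"], observed["value"], atol=1e-6)

    def test_no_observations_returns_prior_mean(self):
        years = np.arange(2000, 2010)
        mu = np.linspace(5, 20, 10)
        prior = self._prior(years, mu)
        observed = pd.DataFrame(columns=["location_id", "year", "value"])
        out = stage3_gp(prior, observed, self._params())
        np.testing.assert_allclose(out["mean"], mu, atol=1e-12)

    def test_matches_closed_form_conditional_on_small_instance(self):
        rng = np.random.default_rng(5)
        years = np.arange(2000, 2008, dtype=float)
        mu = rng.normal(0, 10, size=len(years))
        idx = np.array([0, 2, 3, 6])
        vo = mu[idx] + rng.normal(0, 3, size=len(idx))
        prior = self._prior(years.astype(int), mu)
        observed = pd.DataFrame(
            {"location_id": "l0", "year": years[idx].astype(int), "value": vo}
        )
        params = self._params()
        out = stage3_gp(prior, observed, params)
        mean, cov = _oracle_gp_conditional(
            years, mu, years[idx], vo, mu[idx], 50.0, 8.0, 4.0
        )
        np.testing.assert_allclose(out["mean"], mean, atol=1e-8)
        np.testing.assert_allclose(
            out["sd"], np.sqrt(np.diag(cov) + 4.0), atol=1e-6
        )

    def test_posterior_variance_never_exceeds_prior_variance(self):
        years = np.arange(2000, 2010)
        prior = self._prior(years, np.zeros(10))
        observed = pd.DataFrame(
            {"location_id": "l0", "year": [2003, 2007], "value": [1.0, -2.0]}
        )
        params = self._params()
        out = stage3_gp(prior, observed, params)
        prior_sd = np.sqrt(params.gp_amplitude**2 + params.gp_nugget)
        assert (out["sd"] <= prior_sd + 1e-9).all()

    def test_draw_percentiles_deterministic_given_seed(self):
        years = np.arange(2000, 2010)
        prior = self._prior(years, np.zeros(10))
        observed = pd.DataFrame(
            {"location_id": "l0", "year": [2004], "value": [5.0]}
        )
        a = stage3_gp(prior, observed, self._params())
        b = stage3_gp(prior, observed, self._params())
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            STGPRParams(n_draws=10).validate()
        with pytest.raises(ConfigurationError):
            STGPRParams(zeta_space=1.5).validate()

    def test_matern32_kernel_shape(self):
        assert matern32(np.array(0.0), 2.0, 5.0) == pytest.approx(4.0)
        assert matern32(np.array(100.0), 2.0, 5.0) < 1e-10


class TestFillTimeSeries:
    def test_complete_panel_with_tiny_nugget_reproduces_input(self, small_world):
        truth = small_world.ground_truth.true_availability_panel
        panel = truth[truth["nutrient_id"] == "energy_kcal"]
        params = STGPRParams(gp_nugget=1e-9, n_draws=100, seed=1)
        filled = fill_time_series(panel, small_world.covariates, params)
        merged = filled.merge(
            panel, on=["location_id", "year", "nutrient_id"], suffixes=("_f", "_t")
        )
        np.testing.assert_allclose(merged["value_f"], merged["value_t"], rtol=1e-5)
        assert merged["observed_f"].all()

    def test_every_location_year_populated_and_nonnegative(self, small_world, small_panel):
        params = STGPRParams(n_draws=100, seed=1)
        filled = fill_time_series(
            small_panel, small_world.covariates, params, nutrients=["energy_kcal", "iron_mg"]
        )
        cfg = small_world.config
        assert len(filled) == 2 * cfg.n_locations * len(cfg.years)
        assert (filled["value"] >= 0).all()
        assert (filled["lower"] <= filled["upper"]).all()

    def test_observed_flag_preserved(self, small_world, small_panel):
        params = STGPRParams(n_draws=100, seed=1)
        filled = fill_time_series(
            small_panel, small_world.covariates, params, nutrients=["energy_kcal"]
        )
        obs_keys = set(
            map(tuple, small_panel.query("nutrient_id == 'energy_kcal'")[
                ["location_id", "year"]
            ].itertuples(index=False))
        )
        flagged = set(
            map(tuple, filled[filled["observed"]][["location_id", "year"]].itertuples(
                index=False
            ))
        )
        assert flagged == obs_keys

    def test_rerun_bit_identical(self, small_world, small_panel):
        params = STGPRParams(n_draws=100, seed=6)
        a = fill_time_series(small_panel, small_world.covariates, params,
                             nutrients=["energy_kcal"])
        b = fill_time_series(small_panel, small_world.covariates, params,
                             nutrients=["energy_kcal"])
        pd.testing.assert_frame_equal(a, b)
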