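"""Cross-basis construction and the quasi-Poisson DLNM fit."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import heatlag as hl
from heatlag.basis import build_crossbasis, lag_basis_matrix, log_lag_knots
from heatlag.dlnm import DLNM


@pytest.fixture(scope="module")
def hundred_day_fit(target_weather, target_mortality):
    """A 100-day fit; the fitted design matrix is used for oracle checks."""
    w = target_weather.iloc[:100].reset_index(drop=True)
    y = target_mortality[0]["count"].to_numpy()[:100]
    dates = pd.DatetimeIndex(pd.to_datetime(w["date"]))
    res = DLNM(trend_df_per_year=2).fit(w["tmax"], y, dates)
    return res, res.design, y


class TestCrossBasis:
    def test_tensor_product_dimension(self, one_season_weather):
        cb = build_crossbasis(one_season_weather["tmax"], one_season_weather["date"])
        assert cb.matrix.shape == (62, 4)
        assert cb.n_columns == cb.var_df * cb.lag_df == 4
        # independent audit: the tensor of the marginal bases has the same size
        lag_b = lag_basis_matrix(np.arange(15.0), cb.lag_knots)
        assert cb.matrix.shape[1] == cb.var_basis(np.array([30.0])).shape[1] * lag_b.shape[1]

    def test_constant_series_gives_identical_rows(self):
        dates = pd.date_range("2009-07-01", "2009-08-31")
        cb = build_crossbasis(np.full(62, 30.0), dates)
        assert np.allclose(cb.matrix, cb.matrix[0])

    def test_lag_structure_is_order_dependent(self, one_season_weather):
        rng = np.random.default_rng(0)
        x = one_season_weather["tmax"].to_numpy()
        perm = rng.permutation(len(x))
        a = build_crossbasis(x[perm], one_season_weather["date"]).matrix
        b = build_crossbasis(x, one_season_weather["date"]).matrix[perm]
        assert not np.allclose(a, b)

    def test_too_short_series_is_an_error(self):
        dates = pd.date_range("2009-07-01", periods=10)
        with pytest.raises(ValueError, match="at least"):
            build_crossbasis(np.arange(10.0), dates, max_lag=14)

    def test_log_lag_knot_placement(self):
        knots = log_lag_knots(14, 3)
        assert knots[0] == pytest.approx(0.0)
        assert knots[-1] == pytest.approx(14.0)
        # interior knot equally spaced on the log(lag+1) scale
        assert np.log(knots[1] + 1) == pytest.approx(np.log(15.0) / 2)


class TestFit:
    def test_irls_matches_brute_force_optimizer(self, hundred_day_fit):
        res, X, y = hundred_day_fit

        def negll(beta):
            eta = X @ beta
            return float(np.sum(np.exp(eta)) - y @ eta)

        def grad(beta):
            return X.T @ (np.exp(X @ beta) - y)

        def hess(beta):
            return X.T @ (X * np.exp(X @ beta)[:, None])

        x0 = np.zeros(X.shape[1])
        x0[0] = np.log(y.mean())
        opt = optimize.minimize(negll, x0, jac=grad, hess=hess,
                                method="trust-exact",
                                options={"gtol": 1e-10, "maxiter": 500})
        np.testing.assert_allclose(res.coef, opt.x, atol=1e-6, rtol=1e-6)

    def test_point_estimates_match_poisson_mle(self, hundred_day_fit):
        statsmodels = pytest.importorskip("statsmodels.api")
        res, X, y = hundred_day_fit
        glm = statsmodels.GLM(y, X, family=statsmodels.families.Poisson()).fit()
        np.testing.assert_allclose(res.coef, glm.params, atol=1e-8)
        # dispersion scales only the covariance
        np.testing.assert_allclose(
            res.cov, res.dispersion * glm.cov_params() / glm.scale, rtol=1e-6
        )

    def test_dispersion_and_covariance_shape(self, scenario, target_weather,
                                             target_mortality):
        m, _ = target_mortality
        res = DLNM().fit(target_weather["tmax"], m["count"], target_weather["date"])
        assert res.dispersion > 0
        assert np.allclose(res.cov, res.cov.T)
        assert (np.linalg.eigvalsh(res.cov) > -1e-10).all()

    def test_collinear_design_raises(self):
        dates = pd.date_range("2009-07-01", "2009-08-31")
        counts = np.random.default_rng(0).poisson(10, 62)
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            DLNM().fit(np.full(62, 30.0), counts, dates)


@pytest.fixture(scope="module")
def fitted(target_weather, target_mortality):
    m, _ = target_mortality
    return DLNM().fit(target_weather["tmax"], m["count"], target_weather["date"])


class TestSurface:

    def test_rr_is_one_at_reference(self, fitted):
        ref = float(np.median(fitted.crossbasis.exposure))
        surface = fitted.rr_surface(exposure_grid=np.array([ref, ref + 2.0]))
        at_ref = surface.grid[surface.grid["exposure"] == ref]
        np.testing.assert_allclose(at_ref["rr"], 1.0, atol=1e-12)
        assert len(at_ref) == 15

    def test_ci_brackets_point_estimate(self, fitted):
        surface = fitted.rr_surface()
        assert (surface.grid["lo"] <= surface.grid["rr"] + 1e-12).all()
        assert (surface.grid["rr"] <= surface.grid["hi"] + 1e-12).all()

    def test_widening_grid_preserves_shared_points(self, fitted):
        narrow = fitted.rr_surface(exposure_grid=np.array([32.0, 35.0]))
        wide = fitted.rr_surface(exposure_grid=np.array([28.0, 32.0, 35.0, 38.0]))
        for x in (32.0, 35.0):
            a = narrow.grid[narrow.grid["exposure"] == x].reset_index(drop=True)
            b = wide.grid[wide.grid["exposure"] == x].reset_index(drop=True)
            pd.testing.assert_frame_equal(a, b)

    def test_cumulative_rr_dominates_single_lags_when_signs_agree(self, fitted):
        x_hi = float(np.percentile(fitted.crossbasis.exposure, 95))
        surface = fitted.rr_surface(exposure_grid=np.array([x_hi]))
        per_lag = surface.grid["rr"].to_numpy()
        cum = surface.cumulative["rr"].iloc[0]
        if (per_lag >= 1.0).all():
            assert cum >= per_lag.max() - 1e-12


class TestLagRule:
    def test_persistent_significance_returns_max_lag(self):
        sc = hl.ScenarioConfig(effect_slope=0.25, lag_weights=tuple([1 / 14.0] * 14),
                               baseline_deaths=30, acclim_coeff=0.0, seed=3)
        w = hl.generate_weather(sc, "target")
        m, _ = hl.generate_mortality(w, sc)
        decision = DLNM().fit(w["tmax"], m["count"], w["date"]).specify_lag_days()
        assert decision.significant
        assert decision.lag_days == 14

    def test_null_fit_is_flagged(self):
        sc = hl.ScenarioConfig(effect_slope=0.0, acclim_coeff=0.0, seed=5)
        w = hl.generate_weather(sc, "target")
        m, _ = hl.generate_mortality(w, sc)
        decision = DLNM().fit(w["tmax"], m["count"], w["date"]).specify_lag_days()
        assert not decision.significant
        assert decision.lag_days == 1
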