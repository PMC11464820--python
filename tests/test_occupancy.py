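"""Autologistic occupancy: likelihood oracles, fitting, AIC, ratios."""

import itertools

import numpy as np
import pytest
from scipy.special import expit

from urbanmosaic.occupancy import (
    AutoOccParams,
    AutologisticOccupancy,
    DetectionHistory,
    SiteCovariates,
    compare_aic,
    fit_autologistic,
    loglik_autologistic,
    naive_occupancy,
    occupancy_ratio,
    summarize_covariate,
)
from urbanmosaic.fixtures import OccSimRecipe, simulate_detections
from urbanmosaic.raster import FloatRaster


def enumeration_loglik(y, x, beta, theta, alpha):
    """Independent oracle: sum over every latent occupancy configuration."""
    n, T, W = y.shape
    p = expit(alpha)
    total = 0.0
    for i in range(n):
        lik = 0.0
        for z in itertools.product([0, 1], repeat=T):
            pr = 1.0
            for t in range(T):
                eta = beta[0] + (beta[1] * x[i] if len(beta) > 1 else 0.0)
                if t > 0:
                    eta += theta * z[t - 1]
                psi = expit(eta)
                pr *= psi if z[t] else 1 - psi
                for w in range(W):
                    if np.isnan(y[i, t, w]):
                        continue
                    if z[t]:
                        pr *= p if y[i, t, w] == 1 else 1 - p
                    elif y[i, t, w] == 1:
                        pr = 0.0
            lik += pr
        total += np.log(lik)
    return total


def history(y):
    y = np.asarray(y, dtype=float)
    return DetectionHistory(
        y=y, sites=[f"s{i}" for i in range(y.shape[0])], seasons=[f"t{t}" for t in range(y.shape[1])]
    )


def covariates(x):
    x = np.asarray(x, dtype=float)
    return SiteCovariates(x=x, raw_mean=x, standardized=False)


class TestLoglik:
    def test_matches_enumeration_over_random_draws(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            y = rng.choice([0.0, 1.0, np.nan], size=(3, 2, 2), p=[0.5, 0.3, 0.2])
            x = rng.normal(size=3)
            beta = rng.normal(size=2)
            theta, alpha = rng.normal(), rng.normal()
            got = loglik_autologistic(
                history(y), covariates(x), AutoOccParams(beta=beta, theta=theta, alpha=[alpha])
            )
            assert got == pytest.approx(enumeration_loglik(y, x, beta, theta, alpha), abs=1e-10)

    def test_theta_zero_reduces_to_independent_seasons(self):
        rng = np.random.default_rng(1)
        y = rng.choice([0.0, 1.0], size=(4, 3, 2))
        x = rng.normal(size=4)
        params = AutoOccParams(beta=[0.3, -0.4], theta=0.0, alpha=[0.2])
        full = loglik_autologistic(history(y), covariates(x), params)
        seasons = sum(
            loglik_autologistic(history(y[:, [t], :]), covariates(x), params) for t in range(3)
        )
        assert full == pytest.approx(seasons, abs=1e-10)

    def test_certain_detection_limit_is_occupancy_logistic(self):
        """With p -> 1 and every week detected, the likelihood approaches a
        logistic model for z_t = 1 every season."""
        y = np.ones((5, 2, 2))
        x = np.linspace(-1, 1, 5)
        beta = np.array([0.4, 0.9])
        theta = 0.7
        got = loglik_autologistic(history(y), covariates(x), AutoOccParams(beta=beta, theta=theta, alpha=[10.0]))
        psi1 = expit(beta[0] + beta[1] * x)
        psi2 = expit(beta[0] + beta[1] * x + theta)
        expected = np.log(psi1).sum() + np.log(psi2).sum()
        assert got == pytest.approx(expected, rel=1e-3)

    def test_total_probability_sums_to_one(self):
        """exp(loglik) over all possible single-site histories is 1
        (2 seasons x 1 week: 4 possible detection histories)."""
        params = AutoOccParams(beta=[0.3], theta=0.8, alpha=[-0.2])
        x = np.array([0.0])
        total = 0.0
        for y1 in (0.0, 1.0):
            for y2 in (0.0, 1.0):
                y = np.array([[[y1], [y2]]])
                total += np.exp(loglik_autologistic(history(y), covariates(x), params))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_loglik_nonpositive(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            y = rng.choice([0.0, 1.0], size=(3, 2, 3))
            ll = loglik_autologistic(
                history(y),
                covariates(rng.normal(size=3)),
                AutoOccParams(beta=rng.normal(size=2), theta=rng.normal(), alpha=[rng.normal()]),
            )
            assert ll <= 1e-12

    def test_nonfinite_params_error(self):
        with pytest.raises(ValueError):
            AutoOccParams(beta=[np.inf], theta=0.0, alpha=[0.0])


class TestFit:
    def test_recovery_within_3se(self):
        h, x = simulate_detections(
            OccSimRecipe(seed=0, n_sites=200, n_seasons=4, weeks_per_season=(6, 6, 6, 6))
        )
        fit = fit_autologistic(h, covariates(x), "covariate", seed=0)
        truth = np.array([-0.5, 0.8, 1.0, 0.5])
        est = np.concatenate([fit.params.beta, [fit.params.theta], fit.params.alpha])
        se = fit.se()
        assert fit.converged
        assert (np.abs(est - truth) < 3 * se).all()

    def test_aic_prefers_covariate_model_at_large_effect(self):
        wins = 0
        for rep in range(10):
            h, x = simulate_detections(
                OccSimRecipe(
                    seed=100 + rep,
                    n_sites=100,
                    n_seasons=4,
                    weeks_per_season=(6, 6, 6, 6),
                    true_params=AutoOccParams(beta=[-0.5, 1.5], theta=1.0, alpha=[0.5]),
                )
            )
            cov = covariates(x)
            if fit_autologistic(h, cov, "covariate", seed=0).AIC < fit_autologistic(h, cov, "null", seed=0).AIC:
                wins += 1
        assert wins >= 9

    def test_single_season_errors_on_theta(self):
        h, x = simulate_detections(OccSimRecipe(seed=1, n_sites=20, n_seasons=1, weeks_per_season=(4,)))
        with pytest.raises(ValueError, match="theta"):
            fit_autologistic(h, covariates(x), "covariate")

    def test_loglik_invariant_to_covariate_rescale(self):
        h, x = simulate_detections(OccSimRecipe(seed=9, n_sites=80, n_seasons=3, weeks_per_season=(4, 4, 4)))
        f1 = fit_autologistic(h, covariates(x), "covariate", seed=0)
        f2 = fit_autologistic(h, covariates(2.0 * x + 3.0), "covariate", seed=0)
        assert f1.logLik == pytest.approx(f2.logLik, abs=1e-4)
        # slope transforms by the inverse scale
        assert f2.params.beta[1] == pytest.approx(f1.params.beta[1] / 2.0, abs=0.02)

    def test_estimator_wrapper(self):
        h, x = simulate_detections(OccSimRecipe(seed=2, n_sites=60, n_seasons=2, weeks_per_season=(4, 4)))
        est = AutologisticOccupancy(formula="covariate", seed=0).fit(h, covariates(x))
        assert est.aic_ == pytest.approx(-2 * est.loglik_ + 2 * est.result_.K)


class TestNaiveOccupancy:
    def test_all_ones(self):
        per, avg = naive_occupancy(history(np.ones((4, 2, 3))))
        assert all(v == 1.0 for v in per.values()) and avg == 1.0

    def test_all_zeros(self):
        per, avg = naive_occupancy(history(np.zeros((4, 2, 3))))
        assert avg == 0.0

    def test_hand_tallied_toy_history(self):
        # 4 sites x 2 seasons x 2 weeks
        y = np.array(
            [
                [[1, 0], [0, 0]],
                [[0, 0], [0, 1]],
                [[0, 0], [0, 0]],
                [[1, 1], [1, 0]],
            ],
            dtype=float,
        )
        per, avg = naive_occupancy(history(y))
        assert per["t0"] == pytest.approx(2 / 4)
        assert per["t1"] == pytest.approx(2 / 4)
        assert avg == pytest.approx(0.5)

    def test_unsampled_season_excluded(self):
        y = np.ones((3, 2, 2))
        y[:, 1, :] = np.nan
        per, avg = naive_occupancy(history(y))
        assert list(per) == ["t0"] and avg == 1.0


class TestCompareAic:
    def fake_fit(self, aic):
        return type("F", (), {"AIC": aic, "K": 3, "logLik": -(aic - 6) / 2})()

    def test_single_model(self):
        df = compare_aic({"only": self.fake_fit(100.0)})
        assert df.loc[0, "dAIC"] == 0.0 and df.loc[0, "weight"] == pytest.approx(1.0)

    def test_equal_aic_splits_weight(self):
        df = compare_aic({"a": self.fake_fit(50.0), "b": self.fake_fit(50.0)})
        assert np.allclose(df["weight"], 0.5)
        assert np.allclose(df["cum_weight"], [0.5, 1.0])

    def test_delta_four_weights(self):
        df = compare_aic({"top": self.fake_fit(10.0), "worse": self.fake_fit(14.0)})
        w = np.exp(-2.0) / (1.0 + np.exp(-2.0))
        assert df.loc[0, "weight"] == pytest.approx(1 - w, abs=1e-3)
        assert df.loc[1, "weight"] == pytest.approx(w, abs=1e-3)
        assert not df.loc[1, "competitive"] and df.loc[0, "competitive"]


class TestOccupancyRatio:
    def make_fit(self, beta, theta):
        params = AutoOccParams(beta=beta, theta=theta, alpha=[0.5])
        return type(
            "F", (), {"params": params, "AIC": 0.0, "K": 4, "logLik": 0.0}
        )()

    def test_no_effect_ratio_one(self):
        fit = self.make_fit([0.3, 0.0], 1.0)
        assert occupancy_ratio(fit, -2.0, 2.0) == pytest.approx(1.0)

    def test_theta_zero_closed_form(self):
        fit = self.make_fit([-0.5, 0.8], 0.0)
        expected = expit(-0.5 + 0.8 * 1.5) / expit(-0.5 - 0.8 * 1.5)
        assert occupancy_ratio(fit, -1.5, 1.5) == pytest.approx(expected, abs=1e-9)

    def test_matches_forward_simulation(self):
        beta, theta = [-0.5, 0.8], 1.0
        fit = self.make_fit(beta, theta)
        got = occupancy_ratio(fit, -1.0, 1.0)
        rng = np.random.default_rng(3)
        occ = {}
        for xv in (-1.0, 1.0):
            z = rng.random(200000) < expit(beta[0] + beta[1] * xv)
            for _ in range(60):  # long-run burn-in
                z = rng.random(z.size) < expit(beta[0] + beta[1] * xv + theta * z)
            occ[xv] = z.mean()
        assert got == pytest.approx(occ[1.0] / occ[-1.0], rel=0.02)


class TestSummarizeCovariate:
    def gradient_raster(self, n=40, cell=30.0):
        vals = np.add.outer(np.arange(n), np.arange(n)).astype(float)
        return FloatRaster(values=vals, transform=(0.0, n * cell, cell), crs="m")

    def test_matches_enumeration_oracle(self):
        idx = self.gradient_raster()
        sites = [(450.0, 450.0), (900.0, 300.0)]
        cov = summarize_covariate(idx, sites, radius=150.0)
        xs, ys = idx.cell_centers()
        for k, (sx, sy) in enumerate(sites):
            acc = [
                idx.values[i, j]
                for i in range(40)
                for j in range(40)
                if (xs[i, j] - sx) ** 2 + (ys[i, j] - sy) ** 2 <= 150.0**2
            ]
            assert cov.raw_mean[k] == pytest.approx(np.mean(acc))

    def test_small_radius_own_cell(self):
        idx = self.gradient_raster()
        cov = summarize_covariate(idx, [(45.0, 45.0), (105.0, 45.0)], radius=10.0)
        # cells containing (45,45) and (105,45): row 38, cols 1 and 3
        assert cov.raw_mean.tolist() == [39.0, 41.0]

    def test_standardized_output(self):
        idx = self.gradient_raster()
        cov = summarize_covariate(idx, [(300, 300), (600, 600), (900, 300)], radius=200.0)
        assert abs(cov.x.mean()) < 1e-12 and cov.x.std(ddof=0) == pytest.approx(1.0)

    def test_constant_raster_errors(self):
        flat = FloatRaster(values=np.full((20, 20), 5.0), transform=(0.0, 600.0, 30.0), crs="m")
        with pytest.raises(ValueError, match="constant"):
            summarize_covariate(flat, [(100, 100), (400, 400)], radius=100.0)
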